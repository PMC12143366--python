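"""Pairwise parallelism statistics between comparison units at one divergence
level: Jaccard index of significant gene sets, Fisher's exact overlap test, and
Spearman correlation of log2 fold changes across the whole transcriptome."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model import DETable, ExparallelError

log = logging.getLogger(__name__)


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; defined as 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        log.info("Jaccard of two empty sets, returning 0")
        return 0.0
    return len(a & b) / len(union)


def overlap_fisher(set_a, set_b, universe) -> tuple[float, float]:
    """Fisher's exact test (one-sided, greater) for overrepresentation of the
    overlap of two gene sets within a universe.  Returns (odds ratio, p)."""
    a, b, uni = set(set_a), set(set_b), set(universe)
    if not a <= uni or not b <= uni:
        raise ExparallelError("sets must be subsets of the universe")
    shared = len(a & b)
    table = [
        [shared, len(a) - shared],
        [len(b) - shared, len(uni) - len(a) - len(b) + shared],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def spearman_logfc(de_a: DETable, de_b: DETable) -> tuple[float | None, float | None]:
    """Spearman rho (average ranks for ties) of the two log2FC vectors over all
    genes, with the t-approximation p-value.  Zero variance in either vector is
    undefined and returned as (None, None) with a log message."""
    if set(de_a.gene_ids) != set(de_b.gene_ids):
        raise ExparallelError(
            f"units {de_a.unit_id} and {de_b.unit_id} have different gene universes"
        )
    x = de_a.log2fc.to_numpy(float)
    y = de_b.log2fc.reindex(de_a.gene_ids).to_numpy(float)
    if len(x) < 3:
        raise ExparallelError("Spearman correlation needs at least 3 genes")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        log.info("zero-variance log2FC vector; Spearman rho undefined")
        return None, None
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class PairwiseParallelism:
    """Parallelism statistics for one unordered pair of comparison units."""

    level: str
    unit_a: str
    unit_b: str
    jaccard: float
    n_shared: int
    n_a: int
    n_b: int
    n_universe: int
    fisher_odds: float
    fisher_p: float
    rho: float | None
    rho_p: float | None

    def pair_key(self) -> tuple[str, str]:
        return tuple(sorted((self.unit_a, self.unit_b)))


def pairwise_table(
    detables: list[DETable],
    fdr_threshold: float = 0.05,
    direction_concordant: bool = False,
) -> list[PairwiseParallelism]:
    """All C(n, 2) unordered pairs of units at one level.

    Significant sets are genes with q < ``fdr_threshold``.  By default sharing
    is direction-agnostic (significant in both units regardless of sign); with
    ``direction_concordant`` a gene only counts as shared when its fold change
    has the same sign in both units (the union is unchanged).
    """
    if len(detables) < 2:
        raise ExparallelError("need at least 2 comparison units for pairwise statistics")
    universe = set(detables[0].gene_ids)
    for de in detables[1:]:
        if set(de.gene_ids) != universe:
            raise ExparallelError(
                f"unit {de.unit_id} tested a different gene universe than {detables[0].unit_id}"
            )
    level = detables[0].level or "unknown"

    records = []
    for de_a, de_b in combinations(detables, 2):
        sig_a = de_a.significant_genes(fdr_threshold)
        sig_b = de_b.significant_genes(fdr_threshold)
        shared = sig_a & sig_b
        if direction_concordant and shared:
            sign_a = np.sign(de_a.table.loc[sorted(shared), "log2fc"])
            sign_b = np.sign(de_b.table.loc[sorted(shared), "log2fc"])
            shared = set(np.array(sorted(shared))[(sign_a == sign_b).to_numpy()])
        union = sig_a | sig_b
        jac = len(shared) / len(union) if union else 0.0
        odds, fisher_p = overlap_fisher(sig_a, sig_b, universe)
        rho, rho_p = spearman_logfc(de_a, de_b)
        records.append(
            PairwiseParallelism(
                level=level,
                unit_a=de_a.unit_id,
                unit_b=de_b.unit_id,
                jaccard=jac,
                n_shared=len(sig_a & sig_b),
                n_a=len(sig_a),
                n_b=len(sig_b),
                n_universe=len(universe),
                fisher_odds=odds,
                fisher_p=fisher_p,
                rho=rho,
                rho_p=rho_p,
            )
        )
    return records


def pairwise_frame(records: list[PairwiseParallelism]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def pairwise_values(records: list[PairwiseParallelism], statistic: str) -> dict[tuple[str, str], float]:
    """Map unordered unit pair -> statistic value (``jaccard`` or ``rho``)."""
    out = {}
    for r in records:
        v = getattr(r, statistic)
        if v is not None:
            out[r.pair_key()] = float(v)
    return out
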