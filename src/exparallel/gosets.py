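"""Gene-set-level parallelism.

Three operations: classic per-set Fisher (hypergeometric) enrichment of the
significant genes of one comparison unit; Spearman correlation of log2 fold
changes restricted to the members of each set, for a pair of units; and
distribution summaries of the per-set mean correlation per divergence level.

Enrichment is deliberately the classic one-sided Fisher test per set; no
ontology-hierarchy-aware weighting is applied (the set universe here is flat).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .model import DETable, ExparallelError, GeneSetCollection

log = logging.getLogger(__name__)


def fisher_enrichment(
    de_genes,
    universe,
    sets: GeneSetCollection,
    min_size: int = 5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation test of ``de_genes`` in each
    set with >= ``min_size`` members in the universe; BH-FDR across sets.

    Returns a frame indexed by set id with columns n_in_universe, n_de_in_set,
    fisher_p, qvalue, enriched.
    """
    uni = set(universe)
    de = set(de_genes)
    if not uni:
        raise ExparallelError("empty gene universe")
    if not de <= uni:
        raise ExparallelError("DE genes must be a subset of the universe")
    rows = []
    for sid in sorted(sets):
        members = sets.members(sid) & uni
        if len(members) < min_size:
            continue
        overlap = len(members & de)
        p = stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(de))
        rows.append((sid, len(members), overlap, float(p)))
    if not rows:
        return pd.DataFrame(
            columns=["n_in_universe", "n_de_in_set", "fisher_p", "qvalue", "enriched"]
        )
    df = pd.DataFrame(rows, columns=["set_id", "n_in_universe", "n_de_in_set", "fisher_p"])
    df = df.set_index("set_id")
    df["qvalue"] = bh_adjust(df["fisher_p"].to_numpy())
    df["enriched"] = df["qvalue"] < fdr_threshold
    return df


def enriched_sets(enrichment: pd.DataFrame) -> set[str]:
    if enrichment.empty:
        return set()
    return set(enrichment.index[enrichment["enriched"]])


def per_term_correlation(
    de_a: DETable,
    de_b: DETable,
    sets: GeneSetCollection,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Spearman rho of the two units' log2FC vectors restricted to the members
    of each set with >= ``min_genes`` members in the shared universe.  Sets
    below the size threshold are skipped (count logged); zero-variance sets get
    NaN rho."""
    if set(de_a.gene_ids) != set(de_b.gene_ids):
        raise ExparallelError("units must share a gene universe")
    uni = set(de_a.gene_ids)
    lfc_a = de_a.log2fc
    lfc_b = de_b.log2fc
    rows = []
    skipped = 0
    for sid in sorted(sets):
        members = sorted(sets.members(sid) & uni)
        if len(members) < min_genes:
            skipped += 1
            continue
        x = lfc_a.loc[members].to_numpy(float)
        y = lfc_b.loc[members].to_numpy(float)
        if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
            rows.append((sid, len(members), np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((sid, len(members), float(rho), float(p)))
    if skipped:
        log.info("skipped %d sets below the %d-gene threshold", skipped, min_genes)
    return pd.DataFrame(rows, columns=["set_id", "n_genes", "rho", "rho_p"]).set_index("set_id")


def mean_term_correlation(per_pair_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-set mean rho across the available unit pairs (NaN-aware)."""
    if not per_pair_frames:
        raise ExparallelError("no per-pair term correlations supplied")
    rhos = pd.concat([f["rho"] for f in per_pair_frames], axis=1)
    n_pairs = rhos.notna().sum(axis=1)
    out = pd.DataFrame(
        {
            "mean_rho": rhos.mean(axis=1),
            "n_pairs": n_pairs,
            "n_genes": per_pair_frames[0]["n_genes"],
        }
    )
    return out[out["n_pairs"] > 0]


def summarize_term_distributions(
    per_level_frames: dict[str, list[pd.DataFrame]],
    rng: np.random.Generator | None = None,
    bins: int = 20,
) -> dict:
    """Per level: the distribution of the per-set mean rho across unit pairs --
    overall mean, quantiles and histogram counts on [-1, 1].  With ``rng``, a
    single-random-pair variant (one pairwise rho sampled per set) is added as a
    robustness check."""
    if not per_level_frames:
        raise ExparallelError("no levels supplied")
    edges = np.linspace(-1.0, 1.0, bins + 1)
    summary: dict = {"histogram_edges": edges.tolist(), "levels": {}}
    for level, frames in per_level_frames.items():
        mean_df = mean_term_correlation(frames)
        vals = mean_df["mean_rho"].dropna().to_numpy()
        entry = {
            "n_terms": int(len(vals)),
            "mean": float(np.mean(vals)) if len(vals) else float("nan"),
            "quantiles": {
                str(q): float(np.quantile(vals, q)) if len(vals) else float("nan")
                for q in (0.05, 0.25, 0.5, 0.75, 0.95)
            },
            "histogram": np.histogram(vals, bins=edges)[0].tolist(),
        }
        if rng is not None:
            rhos = pd.concat([f["rho"] for f in frames], axis=1)
            picks = []
            for _, row in rhos.iterrows():
                avail = row.dropna().to_numpy()
                if len(avail):
                    picks.append(float(avail[rng.integers(len(avail))]))
            entry["random_pair_mean"] = float(np.mean(picks)) if picks else float("nan")
        summary["levels"][level] = entry
    return summary
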