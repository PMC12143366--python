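"""Core data containers shared by every pipeline stage.

The pipeline starts from a gene x sample integer count table, a sample design
table describing the experimental structure (divergence level, lineage,
replicate/sub-replicate, ancestral vs evolved state), and an optional
gene -> gene-set annotation.  These containers validate the invariants every
downstream stage relies on (unique ids, non-negative integer counts, known
level/state labels) so that stage code can stay free of defensive checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Divergence levels, ordered from lowest to highest genetic divergence.
LEVELS = ("within_population", "between_populations", "between_species")

#: Sample states within one common-garden experiment.
STATES = ("ancestral", "evolved")

DESIGN_COLUMNS = ("sample_id", "level", "lineage_id", "subreplicate_id", "state")


class ExparallelError(ValueError):
    """Base class for input-contract violations."""


@dataclass
class CountMatrix:
    """Integer expression counts, genes as rows, samples as columns.

    ``library_sizes`` are always the exact column sums of ``counts``; they are
    recomputed, never stored, so they cannot drift out of sync.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ExparallelError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ExparallelError(f"duplicate sample ids: {dups}")
        for col, dtype in df.dtypes.items():
            if dtype.kind not in "iu":
                bad = df[col][~df[col].apply(lambda v: float(v).is_integer())]
                gene = bad.index[0] if len(bad) else df.index[0]
                raise ExparallelError(
                    f"non-integer count for gene {gene!r}, sample {col!r}"
                )
        if (df.to_numpy() < 0).any():
            gi, sj = np.argwhere(df.to_numpy() < 0)[0]
            raise ExparallelError(
                f"negative count for gene {df.index[gi]!r}, sample {df.columns[sj]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset(
        self, genes: list[str] | None = None, samples: list[str] | None = None
    ) -> "CountMatrix":
        df = self.counts
        if genes is not None:
            missing = set(genes) - set(df.index)
            if missing:
                raise ExparallelError(f"genes absent from count matrix: {sorted(missing)}")
            df = df.loc[genes]
        if samples is not None:
            missing = set(samples) - set(df.columns)
            if missing:
                raise ExparallelError(f"samples absent from count matrix: {sorted(missing)}")
            df = df[samples]
        return CountMatrix(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class SampleDesign:
    """Per-sample experimental factors.

    One row per sample: divergence level, lineage (evolutionary replicate /
    population / species depending on the level), optional sub-replicate, and
    ancestral vs evolved state.  Level and state strings are normalized to
    lowercase; only the known vocabulary is accepted.  Sub-replicates are only
    legal at the within-population level, where sequencing replicates of one
    evolved replicate exist.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing_cols = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ExparallelError(f"design table missing columns: {missing_cols}")
        df = df[list(DESIGN_COLUMNS)]
        for col in ("sample_id", "level", "lineage_id", "subreplicate_id", "state"):
            df[col] = df[col].fillna("").astype(str).str.strip()
        df["level"] = df["level"].str.lower()
        df["state"] = df["state"].str.lower()

        if df["sample_id"].duplicated().any():
            dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
            raise ExparallelError(f"duplicate sample ids in design: {dups}")
        bad_level = sorted(set(df["level"]) - set(LEVELS))
        if bad_level:
            raise ExparallelError(
                f"unknown divergence level(s) {bad_level}; expected one of {LEVELS}"
            )
        bad_state = sorted(set(df["state"]) - set(STATES))
        if bad_state:
            raise ExparallelError(f"unknown state(s) {bad_state}; expected one of {STATES}")
        for level in sorted(set(df["level"])):
            sub = df[df["level"] == level]
            for state in STATES:
                if not (sub["state"] == state).any():
                    raise ExparallelError(f"level {level!r} has no {state} samples")
        nonwithin = df[(df["level"] != "within_population") & (df["subreplicate_id"] != "")]
        if len(nonwithin):
            raise ExparallelError(
                "sub-replicates are only allowed at the within_population level; "
                f"offending samples: {nonwithin['sample_id'].tolist()}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def levels(self) -> list[str]:
        present = set(self.table["level"])
        return [lv for lv in LEVELS if lv in present]

    def samples_at(self, level: str, state: str | None = None) -> list[str]:
        df = self.table
        mask = df["level"] == level
        if state is not None:
            mask &= df["state"] == state
        return df.loc[mask, "sample_id"].tolist()

    def lineages(self, level: str, state: str = "evolved") -> list[str]:
        df = self.table
        mask = (df["level"] == level) & (df["state"] == state)
        return sorted(set(df.loc[mask, "lineage_id"]))

    def row(self, sample_id: str) -> pd.Series:
        df = self.table
        hit = df[df["sample_id"] == sample_id]
        if hit.empty:
            raise ExparallelError(f"sample {sample_id!r} not in design")
        return hit.iloc[0]


def check_join(counts: CountMatrix, design: SampleDesign) -> None:
    """Verify the counts/design join loses no samples; report set differences."""
    c = set(counts.sample_ids)
    d = set(design.sample_ids)
    if c != d:
        raise ExparallelError(
            "counts and design sample sets differ; "
            f"design-only: {sorted(d - c)}, counts-only: {sorted(c - d)}"
        )


@dataclass
class DETable:
    """Per-gene differential-expression result for one evolved-vs-ancestral
    comparison unit: log2 fold change, raw LRT p-value and BH-FDR q-value."""

    unit_id: str
    table: pd.DataFrame  # index gene_id; columns log2fc, pvalue, qvalue
    level: str | None = None

    def __post_init__(self) -> None:
        df = self.table
        need = {"log2fc", "pvalue", "qvalue"}
        if not need <= set(df.columns):
            raise ExparallelError(f"DETable needs columns {sorted(need)}")
        p = df["pvalue"].to_numpy(float)
        q = df["qvalue"].to_numpy(float)
        if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
            raise ExparallelError("pvalues must lie in [0, 1]")
        if np.isnan(q).any() or (q < 0).any() or (q > 1).any():
            raise ExparallelError("qvalues must lie in [0, 1]")
        if (q < p - 1e-12).any():
            raise ExparallelError("BH qvalues cannot be smaller than raw pvalues")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def significant_genes(self, fdr_threshold: float = 0.05) -> set[str]:
        return set(self.table.index[self.table["qvalue"] < fdr_threshold])

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


@dataclass
class GeneSetCollection:
    """Gene sets (e.g. GO terms) over a declared gene universe."""

    sets: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empties = [sid for sid, members in self.sets.items() if not members]
        if empties:
            raise ExparallelError(f"empty gene sets not allowed: {empties}")
        for sid in self.sets:
            self.names.setdefault(sid, sid)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> frozenset:
        return self.sets[set_id]

    def items(self):
        return self.sets.items()

    def restrict_to_universe(self, universe) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets emptied by the
        intersection (count logged)."""
        uni = frozenset(universe)
        kept: dict[str, frozenset] = {}
        dropped = 0
        for sid, members in self.sets.items():
            inter = members & uni
            if inter:
                kept[sid] = inter
            else:
                dropped += 1
        if dropped:
            log.info("dropped %d gene sets with no members in the universe", dropped)
        return GeneSetCollection(kept, {sid: self.names[sid] for sid in kept})
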