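"""Synthetic evolve-and-resequence transcriptome generator.

Emulates the data structure of a three-common-garden design probing parallel
gene-expression evolution at three divergence levels:

* within population  -- 10 evolved replicates x 3 sub-replicates + 5 shared
  ancestral replicates (all replicates derive from one founder population);
* between populations -- 3 populations x 5 evolved replicates, each population
  with its own 5 reconstituted ancestral replicates;
* between species    -- 2 species x 5 evolved replicates + 5 ancestral each.

Each lineage owns an *adaptive gene set*: a level-wide shared core (fraction
``s`` of the per-lineage set, the operational knob for genetic redundancy)
plus lineage-private genes.  Sharing decreases with divergence
(s_within > s_between_populations > s_between_species), so true parallelism
decreases with divergence by construction.  Counts are negative-binomial with
gene-specific log-normal baselines and gamma dispersions; adaptive genes in
evolved samples have their mean multiplied by 2**log2FC.  Sub-replicates share
their lineage's effects and differ only by counting noise (they do not model
genetic drift, mirroring how phenotyping sub-replicates behave in real data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import LEVELS, CountMatrix, ExparallelError, GeneSetCollection, SampleDesign


@dataclass(frozen=True)
class LevelDesign:
    """Replicate structure of one common-garden experiment."""

    level: str
    n_lineages: int
    n_evolved_samples: int  # samples per lineage (sub-replicates or replicates)
    has_subreplicates: bool
    n_ancestral: int  # ancestral replicates (shared, or per lineage)
    shared_ancestral: bool
    sharing: float  # expected overlap s of adaptive sets between lineage pairs


def default_level_designs() -> tuple[LevelDesign, ...]:
    return (
        LevelDesign("within_population", 10, 3, True, 5, True, 0.6),
        LevelDesign("between_populations", 3, 5, False, 5, False, 0.3),
        LevelDesign("between_species", 2, 5, False, 5, False, 0.1),
    )


@dataclass
class SimulationConfig:
    n_genes: int = 5000
    level_designs: tuple[LevelDesign, ...] = field(default_factory=default_level_designs)
    frac_adaptive: float = 0.05
    effect_mean: float = 1.0
    effect_sd: float = 0.25
    sign_concordance: float = 1.0
    baseline_log_sd: float = 1.2  # sd of ln-scale baseline expression
    dispersion_shape: float = 2.0
    dispersion_rate: float = 40.0  # gamma rate; mean dispersion = shape/rate
    libsize_range: tuple[float, float] = (6.4e6, 15.7e6)
    n_sets: int = 200
    set_size_range: tuple[int, int] = (10, 100)
    frac_adaptive_sets: float = 0.2
    enrichment_boost: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ExparallelError("n_genes must be positive")
        if not 0.0 <= self.frac_adaptive <= 1.0:
            raise ExparallelError("frac_adaptive must lie in [0, 1]")
        if not 0.0 <= self.sign_concordance <= 1.0:
            raise ExparallelError("sign_concordance must lie in [0, 1]")
        if self.effect_sd < 0:
            raise ExparallelError("effect_sd must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ExparallelError("libsize_range bounds must be positive and ordered")
        if self.dispersion_shape <= 0 or self.dispersion_rate <= 0:
            raise ExparallelError("dispersion gamma parameters must be positive")
        for ld in self.level_designs:
            if ld.level not in LEVELS:
                raise ExparallelError(f"unknown level {ld.level!r}")
            if not 0.0 <= ld.sharing <= 1.0:
                raise ExparallelError(f"sharing for {ld.level} must lie in [0, 1]")
            if min(ld.n_lineages, ld.n_evolved_samples, ld.n_ancestral) < 1:
                raise ExparallelError(f"degenerate replicate structure for {ld.level}")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ExparallelError("set_size_range must be ordered and >= 1")
        if hi > self.n_genes:
            raise ExparallelError("set_size_range exceeds n_genes")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Independent, seed-derived streams for the three stochastic stages."""
        ss = np.random.SeedSequence(self.seed)
        truth, counts, sets = ss.spawn(3)
        return {
            "truth": np.random.default_rng(truth),
            "counts": np.random.default_rng(counts),
            "sets": np.random.default_rng(sets),
        }


@dataclass
class LineageTruth:
    genes: np.ndarray  # integer gene indices, adaptive in this lineage
    log2fc: np.ndarray  # matching true effects (signed, log2 scale)


@dataclass
class LevelTruth:
    sharing: float
    core: np.ndarray  # level-wide shared-core gene indices
    lineages: dict[str, LineageTruth]


@dataclass
class AdaptiveTruth:
    """Simulator ground truth: per-lineage adaptive sets and effects, plus the
    per-gene baseline relative expression and NB dispersion."""

    gene_ids: list[str]
    baseline_props: np.ndarray  # relative expression, sums to 1
    dispersions: np.ndarray
    levels: dict[str, LevelTruth]
    adaptive_set_ids: set[str] = field(default_factory=set)

    def adaptive_gene_union(self) -> np.ndarray:
        idx: set[int] = set()
        for lt in self.levels.values():
            for lin in lt.lineages.values():
                idx.update(lin.genes.tolist())
        return np.array(sorted(idx), dtype=int)

    def adaptive_set(self, level: str, lineage: str) -> set[str]:
        lt = self.levels[level].lineages[lineage]
        return {self.gene_ids[i] for i in lt.genes}

    def to_json_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "baseline_props": self.baseline_props.tolist(),
            "dispersions": self.dispersions.tolist(),
            "adaptive_set_ids": sorted(self.adaptive_set_ids),
            "levels": {
                level: {
                    "sharing": lt.sharing,
                    "core": [self.gene_ids[i] for i in lt.core],
                    "lineages": {
                        lin: {
                            "genes": [self.gene_ids[i] for i in t.genes],
                            "log2fc": t.log2fc.tolist(),
                        }
                        for lin, t in lt.lineages.items()
                    },
                }
                for level, lt in self.levels.items()
            },
        }


_LEVEL_PREFIX = {
    "within_population": "wp",
    "between_populations": "bp",
    "between_species": "bs",
}

_LINEAGE_STEM = {
    "within_population": "rep",
    "between_populations": "pop",
    "between_species": "sp",
}


def lineage_ids(ld: LevelDesign) -> list[str]:
    stem = _LINEAGE_STEM[ld.level]
    return [f"{stem}{i + 1:02d}" for i in range(ld.n_lineages)]


def simulate_truth(config: SimulationConfig) -> AdaptiveTruth:
    """Draw the adaptive architecture: per-lineage adaptive gene sets built as a
    level-wide shared core of size round(s*k) plus lineage-private genes, with
    log2-scale effects Normal(effect_mean, effect_sd) and random signs; shared
    genes reuse the core sign with probability ``sign_concordance``."""
    config.validate()
    rng = config.rngs()["truth"]
    n = config.n_genes
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]

    raw = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=n)
    props = raw / raw.sum()
    disp = rng.gamma(shape=config.dispersion_shape, scale=1.0 / config.dispersion_rate, size=n)

    k = round(config.frac_adaptive * n)
    levels: dict[str, LevelTruth] = {}
    for ld in config.level_designs:
        c = round(ld.sharing * k)
        if c > n or k > n:
            raise ExparallelError("adaptive set larger than the gene universe")
        core = np.sort(rng.choice(n, size=c, replace=False))
        core_sign = rng.choice([-1.0, 1.0], size=c)
        remainder = np.setdiff1d(np.arange(n), core)
        lineages: dict[str, LineageTruth] = {}
        for lin in lineage_ids(ld):
            if k - c > 0:
                private = np.sort(rng.choice(remainder, size=k - c, replace=False))
            else:
                private = np.array([], dtype=int)
            genes = np.concatenate([core, private]).astype(int)
            mags = rng.normal(config.effect_mean, config.effect_sd, size=k)
            keep_core = rng.random(c) < config.sign_concordance
            signs_core = np.where(keep_core, core_sign, -core_sign)
            signs_priv = rng.choice([-1.0, 1.0], size=k - c)
            signs = np.concatenate([signs_core, signs_priv])
            lineages[lin] = LineageTruth(genes=genes, log2fc=mags * signs)
        levels[ld.level] = LevelTruth(sharing=ld.sharing, core=core, lineages=lineages)
    return AdaptiveTruth(gene_ids, props, disp, levels)


def _sample_plan(config: SimulationConfig) -> list[dict]:
    """Deterministic sample ordering: levels in canonical order, evolved
    samples per lineage first, then ancestral replicates."""
    plan: list[dict] = []
    for ld in config.level_designs:
        pre = _LEVEL_PREFIX[ld.level]
        for lin in lineage_ids(ld):
            for j in range(ld.n_evolved_samples):
                plan.append(
                    {
                        "sample_id": f"{pre}_{lin}_e{j + 1}",
                        "level": ld.level,
                        "lineage_id": lin,
                        "subreplicate_id": f"s{j + 1}" if ld.has_subreplicates else "",
                        "state": "evolved",
                    }
                )
        if ld.shared_ancestral:
            for j in range(ld.n_ancestral):
                plan.append(
                    {
                        "sample_id": f"{pre}_anc{j + 1}",
                        "level": ld.level,
                        "lineage_id": "founder",
                        "subreplicate_id": "",
                        "state": "ancestral",
                    }
                )
        else:
            for lin in lineage_ids(ld):
                for j in range(ld.n_ancestral):
                    plan.append(
                        {
                            "sample_id": f"{pre}_{lin}_anc{j + 1}",
                            "level": ld.level,
                            "lineage_id": lin,
                            "subreplicate_id": "",
                            "state": "ancestral",
                        }
                    )
    return plan


def simulate_counts(
    config: SimulationConfig, truth: AdaptiveTruth
) -> tuple[CountMatrix, SampleDesign]:
    """Draw NB counts for every sample of every common garden.

    Per sample, count_g ~ NB(mean = libsize * p_g * fold, dispersion phi_g)
    where fold = 2**log2FC for genes adaptive in the owning lineage of an
    evolved sample and 1 otherwise.  Dispersion below 1e-8 falls back to the
    Poisson limit.
    """
    config.validate()
    rng = config.rngs()["counts"]
    plan = _sample_plan(config)
    n = config.n_genes
    lo, hi = config.libsize_range
    libsizes = rng.uniform(lo, hi, size=len(plan))

    cols = {}
    for s, row in enumerate(plan):
        fold = np.ones(n)
        if row["state"] == "evolved":
            lt = truth.levels[row["level"]].lineages[row["lineage_id"]]
            fold[lt.genes] = 2.0 ** lt.log2fc
        mu = libsizes[s] * truth.baseline_props * fold
        phi = truth.dispersions
        counts = np.empty(n, dtype=np.int64)
        poisson_like = phi < 1e-8
        if poisson_like.any():
            counts[poisson_like] = rng.poisson(mu[poisson_like])
        nb = ~poisson_like
        if nb.any():
            r = 1.0 / phi[nb]
            p = r / (r + mu[nb])
            counts[nb] = rng.negative_binomial(r, p)
        cols[row["sample_id"]] = counts

    counts_df = pd.DataFrame(cols, index=truth.gene_ids)
    design = SampleDesign(pd.DataFrame(plan))
    return CountMatrix(counts_df), design


def simulate_gene_sets(config: SimulationConfig, truth: AdaptiveTruth) -> GeneSetCollection:
    """Draw ``n_sets`` gene sets with sizes uniform in ``set_size_range``.  A
    fraction of the sets is designated "adaptive": their members are sampled
    with odds multiplied by ``enrichment_boost`` for genes adaptive in at least
    one lineage.  Designated ids are recorded in ``truth.adaptive_set_ids``."""
    config.validate()
    rng = config.rngs()["sets"]
    n = config.n_genes
    lo, hi = config.set_size_range
    n_adaptive = round(config.frac_adaptive_sets * config.n_sets)
    designated = set(rng.choice(config.n_sets, size=n_adaptive, replace=False).tolist())
    boost_idx = truth.adaptive_gene_union()

    sets: dict[str, frozenset] = {}
    truth.adaptive_set_ids = set()
    for i in range(config.n_sets):
        sid = f"GS{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        weights = np.ones(n)
        if i in designated and len(boost_idx):
            weights[boost_idx] = config.enrichment_boost
            truth.adaptive_set_ids.add(sid)
        members = rng.choice(n, size=size, replace=False, p=weights / weights.sum())
        sets[sid] = frozenset(truth.gene_ids[j] for j in members)
    return GeneSetCollection(sets)


def simulate_study(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleDesign, GeneSetCollection, AdaptiveTruth]:
    """Convenience wrapper: truth, counts, design and gene sets from one config."""
    truth = simulate_truth(config)
    counts, design = simulate_counts(config, truth)
    sets = simulate_gene_sets(config, truth)
    return counts, design, sets, truth


def expected_null_jaccard(n_genes: int, k: int) -> float:
    """Approximate expected Jaccard of two independent uniform k-subsets of n
    genes: E|A&B| = k^2/n and E|A|B| = 2k - k^2/n, whose ratio simplifies to
    k/(2n - k).  Accurate to a few percent for k << n (checked by Monte-Carlo
    in the tests)."""
    if k == 0:
        return 0.0
    return k / (2 * n_genes - k)


def binom(n: int, k: int) -> int:
    return math.comb(n, k)
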