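"""Statistical comparison of parallelism between divergence levels.

Two instruments:

* one-sided Wilcoxon signed-rank tests of the within-level pairwise estimates
  against the scalar summary of a more divergent level (mean of the
  between-populations estimates, or the single between-species estimate), with
  Bonferroni correction over the three level pairs; and
* a k-of-n jackknife that recomputes the mean pairwise statistic over every
  k-subset of the within-population replicates (all C(n, k) subsets,
  lexicographic), equalizing the comparison structure across levels, with an
  empirical tail probability against the reference value.

The Wilcoxon test uses the classical zero-drop (Pratt-drop) convention and
average ranks for tied absolute differences; p-values are exact (conditional on
the observed ranks) for n <= 20 via convolution of the rank generating
function, and use the normal approximation with tie and continuity corrections
above.  At n = 3 the smallest attainable one-sided p is 1/8, which matters when
only three between-populations estimates exist.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

from .model import ExparallelError

log = logging.getLogger(__name__)

EXACT_LIMIT = 20  # largest n for which the exact signed-rank distribution is used


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float, alternative: str) -> float:
    """Exact null distribution of W+ conditional on the observed (possibly
    tied, average) ranks, by convolving the generating function over all 2^n
    sign assignments.  Ranks are multiples of 1/2, so doubling makes them
    integers."""
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(poly)
        shifted[r:] = poly[: total + 1 - r]
        poly = poly + shifted
    poly /= 2.0 ** len(r2)
    w2 = int(np.rint(2.0 * w_plus))
    if alternative == "greater":
        return float(poly[w2:].sum())
    return float(poly[: w2 + 1].sum())


def wilcoxon_signed_rank(values, reference: float = 0.0, alternative: str = "greater") -> float:
    """One-sample, one-sided Wilcoxon signed-rank p-value of ``values`` against
    ``reference``.  Zero differences are dropped; if all differences are zero,
    p = 1 with a warning."""
    if alternative not in ("greater", "less"):
        raise ExparallelError("alternative must be 'greater' or 'less'")
    d = np.asarray(values, dtype=float) - reference
    if np.isnan(d).any():
        raise ExparallelError("NaN values are not allowed")
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        log.warning("all differences are zero; signed-rank p = 1")
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        return _exact_signed_rank_p(ranks, w_plus, alternative)
    mean = n * (n + 1) / 4.0
    # tie correction over groups of tied |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((counts ** 3 - counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w_plus - 0.5 - mean) / sd
        return float(norm.sf(z))
    z = (w_plus + 0.5 - mean) / sd
    return float(norm.cdf(z))


def bonferroni_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """p * m capped at 1; ``m`` defaults to the number of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ExparallelError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


@dataclass
class LevelComparison:
    """One Wilcoxon comparison of parallelism between two divergence levels."""

    statistic: str  # e.g. "jaccard_genes", "rho_genes", "jaccard_go", "rho_go"
    level_pair: tuple[str, str]  # (closer level, more divergent level)
    n_obs: int  # pairwise estimates entering the test
    reference: float  # scalar summary of the more divergent level
    wilcoxon_p: float
    p_bonferroni: float = float("nan")
    consistent: bool = False  # mean of the closer level exceeds the reference


def compare_levels(
    values_by_level: dict[str, list[float]], statistic: str = "statistic"
) -> list[LevelComparison]:
    """The three one-sided comparisons, in the direction "closer level more
    parallel": (1) within-population values vs the mean of the
    between-populations estimates, (2) within-population values vs the single
    between-species estimate, (3) between-populations values vs the
    between-species estimate.  Bonferroni over the three tests."""
    for level in ("within_population", "between_populations", "between_species"):
        if level not in values_by_level or not len(values_by_level[level]):
            raise ExparallelError(f"missing pairwise estimates for level {level!r}")
    within = list(values_by_level["within_population"])
    between = list(values_by_level["between_populations"])
    species = list(values_by_level["between_species"])
    mean_between = float(np.mean(between))
    species_value = float(np.mean(species))  # single estimate in the canonical design

    plan = [
        (("within_population", "between_populations"), within, mean_between),
        (("within_population", "between_species"), within, species_value),
        (("between_populations", "between_species"), between, species_value),
    ]
    out = []
    for pair, values, ref in plan:
        p = wilcoxon_signed_rank(values, ref, alternative="greater")
        out.append(
            LevelComparison(
                statistic=statistic,
                level_pair=pair,
                n_obs=len(values),
                reference=ref,
                wilcoxon_p=p,
                consistent=bool(np.mean(values) > ref),
            )
        )
    adj = bonferroni_adjust([c.wilcoxon_p for c in out])
    for c, pa in zip(out, adj):
        c.p_bonferroni = float(pa)
    return out


def ordering_consistent(values_by_level: dict[str, list[float]]) -> bool:
    """True when mean parallelism is strictly ordered
    within > between-populations > between-species."""
    means = {lv: float(np.mean(vals)) for lv, vals in values_by_level.items()}
    return (
        means["within_population"] > means["between_populations"] > means["between_species"]
    )


@dataclass
class JackknifeResult:
    """All-subsets k-of-n jackknife of a mean pairwise statistic."""

    statistic: str
    k: int
    n_units: int
    n_iterations: int
    estimates: np.ndarray  # one mean pairwise value per k-subset
    reference: float
    empirical_p: float  # fraction of subsets with estimate <= reference
    exceedance_fraction: float = field(default=float("nan"))  # fraction > reference

    def to_json_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "k": self.k,
            "n_units": self.n_units,
            "n_iterations": self.n_iterations,
            "reference": self.reference,
            "empirical_p": self.empirical_p,
            "exceedance_fraction": self.exceedance_fraction,
            "estimates": self.estimates.tolist(),
        }


def jackknife_parallelism(
    pairwise_values: dict[tuple[str, str], float],
    k: int,
    reference: float,
    statistic: str = "statistic",
) -> JackknifeResult:
    """For every k-subset of the units (lexicographic order of sorted unit
    ids), average the C(k, 2) pairwise values of the subset.  ``empirical_p``
    is the fraction of subsets whose estimate is <= reference (the natural tail
    for "the closer level is more parallel"); the complementary exceedance
    fraction (> reference) is reported alongside."""
    units = sorted({u for pair in pairwise_values for u in pair})
    n = len(units)
    if k < 2:
        raise ExparallelError("jackknife subset size k must be >= 2 (subsets need pairs)")
    if k >= n:
        raise ExparallelError(f"jackknife needs k < n units (k={k}, n={n})")
    expected_pairs = {tuple(sorted(p)) for p in combinations(units, 2)}
    missing = expected_pairs - {tuple(sorted(p)) for p in pairwise_values}
    if missing:
        raise ExparallelError(f"missing pairwise values for unit pairs: {sorted(missing)}")
    vals = {tuple(sorted(p)): v for p, v in pairwise_values.items()}

    estimates = []
    for subset in combinations(units, k):
        pair_vals = [vals[pair] for pair in combinations(subset, 2)]
        estimates.append(float(np.mean(pair_vals)))
    estimates = np.array(estimates)
    n_iter = len(estimates)
    assert n_iter == math.comb(n, k)
    return JackknifeResult(
        statistic=statistic,
        k=k,
        n_units=n,
        n_iterations=n_iter,
        estimates=estimates,
        reference=float(reference),
        empirical_p=float((estimates <= reference).mean()),
        exceedance_fraction=float((estimates > reference).mean()),
    )
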