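"""Filtering, normalization and the evolved-vs-ancestral NB GLM test.

One *comparison unit* is a single evolved-vs-ancestral contrast at one
divergence level: a within-population evolved replicate (its sub-replicates vs
the shared ancestral replicates), one population (its evolved replicates vs its
ancestral replicates), or one species.  ``de_test`` fits, per gene, a
negative-binomial GLM with a log link, offset log(effective library size), and
the single evolution factor, and reports the likelihood-ratio test of the
group effect against chi-square(1), the log2 fold change of the fitted group
rates, and BH-FDR q-values.

Dispersion is a shrunk tagwise estimate: a method-of-moments (Pearson-style)
estimate with an n/(n-p) degrees-of-freedom correction, averaged 50/50 with
the common dispersion across genes and floored at 1e-6.  This is a documented,
self-contained stand-in for an edgeR-style pipeline; the downstream parallelism
statistics consume only log2FC / p / q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .model import CountMatrix, DETable, ExparallelError, SampleDesign

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-6
SHRINKAGE_WEIGHT = 0.5  # weight of the tagwise estimate; rest goes to common


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_by_cpm(
    counts: CountMatrix, threshold: float = 1.0, scope: list[str] | None = None
) -> CountMatrix:
    """Keep genes with CPM >= threshold in *every* sample of ``scope``
    (default: all samples).  Row order is preserved."""
    if threshold <= 0:
        raise ExparallelError("CPM threshold must be positive")
    sub = counts.subset(samples=scope) if scope is not None else counts
    lib = sub.library_sizes.to_numpy(float)
    if (lib == 0).any():
        zero = [s for s, l in zip(sub.sample_ids, lib) if l == 0]
        raise ExparallelError(f"zero library size for samples {zero}")
    cpm = sub.counts.to_numpy(float) / lib[None, :] * 1e6
    keep = (cpm >= threshold).all(axis=1)
    if not keep.any():
        raise ExparallelError(
            f"no gene passes CPM >= {threshold} in all scoped samples; "
            "lower the threshold or narrow the scope"
        )
    log.info("CPM filter kept %d / %d genes", int(keep.sum()), counts.n_genes)
    return CountMatrix(counts.counts.loc[keep])


def tmm_norm_factors(counts: CountMatrix) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (30% two-sided M-trim, 5%
    two-sided A-trim, unweighted), computed against the sample whose scaled
    upper quartile is closest to the mean, then rescaled to geometric mean 1."""
    y = counts.counts.to_numpy(float)
    lib = counts.library_sizes.to_numpy(float)
    if (lib == 0).any():
        zero = [s for s, l in zip(counts.sample_ids, lib) if l == 0]
        raise ExparallelError(f"zero library size for samples {zero}")
    scaled_q75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(scaled_q75 - scaled_q75.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        mask = (y[:, j] > 0) & (y[:, ref] > 0)
        if not mask.any():
            continue
        pj = y[mask, j] / lib[j]
        pr = y[mask, ref] / lib[ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        m_lo, m_hi = np.quantile(m, [0.30, 0.70])
        a_lo, a_hi = np.quantile(a, [0.05, 0.95])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if keep.any():
            factors[j] = 2.0 ** m[keep].mean()
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="norm_factor")


@dataclass
class NormalizedExpression:
    """log2 counts-per-million with a prior count, plus the TMM factors used."""

    logcpm: pd.DataFrame  # genes x samples
    norm_factors: pd.Series

    def __post_init__(self) -> None:
        nf = self.norm_factors.to_numpy(float)
        if (nf <= 0).any():
            raise ExparallelError("normalization factors must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.logcpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.logcpm.columns)


def normalize_log_cpm(counts: CountMatrix, prior_count: float = 0.5) -> NormalizedExpression:
    """log2((count + prior) / (effective libsize + 2*prior) * 1e6) with
    effective libsize = library size x TMM factor."""
    factors = tmm_norm_factors(counts)
    eff = counts.library_sizes.to_numpy(float) * factors.to_numpy(float)
    y = counts.counts.to_numpy(float)
    logcpm = np.log2((y + prior_count) / (eff[None, :] + 2.0 * prior_count) * 1e6)
    return NormalizedExpression(
        pd.DataFrame(logcpm, index=counts.gene_ids, columns=counts.sample_ids), factors
    )


# ---------------------------------------------------------------------------
# comparison units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonUnit:
    """One evolved-vs-ancestral contrast."""

    unit_id: str
    level: str
    lineage_id: str
    evolved_samples: tuple[str, ...]
    ancestral_samples: tuple[str, ...]


def build_comparison_units(
    design: SampleDesign, level: str | None = None
) -> list[ComparisonUnit]:
    """One unit per evolved lineage.  The ancestral group is the lineage's own
    ancestral replicates when it has any (between-populations / between-species
    gardens), otherwise the level's shared ancestral replicates
    (within-population garden)."""
    units: list[ComparisonUnit] = []
    levels = [level] if level is not None else design.levels()
    df = design.table
    for lv in levels:
        anc_all = design.samples_at(lv, "ancestral")
        for lin in design.lineages(lv, "evolved"):
            evolved = df.loc[
                (df["level"] == lv) & (df["state"] == "evolved") & (df["lineage_id"] == lin),
                "sample_id",
            ].tolist()
            own_anc = df.loc[
                (df["level"] == lv)
                & (df["state"] == "ancestral")
                & (df["lineage_id"] == lin),
                "sample_id",
            ].tolist()
            anc = own_anc if own_anc else anc_all
            units.append(
                ComparisonUnit(
                    unit_id=f"{lv}:{lin}",
                    level=lv,
                    lineage_id=lin,
                    evolved_samples=tuple(evolved),
                    ancestral_samples=tuple(anc),
                )
            )
    return units


# ---------------------------------------------------------------------------
# NB GLM fitting
# ---------------------------------------------------------------------------

def _fit_nb_rates(y: np.ndarray, offsets: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene MLE of the NB rate mu (mean = mu * offset) at fixed dispersion.

    Newton iteration on the score in log-mu space; the score is strictly
    decreasing in mu so the root is unique.  Genes whose counts sum to zero
    have MLE mu = 0.
    """
    tot = y.sum(axis=1)
    zero = tot == 0
    mu0 = np.where(zero, 1.0, tot / offsets.sum())
    eta = np.log(mu0)
    r = 1.0 / phi
    for _ in range(100):
        lam = np.exp(eta)[:, None] * offsets[None, :]
        t = phi[:, None] * lam
        frac = t / (1.0 + t)
        score = tot - ((y + r[:, None]) * frac).sum(axis=1)
        dscore = -((y + r[:, None]) * frac / (1.0 + t)).sum(axis=1)
        step = np.where(zero, 0.0, score / np.where(dscore == 0, 1.0, dscore))
        step = np.clip(step, -10.0, 10.0)
        eta = eta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.exp(eta)
    mu[zero] = 0.0
    return mu


def _nb_loglik(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, mu: np.ndarray
) -> np.ndarray:
    """NB log-likelihood terms that depend on the mean (constants in y and phi
    are dropped; they cancel in the LRT)."""
    lam = mu[:, None] * offsets[None, :]
    term1 = xlogy(y, lam)  # 0 * log 0 -> 0 for all-zero genes
    term2 = (y + 1.0 / phi[:, None]) * np.log1p(phi[:, None] * lam)
    return (term1 - term2).sum(axis=1)


def _mom_dispersion(y: np.ndarray, offsets: np.ndarray, group_masks: list[np.ndarray]) -> np.ndarray:
    """Shrunk tagwise dispersion: df-corrected method-of-moments estimate per
    gene, averaged 50/50 with the common (mean) dispersion, floored."""
    n = y.shape[1]
    p = len(group_masks)
    mu_hat = np.zeros_like(y, dtype=float)
    for mask in group_masks:
        rate = y[:, mask].sum(axis=1) / offsets[mask].sum()
        mu_hat[:, mask] = rate[:, None] * offsets[None, mask]
    resid2 = (y - mu_hat) ** 2
    denom = (mu_hat ** 2).sum(axis=1)
    num = resid2.sum(axis=1) * n / (n - p) - mu_hat.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tag = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    tag = np.clip(tag, 0.0, None)
    common = float(tag.mean())
    return np.maximum(SHRINKAGE_WEIGHT * tag + (1.0 - SHRINKAGE_WEIGHT) * common, DISPERSION_FLOOR)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1),
    returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ExparallelError("pvalues must be a 1-D vector")
    if np.isnan(p).any():
        raise ExparallelError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ExparallelError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts: CountMatrix,
    design: SampleDesign,
    unit: ComparisonUnit,
    dispersion: float | np.ndarray | None = None,
) -> DETable:
    """Evolved-vs-ancestral NB GLM likelihood-ratio test for one unit.

    ``counts`` should already be CPM-filtered for the unit's experiment.  Pass
    ``dispersion`` to fix the NB dispersion (scalar or per-gene) instead of
    estimating it; values are floored at 1e-12.
    """
    if len(unit.evolved_samples) < 2 or len(unit.ancestral_samples) < 2:
        raise ExparallelError(
            f"unit {unit.unit_id}: both groups need >= 2 samples "
            f"(got {len(unit.evolved_samples)} evolved, {len(unit.ancestral_samples)} ancestral)"
        )
    samples = list(unit.evolved_samples) + list(unit.ancestral_samples)
    missing = set(samples) - set(counts.sample_ids)
    if missing:
        raise ExparallelError(f"unit {unit.unit_id}: samples absent from counts: {sorted(missing)}")
    sub = counts.subset(samples=samples)
    y = sub.counts.to_numpy(float)
    factors = tmm_norm_factors(sub).to_numpy(float)
    offsets = sub.library_sizes.to_numpy(float) * factors

    n_e = len(unit.evolved_samples)
    mask_e = np.zeros(len(samples), dtype=bool)
    mask_e[:n_e] = True
    mask_a = ~mask_e

    if dispersion is None:
        phi = _mom_dispersion(y, offsets, [mask_e, mask_a])
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (sub.n_genes,)).copy()
        phi = np.maximum(phi, 1e-12)

    mu_null = _fit_nb_rates(y, offsets, phi)
    mu_e = _fit_nb_rates(y[:, mask_e], offsets[mask_e], phi)
    mu_a = _fit_nb_rates(y[:, mask_a], offsets[mask_a], phi)

    ll_null = _nb_loglik(y, offsets, phi, mu_null)
    ll_alt = _nb_loglik(y[:, mask_e], offsets[mask_e], phi, mu_e) + _nb_loglik(
        y[:, mask_a], offsets[mask_a], phi, mu_a
    )
    lrt = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)
    pvalue = chi2.sf(lrt, df=1)
    qvalue = bh_adjust(pvalue)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mu_e) - np.log2(mu_a)
    log2fc[(mu_e == 0) & (mu_a == 0)] = 0.0

    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "qvalue": qvalue}, index=sub.gene_ids
    )
    return DETable(unit.unit_id, table, level=unit.level)


def estimate_level_dispersion(
    counts: CountMatrix, design: SampleDesign, level: str
) -> np.ndarray:
    """Shrunk tagwise dispersion estimated once per common-garden experiment,
    using every sample of the level and the full cell structure
    (lineage x state) as the fitted means.

    Estimating on the whole experiment (~24 residual df in the canonical
    designs) rather than on each unit's handful of samples keeps the deep tail
    of the LRT p-values close to chi-square(1); it mirrors how an edgeR-style
    analysis estimates one dispersion per dataset before testing contrasts.
    """
    scope = design.samples_at(level)
    sub = counts.subset(samples=scope)
    factors = tmm_norm_factors(sub).to_numpy(float)
    offsets = sub.library_sizes.to_numpy(float) * factors
    df = design.table
    df = df[df["level"] == level].set_index("sample_id").loc[scope]
    cells = df["lineage_id"] + "/" + df["state"]
    masks = [
        (cells == cell).to_numpy() for cell in sorted(cells.unique())
    ]
    return _mom_dispersion(sub.counts.to_numpy(float), offsets, masks)


def de_tables_for_level(
    counts: CountMatrix,
    design: SampleDesign,
    level: str,
    cpm_threshold: float = 1.0,
) -> list[DETable]:
    """Filter the level's samples by CPM, estimate one dispersion per gene from
    the whole experiment, and run ``de_test`` for every unit.

    Filtering is per experiment (each common garden is an independent dataset),
    so all units at one level share one gene universe and one dispersion
    estimate.
    """
    scope = design.samples_at(level)
    filtered = filter_by_cpm(counts.subset(samples=scope), cpm_threshold)
    phi = estimate_level_dispersion(filtered, design, level)
    return [
        de_test(filtered, design, u, dispersion=phi)
        for u in build_comparison_units(design, level)
    ]
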