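"""Filtering, TMM normalization and the NB GLM LRT, checked against
closed-form and brute-force numeric oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from exparallel import (
    CountMatrix,
    ExparallelError,
    bh_adjust,
    build_comparison_units,
    de_test,
    filter_by_cpm,
    normalize_log_cpm,
    tmm_norm_factors,
)
from exparallel.de import ComparisonUnit

from conftest import make_design_frame
from exparallel.model import SampleDesign


def cm(data: dict, genes: list[str]) -> CountMatrix:
    return CountMatrix(pd.DataFrame(data, index=genes, dtype="int64"))


class TestFilterByCpm:
    def test_zero_count_gene_removed_at_threshold_one(self):
        counts = cm({"s1": [0, 10], "s2": [5, 10]}, ["g1", "g2"])
        kept = filter_by_cpm(counts, 1.0)
        assert kept.gene_ids == ["g2"]

    def test_identity_when_all_pass(self):
        counts = cm({"s1": [10, 20], "s2": [30, 40]}, ["g1", "g2"])
        assert filter_by_cpm(counts, 1.0) == counts

    def test_hand_computed_cpm_boundary(self):
        """Library sizes must be exactly 1e6 and 2e6, so a padding gene
        absorbs the remainder; g2 has CPM 0.5 in s2 and is removed, g3 has a
        zero count, only g1 survives."""
        g1 = [1, 2]
        g2 = [1, 1]
        g3 = [0, 5]
        pad = [10**6 - 2, 2 * 10**6 - 8]
        counts = cm({"s1": [g1[0], g2[0], g3[0], pad[0]], "s2": [g1[1], g2[1], g3[1], pad[1]]},
                    ["g1", "g2", "g3", "pad"])
        assert counts.library_sizes.tolist() == [10**6, 2 * 10**6]
        kept = filter_by_cpm(counts, 1.0)
        assert "g1" in kept.gene_ids and "g2" not in kept.gene_ids and "g3" not in kept.gene_ids

    def test_empty_result_advises(self):
        counts = cm({"s1": [2], "s2": [1]}, ["g1"])
        with pytest.raises(ExparallelError, match="threshold"):
            filter_by_cpm(counts, 1e7)


class TestTMM:
    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.integers(1, 1000, size=50)
        counts = cm({"s1": col, "s2": col}, [f"g{i}" for i in range(50)])
        assert np.allclose(tmm_norm_factors(counts).to_numpy(), 1.0)

    def test_pure_depth_difference_absorbed(self, rng):
        """One sample exactly 2x the other: all M-values are 0, so the trimmed
        mean is 0 and both factors are 1."""
        col = rng.integers(1, 1000, size=50)
        counts = cm({"s1": col, "s2": 2 * col}, [f"g{i}" for i in range(50)])
        assert np.allclose(tmm_norm_factors(counts).to_numpy(), 1.0)

    def test_geometric_mean_one(self, rng):
        counts = cm(
            {f"s{j}": rng.integers(0, 500, size=80) + (j == 0) for j in range(4)},
            [f"g{i}" for i in range(80)],
        )
        f = tmm_norm_factors(counts).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_prior_count_keeps_zero_counts_finite(self):
        counts = cm({"s1": [0, 100], "s2": [5, 95]}, ["g1", "g2"])
        norm = normalize_log_cpm(counts, prior_count=0.5)
        assert np.isfinite(norm.logcpm.to_numpy()).all()

    def test_zero_library_rejected(self):
        counts = cm({"s1": [0, 0], "s2": [1, 2]}, ["g1", "g2"])
        with pytest.raises(ExparallelError, match="zero library"):
            tmm_norm_factors(counts)


def _unit(n_e: int, n_a: int) -> tuple[ComparisonUnit, SampleDesign]:
    rows = [(f"e{i}", "within_population", "rep01", f"s{i}", "evolved") for i in range(n_e)]
    rows += [(f"a{i}", "within_population", "founder", "", "ancestral") for i in range(n_a)]
    design = SampleDesign(make_design_frame(rows))
    unit = ComparisonUnit(
        "within_population:rep01",
        "within_population",
        "rep01",
        tuple(f"e{i}" for i in range(n_e)),
        tuple(f"a{i}" for i in range(n_a)),
    )
    return unit, design


def nb_loglik_scalar(y, offsets, phi, mu):
    """Full NB log-likelihood (oracle; includes all constants)."""
    r = 1.0 / phi
    lam = mu * offsets
    p = r / (r + lam)
    return float(
        np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1) + r * np.log(p) + y * np.log1p(-p))
    )


def lrt_oracle(y_e, y_a, off_e, off_a, phi):
    """Brute-force 1-D numeric MLE per group and for the pooled null."""

    def best(y, off):
        res = minimize_scalar(
            lambda lm: -nb_loglik_scalar(y, off, phi, np.exp(lm)),
            bounds=(-40, 10),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return -res.fun

    ll_alt = best(y_e, off_e) + best(y_a, off_a)
    ll_null = best(np.concatenate([y_e, y_a]), np.concatenate([off_e, off_a]))
    return 2.0 * (ll_alt - ll_null)


class TestDeTest:
    def test_identical_groups_are_null(self):
        unit, design = _unit(2, 2)
        counts = cm(
            {"e0": [50, 7], "e1": [50, 7], "a0": [50, 7], "a1": [50, 7]}, ["g1", "g2"]
        )
        de = de_test(counts, design, unit, dispersion=0.1)
        assert np.allclose(de.table["log2fc"], 0.0)
        assert np.allclose(de.table["pvalue"], 1.0)

    def test_two_vs_two_doubling_matches_numeric_mle_oracle(self):
        """Equal library sizes, counts (10,10) vs (20,20), fixed phi=0.1:
        log2fc is exactly 1 and the LRT matches a brute-force 1-D numeric MLE
        to 1e-6."""
        unit, design = _unit(2, 2)
        pad = 10_000
        counts = cm(
            {"e0": [20, pad], "e1": [20, pad], "a0": [10, pad + 10], "a1": [10, pad + 10]},
            ["g1", "pad"],
        )
        # equal library sizes by construction
        assert len(set(counts.library_sizes)) == 1
        de = de_test(counts, design, unit, dispersion=0.1)
        assert de.table.loc["g1", "log2fc"] == pytest.approx(1.0, abs=1e-9)
        off = counts.library_sizes.to_numpy(float)  # TMM factors ~1 here
        factors = tmm_norm_factors(counts).to_numpy()
        off = off * factors
        expected = lrt_oracle(
            np.array([20.0, 20.0]), np.array([10.0, 10.0]), off[:2], off[2:], 0.1
        )
        got = chi2.isf(de.table.loc["g1", "pvalue"], df=1)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_poisson_limit_matches_closed_form_poisson_lrt(self):
        """As dispersion -> 0 the NB LRT equals the Poisson GLM LRT, whose
        MLEs are closed form (group count sums / offset sums)."""
        rng = np.random.default_rng(42)
        y = rng.poisson(100, size=(30, 6))
        genes = [f"g{i}" for i in range(30)]
        counts = CountMatrix(
            pd.DataFrame(y, index=genes, columns=["e0", "e1", "e2", "a0", "a1", "a2"]).astype(
                "int64"
            )
        )
        unit, design = _unit(3, 3)
        de = de_test(counts, design, unit, dispersion=1e-10)
        factors = tmm_norm_factors(counts).to_numpy()
        off = counts.library_sizes.to_numpy(float) * factors

        def pois_ll(y, off):
            mu = y.sum() / off.sum()
            lam = mu * off
            return np.sum(y * np.log(lam) - lam)

        for i, g in enumerate(genes):
            ye, ya = y[i, :3].astype(float), y[i, 3:].astype(float)
            lrt = 2 * (
                pois_ll(ye, off[:3]) + pois_ll(ya, off[3:]) - pois_ll(y[i].astype(float), off)
            )
            got = chi2.isf(de.table.loc[g, "pvalue"], df=1)
            assert got == pytest.approx(lrt, abs=1e-4)

    def test_group_without_replication_rejected(self):
        unit, design = _unit(1, 2)
        counts = cm({"e0": [1], "a0": [2], "a1": [3]}, ["g1"])
        with pytest.raises(ExparallelError, match=">= 2 samples"):
            de_test(counts, design, unit)

    def test_invariant_to_sample_column_order(self, small_study):
        counts, design, _, _ = small_study
        units = build_comparison_units(design, "between_species")
        u = units[0]
        sub = counts.subset(samples=list(u.evolved_samples) + list(u.ancestral_samples))
        d1 = de_test(sub, design, u, dispersion=0.05)
        shuffled = CountMatrix(sub.counts[list(reversed(sub.sample_ids))])
        d2 = de_test(shuffled, design, u, dispersion=0.05)
        assert np.allclose(d1.table["pvalue"], d2.table["pvalue"], atol=1e-8)
        assert np.allclose(d1.table["log2fc"], d2.table["log2fc"], atol=1e-8)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        # sorted p_i * m / i = (0.04, 0.04, 0.04, 0.04)
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones_stay_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ExparallelError, match="NaN"):
            bh_adjust([0.1, float("nan")])

    def test_q_at_least_p_and_order_restored(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        # order restored: permuting input permutes output identically
        perm = rng.permutation(200)
        assert np.allclose(bh_adjust(p[perm]), q[perm])
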