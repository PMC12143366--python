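"""Generator contracts: sharing structure of adaptive sets, NB moments,
determinism, and gene-set enrichment structure."""

import dataclasses

import numpy as np
import pytest

from exparallel import (
    LevelDesign,
    SimulationConfig,
    jaccard,
    simulate_counts,
    simulate_gene_sets,
    simulate_truth,
)
from exparallel.model import ExparallelError
from exparallel.simulate import expected_null_jaccard


def two_lineage_cfg(sharing: float, n_genes: int = 400, seed: int = 0, **kw) -> SimulationConfig:
    ld = LevelDesign("between_species", 2, 3, False, 3, False, sharing)
    return SimulationConfig(n_genes=n_genes, level_designs=(ld,), seed=seed, **kw)


class TestSimulateTruth:
    def test_full_sharing_gives_identical_adaptive_sets(self):
        truth = simulate_truth(two_lineage_cfg(sharing=1.0))
        a = truth.adaptive_set("between_species", "sp01")
        b = truth.adaptive_set("between_species", "sp02")
        assert a == b
        assert jaccard(a, b) == 1.0

    def test_zero_sharing_matches_null_overlap_expectation(self):
        """With s=0 the cores are empty and two lineages' adaptive sets are
        independent uniform draws; the mean Jaccard over many replicate draws
        must match the k/(n-k) expectation of uniform sampling without
        replacement (Monte-Carlo over 1000 seeds at small n)."""
        n_genes, frac = 200, 0.05
        k = round(frac * n_genes)
        jacs = []
        for seed in range(1000):
            truth = simulate_truth(
                two_lineage_cfg(sharing=0.0, n_genes=n_genes, seed=seed, frac_adaptive=frac)
            )
            jacs.append(
                jaccard(
                    truth.adaptive_set("between_species", "sp01"),
                    truth.adaptive_set("between_species", "sp02"),
                )
            )
        expected = expected_null_jaccard(n_genes, k)
        assert np.mean(jacs) == pytest.approx(expected, rel=0.25)
        assert np.mean(jacs) < 0.1

    def test_no_adaptive_genes_when_fraction_zero(self):
        truth = simulate_truth(two_lineage_cfg(sharing=0.5, frac_adaptive=0.0))
        for lin in ("sp01", "sp02"):
            assert truth.adaptive_set("between_species", lin) == set()

    def test_adaptive_set_size_and_core_overlap(self):
        cfg = two_lineage_cfg(sharing=0.6, n_genes=1000, frac_adaptive=0.1)
        truth = simulate_truth(cfg)
        k = round(0.1 * 1000)
        a = truth.adaptive_set("between_species", "sp01")
        b = truth.adaptive_set("between_species", "sp02")
        assert len(a) == len(b) == k
        assert len(a & b) >= round(0.6 * k)  # the shared core is always common


class TestSimulateCounts:
    def test_poisson_limit_mean_ratio_two(self):
        """effect_sd=0, effect_mean=1, near-zero dispersion, large libraries:
        evolved/ancestral mean count ratio of adaptive genes is ~2."""
        cfg = two_lineage_cfg(sharing=1.0, seed=3, effect_sd=0.0, sign_concordance=1.0)
        truth = simulate_truth(cfg)
        truth.dispersions[:] = 0.0  # Poisson limit
        lt = truth.levels["between_species"].lineages["sp01"]
        lt.log2fc[:] = 1.0
        counts, design = simulate_counts(cfg, truth)
        evo = design.samples_at("between_species", "evolved")
        evo = [s for s in evo if "sp01" in s]
        anc = [s for s in design.samples_at("between_species", "ancestral") if "sp01" in s]
        cpm = counts.counts / counts.library_sizes * 1e6
        genes = [truth.gene_ids[i] for i in lt.genes]
        ratio = cpm.loc[genes, evo].mean(axis=1) / cpm.loc[genes, anc].mean(axis=1)
        assert np.median(ratio) == pytest.approx(2.0, rel=0.1)

    def test_same_seed_bit_identical(self):
        cfg = two_lineage_cfg(sharing=0.5, seed=11)
        t1 = simulate_truth(cfg)
        c1, d1 = simulate_counts(cfg, t1)
        t2 = simulate_truth(cfg)
        c2, d2 = simulate_counts(cfg, t2)
        assert c1.counts.equals(c2.counts)
        assert d1.table.equals(d2.table)

    def test_nb_moments_match(self):
        """Across 10^4 samples of one high-dispersion gene, the empirical
        variance matches mean + phi * mean^2 within 5%."""
        rng = np.random.default_rng(5)
        phi, mu = 0.3, 500.0
        r = 1.0 / phi
        draws = rng.negative_binomial(r, r / (r + mu), size=10_000)
        # oracle: the exact NB parametrization the generator uses
        assert draws.mean() == pytest.approx(mu, rel=0.05)
        assert draws.var() == pytest.approx(mu + phi * mu * mu, rel=0.05)
        # same check through the generator itself: many samples of one gene
        ld = LevelDesign("between_species", 1, 2, False, 2, False, 0.0)
        cfg = SimulationConfig(
            n_genes=10_000, level_designs=(ld,), frac_adaptive=0.0, seed=5,
            dispersion_shape=1e6, dispersion_rate=1e6 / 0.3,  # phi ~= 0.3 for all genes
            baseline_log_sd=0.0, libsize_range=(1e6, 1e6),
        )
        truth = simulate_truth(cfg)
        counts, _ = simulate_counts(cfg, truth)
        col = counts.counts.iloc[:, 0].to_numpy(float)  # iid across genes here
        m = col.mean()
        assert col.var() == pytest.approx(m + 0.3 * m * m, rel=0.05)


class TestSimulateGeneSets:
    def test_boost_one_is_uniform_and_reproducible(self):
        cfg = two_lineage_cfg(sharing=0.5, seed=2, n_sets=20, set_size_range=(5, 10),
                              enrichment_boost=1.0)
        truth = simulate_truth(cfg)
        s1 = simulate_gene_sets(cfg, truth)
        s2 = simulate_gene_sets(cfg, simulate_truth(cfg))
        assert {k: s1.members(k) for k in s1} == {k: s2.members(k) for k in s2}

    def test_extreme_boost_concentrates_adaptive_genes(self):
        cfg = two_lineage_cfg(
            sharing=1.0, n_genes=400, frac_adaptive=0.2, seed=4,
            n_sets=20, set_size_range=(5, 10), enrichment_boost=1e9,
            frac_adaptive_sets=0.5,
        )
        truth = simulate_truth(cfg)
        sets = simulate_gene_sets(cfg, truth)
        adaptive = {truth.gene_ids[i] for i in truth.adaptive_gene_union()}
        assert truth.adaptive_set_ids
        for sid in truth.adaptive_set_ids:
            assert sets.members(sid) <= adaptive

    def test_set_size_exceeding_universe_rejected(self):
        with pytest.raises(ExparallelError, match="set_size_range"):
            two_lineage_cfg(sharing=0.5, n_genes=50, set_size_range=(10, 100)).validate()


def test_invalid_configs_rejected():
    with pytest.raises(ExparallelError):
        dataclasses.replace(SimulationConfig(), frac_adaptive=1.5).validate()
    with pytest.raises(ExparallelError):
        dataclasses.replace(SimulationConfig(), libsize_range=(0.0, 1e6)).validate()
    with pytest.raises(ExparallelError):
        dataclasses.replace(SimulationConfig(), effect_sd=-1.0).validate()
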