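"""Tests for the synthetic autotetraploid population generator."""

import numpy as np
import pytest
from scipy import stats

from polygs import (
    SimulationConfig,
    call_genotypes,
    drop_genes,
    gene_dropping_relationship,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_reads,
)
from polygs.simulate import ReadCountMatrix


# ----------------------------------------------------------------------
# pedigree simulation
# ----------------------------------------------------------------------

class TestSimulatePedigree:
    def test_single_cross_structure(self):
        cfg = SimulationConfig(
            n_founders=2, n_crosses=1, progeny_per_cross=3, seed=1
        )
        ped = simulate_pedigree(cfg)
        assert ped.n == 5
        assert ped.is_founder.sum() == 2
        kids = [(s, d) for s, d in zip(ped.sire[2:], ped.dam[2:])]
        assert len(set(kids)) == 1  # all 3 share the same parent pair

    def test_study_scale_counts(self):
        cfg = SimulationConfig(
            n_founders=146, n_crosses=124, progeny_per_cross=15, seed=2
        )
        ped = simulate_pedigree(cfg)
        assert ped.n == 146 + 124 * 15  # ~1,860 progeny, study scale
        assert (~ped.is_founder).sum() == 1860

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_founders=10, n_crosses=8, progeny_per_cross=4, seed=7)
        p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert p1.ids == p2.ids
        assert np.array_equal(p1.sire, p2.sire) and np.array_equal(p1.dam, p2.dam)

    def test_too_many_crosses_error(self):
        cfg = SimulationConfig(n_founders=3, n_crosses=5, progeny_per_cross=1, seed=1)
        with pytest.raises(ValueError, match="pairs"):
            simulate_pedigree(cfg)

    def test_parents_precede_offspring_multigeneration(self):
        cfg = SimulationConfig(
            n_founders=12, n_crosses=5, progeny_per_cross=4, n_generations=3, seed=3
        )
        ped = simulate_pedigree(cfg)
        known = ped.sire >= 0
        assert np.all(ped.sire[known] < np.arange(ped.n)[known])


# ----------------------------------------------------------------------
# gene dropping (dosages)
# ----------------------------------------------------------------------

class TestDropGenes:
    def test_transmission_matches_hypergeometric(self):
        """Transmitted counts given parent dosage d follow Hyp(4, d, 2).

        Offspring of (sire, unknown dam at frequency ~0) whose sire has
        dosage d receive exactly the sire's gametic count, pooled over
        markers and offspring for a chi-square test at alpha=0.001.
        """
        from polygs.pedigree import Pedigree

        n_off, m = 6, 200_000
        ids = ["s", "d"] + [f"o{i}" for i in range(n_off)]
        ped = Pedigree(
            ids=ids,
            sire=np.array([-1, -1] + [0] * n_off),
            dam=np.array([-1, -1] + [1] * n_off),
            ploidy=4,
        )
        rng = np.random.default_rng(5)
        pop = drop_genes(ped, rng.uniform(0.15, 0.5, m), seed=11)
        sire_d, dam_d = pop.true_dosage[0], pop.true_dosage[1]
        for d in (1, 2, 3):
            cond = (sire_d == d) & (dam_d == 0)  # dam transmits 0 for sure
            draws = pop.true_dosage[2:, cond].ravel()
            assert draws.size > 10_000
            expected = stats.hypergeom.pmf(np.arange(3), 4, d, 2)
            observed = np.bincount(draws, minlength=3)[:3]
            keep = expected > 0
            _, p = stats.chisquare(
                observed[keep], expected[keep] / expected[keep].sum() * draws.size
            )
            assert p > 0.001, f"transmission for d={d} deviates (p={p:.2e})"

    def test_duplex_cross_mean_dosage(self):
        """Sire d=2 x dam d=2 gives offspring mean dosage 2 (hypergeometric means)."""
        from polygs.pedigree import Pedigree

        n_off = 10_000
        ped = Pedigree(
            ids=["s", "d"] + [f"o{i}" for i in range(n_off)],
            sire=np.array([-1, -1] + [0] * n_off),
            dam=np.array([-1, -1] + [1] * n_off),
            ploidy=4,
        )
        pop = drop_genes(ped, np.full(40, 0.5), seed=3)
        both_duplex = (pop.true_dosage[0] == 2) & (pop.true_dosage[1] == 2)
        assert both_duplex.any()
        offspring = pop.true_dosage[2:, both_duplex]
        se = offspring.std() / np.sqrt(offspring.size)
        assert abs(offspring.mean() - 2.0) < 3 * se + 1e-12

    def test_drift_preserves_mean_frequency(self):
        """Random crossing only drifts: mean frequency stays near the founder value."""
        cfg = SimulationConfig(
            n_founders=30,
            n_crosses=20,
            progeny_per_cross=5,
            n_generations=5,
            seed=9,
        )
        ped = simulate_pedigree(cfg)
        m = 400
        pop = drop_genes(ped, np.full(m, 0.3), seed=21)
        final = [i for i in range(ped.n) if ped.ids[i].startswith("G5")]
        freq = pop.true_dosage[final].mean() / 4.0
        # MC error over markers (drift is shared within marker across sibs)
        assert abs(freq - 0.3) < 0.03

    def test_rejects_non_tetraploid(self, toy_pedigree):
        from dataclasses import replace

        ped2 = replace(toy_pedigree, ploidy=2)
        with pytest.raises(ValueError, match="ploidy"):
            drop_genes(ped2, np.array([0.5]), seed=0)

    def test_founder_freq_bounds(self, toy_pedigree):
        with pytest.raises(ValueError, match="strictly inside"):
            drop_genes(toy_pedigree, np.array([0.0, 0.5]), seed=0)


# ----------------------------------------------------------------------
# gene-dropping relationship oracle
# ----------------------------------------------------------------------

class TestGeneDroppingRelationship:
    def test_unrelated_founders_identity(self):
        from polygs.pedigree import Pedigree

        ped = Pedigree(
            ids=["a", "b", "c"],
            sire=np.array([-1, -1, -1]),
            dam=np.array([-1, -1, -1]),
        )
        gd = gene_dropping_relationship(ped, n_replicates=2000, seed=1)
        assert np.allclose(gd.values, np.eye(3))  # founders: exact, no MC noise

    def test_parent_offspring_and_full_sibs(self, toy_pedigree):
        gd = gene_dropping_relationship(toy_pedigree, n_replicates=40_000, seed=2)
        ix = {ind: i for i, ind in enumerate(gd.labels)}
        for pair in (("a", "c"), ("c", "d")):  # parent-offspring; full sibs
            val = gd.values[ix[pair[0]], ix[pair[1]]]
            se = gd.se[ix[pair[0]], ix[pair[1]]]
            assert abs(val - 0.5) < 3 * se + 1e-12

    def test_diploid_mode_parent_offspring(self, toy_pedigree):
        from dataclasses import replace

        gd = gene_dropping_relationship(
            replace(toy_pedigree, ploidy=2), n_replicates=40_000, seed=3, ploidy=2
        )
        assert abs(gd.values[0, 2] - 0.5) < 0.02

    def test_symmetric_nonnegative(self, toy_pedigree):
        gd = gene_dropping_relationship(toy_pedigree, n_replicates=2000, seed=4)
        assert np.allclose(gd.values, gd.values.T)
        assert (gd.values >= 0).all()


# ----------------------------------------------------------------------
# read simulation and genotype calling
# ----------------------------------------------------------------------

class TestSimulateReads:
    def test_heterozygote_ratio_centered(self):
        d = np.full((100, 100), 2)
        reads = simulate_reads(d, mean_depth=40, depth_dispersion=0, seq_error=0, seed=1)
        r = reads.ratio()
        se = np.nanstd(r) / np.sqrt(r.size)
        assert abs(np.nanmean(r) - 0.5) < 3 * se

    def test_error_rate_sets_null_ratio(self):
        d = np.zeros((100, 100), dtype=int)
        reads = simulate_reads(d, mean_depth=60, depth_dispersion=0, seq_error=0.01, seed=2)
        assert abs(np.nanmean(reads.ratio()) - 0.01) < 0.002

    def test_poisson_depth_mean_recovery(self):
        d = np.zeros((100, 1000), dtype=int)
        reads = simulate_reads(d, mean_depth=73, depth_dispersion=0, seed=3)
        assert abs(reads.depth.mean() - 73) / 73 < 0.01

    def test_overdispersed_depth_variance(self):
        d = np.zeros((200, 500), dtype=int)
        phi = 0.2
        reads = simulate_reads(d, mean_depth=73, depth_dispersion=phi, seed=4)
        expected_var = 73 + phi * 73**2
        assert abs(reads.depth.var() / expected_var - 1) < 0.1

    def test_negative_dispersion_error(self):
        with pytest.raises(ValueError, match="dispersion"):
            simulate_reads(np.zeros((2, 2)), depth_dispersion=-1, seed=0)

    def test_ratio_converges_to_quarter_dosage(self):
        d = np.tile(np.arange(5), (200, 1))
        reads = simulate_reads(d, mean_depth=10_000, depth_dispersion=0, seq_error=0, seed=5)
        assert np.nanmax(np.abs(reads.ratio() - d / 4.0)) < 0.02


class TestCallGenotypes:
    def test_naive_round_example(self):
        reads = ReadCountMatrix(alt=np.array([[74]]), ref=np.array([[26]]))
        assert call_genotypes(reads, ploidy=4, method="naive_round")[0, 0] == 3

    def test_zero_depth_is_missing(self):
        reads = ReadCountMatrix(alt=np.array([[0]]), ref=np.array([[0]]))
        for method in ("naive_round", "binomial_map"):
            assert np.isnan(call_genotypes(reads, ploidy=4, method=method)[0, 0])

    def test_high_depth_consistency(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 5, size=(100, 100))
        reads = simulate_reads(d, mean_depth=500, depth_dispersion=0, seq_error=0, seed=7)
        called = call_genotypes(reads, ploidy=4, method="binomial_map", seq_error=1e-6)
        obs = ~np.isnan(called)
        assert np.mean(called[obs] != d[obs]) < 0.001

    def test_low_depth_heterozygote_miscall_enumeration(self):
        """At depth 5, MAP calling must miscall simplex heterozygotes often.

        Exact oracle: enumerate alt counts 0..5 under Binomial(5, 1/4)
        and sum the probability of counts whose MAP dosage is not 1.
        """
        depth, e = 5, 0.005
        pi = lambda d: d / 4 * (1 - e) + (1 - d / 4) * e
        miscall_prob = 0.0
        for alt in range(depth + 1):
            liks = [
                stats.binom.pmf(alt, depth, pi(d)) for d in range(5)
            ]
            if int(np.argmax(liks)) != 1:
                miscall_prob += stats.binom.pmf(alt, depth, pi(1))
        assert miscall_prob > 0.3  # the exact enumeration says calling must fail often

        # empirical agreement with the enumeration
        d = np.ones((200, 200), dtype=int)
        alt = np.random.default_rng(8).binomial(depth, pi(1), size=d.shape)
        reads = ReadCountMatrix(alt=alt, ref=depth - alt)
        called = call_genotypes(reads, ploidy=4, method="binomial_map", seq_error=e)
        rate = np.mean(called != 1)
        assert abs(rate - miscall_prob) < 0.02

    def test_unknown_method_error(self):
        reads = ReadCountMatrix(alt=np.array([[1]]), ref=np.array([[1]]))
        with pytest.raises(ValueError, match="method"):
            call_genotypes(reads, ploidy=4, method="magic")


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

class TestSimulatePhenotypes:
    def _pop(self, cfg):
        ped = simulate_pedigree(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        return drop_genes(ped, rng.uniform(0.2, 0.8, cfg.n_markers), seed=cfg.seed + 2)

    def test_degenerate_model_exact(self):
        cfg = SimulationConfig(
            n_founders=6,
            n_crosses=3,
            progeny_per_cross=2,
            n_markers=20,
            n_years=2,
            year_effects=(0.0, 1.0),
            mu=5.0,
            field_dims=(4, 4),
            variance_components={k: 0.0 for k in ("additive", "row", "column", "gxe", "residual")},
            seed=31,
        )
        ph = simulate_phenotypes(self._pop(cfg), cfg)
        assert np.allclose(ph.loc[ph.year == 1, "value"], 5.0)
        assert np.allclose(ph.loc[ph.year == 2, "value"], 6.0)

    def test_variance_decomposition(self):
        """Realized component variances within 10% of the configured values."""
        cfg = SimulationConfig(
            n_founders=60,
            n_crosses=55,
            progeny_per_cross=50,
            n_markers=200,
            n_years=2,
            field_dims=(60, 50),
            variance_components={
                "additive": 1.0,
                "row": 0.5,
                "column": 0.5,
                "gxe": 0.8,
                "residual": 2.0,
            },
            seed=33,
        )
        pop = self._pop(cfg)
        ph = simulate_phenotypes(pop, cfg, seed=99)
        assert len(ph) >= 5000
        # additive: exactly rescaled true bv
        a = pop.true_bv / pop.true_bv.std()
        assert abs(np.var(a) - 1.0) < 1e-9
        total_expected = sum(cfg.variance_components.values())
        assert abs(ph["value"].var() / total_expected - 1) < 0.1

    def test_h2_in_study_range_by_default(self):
        cfg = SimulationConfig()
        vc = cfg.variance_components
        h2 = vc["additive"] / sum(vc.values())
        assert 0.15 <= h2 <= 0.57

    def test_deterministic(self, small_population, small_config):
        pop, _, _ = small_population
        ph1 = simulate_phenotypes(pop, small_config, seed=5)
        ph2 = simulate_phenotypes(pop, small_config, seed=5)
        assert ph1.equals(ph2)

    def test_field_too_small(self):
        cfg = SimulationConfig(
            n_founders=10,
            n_crosses=5,
            progeny_per_cross=4,
            n_markers=10,
            field_dims=(2, 2),
            seed=1,
        )
        with pytest.raises(ValueError, match="field"):
            simulate_phenotypes(self._pop(cfg), cfg)
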