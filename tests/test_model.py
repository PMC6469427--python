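"""Tests for the Bayesian mixed model: design, Gibbs sampler, DIC, eBLUEs."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from polygs import (
    ModelSpec,
    build_design,
    fit_eblue,
    fit_gibbs,
    gmatrix,
    heritability,
    identity_matrix,
)
from polygs.model import ModelError, conditional_dic


def hwe_population(seed, n=300, m=800, h2=0.5):
    """Marker data plus y = a + e at realized heritability h2."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m)
    dos = rng.binomial(4, p, size=(n, m)).astype(float)
    labels = [f"g{i}" for i in range(n)]
    G = gmatrix(dos, "G4", labels=labels)
    W = dos - dos.mean(0)
    a = W @ rng.standard_normal(m)
    a = a / a.std() * np.sqrt(h2)
    y = a + rng.standard_normal(n) * np.sqrt(1 - h2)
    ph = pd.DataFrame(
        {"genotype": labels, "year": 1, "row": 1, "column": 1, "trait": "t", "value": y}
    )
    return G, ph, a


def quick_spec(K, seed=0, **kw):
    defaults = dict(
        trait="t",
        relationship=K,
        n_iter=2000,
        burn_in=500,
        thin=3,
        include_row=False,
        include_column=False,
        seed=seed,
    )
    defaults.update(kw)
    return ModelSpec(**defaults)


class TestBuildDesign:
    def test_two_year_dimensions(self, tidy_phenotypes):
        K = identity_matrix(["g1", "g2", "g3"])
        design = build_design(tidy_phenotypes, ModelSpec(trait="t", relationship=K))
        assert design.n_records == 6
        assert design.fixed.shape == (6, 2)  # intercept + one year contrast
        names = [b.name for b in design.blocks]
        assert "gxe" in names
        gxe = design.blocks[names.index("gxe")]
        assert gxe.q == 6  # 3 genotypes x 2 years
        assert design.geno_index.shape == (6,)

    def test_single_year_drops_year_terms(self, tidy_phenotypes):
        one = tidy_phenotypes[tidy_phenotypes.year == 1]
        K = identity_matrix(["g1", "g2", "g3"])
        design = build_design(one, ModelSpec(trait="t", relationship=K))
        assert design.fixed.shape[1] == 1  # intercept only
        assert all(b.name != "gxe" for b in design.blocks)

    def test_nesting_row_col_in_year(self, tidy_phenotypes):
        K = identity_matrix(["g1", "g2", "g3"])
        design = build_design(tidy_phenotypes, ModelSpec(trait="t", relationship=K))
        row = next(b for b in design.blocks if b.name == "row")
        assert row.q == 6  # 3 rows x 2 years when nested

    def test_unknown_genotype_error(self, tidy_phenotypes):
        K = identity_matrix(["g1", "g2"])  # g3 missing
        with pytest.raises(ModelError, match="g3"):
            build_design(tidy_phenotypes, ModelSpec(trait="t", relationship=K))

    def test_non_finite_y_error(self, tidy_phenotypes):
        bad = tidy_phenotypes.copy()
        bad.loc[0, "value"] = np.nan
        K = identity_matrix(["g1", "g2", "g3"])
        with pytest.raises(ModelError, match="finite"):
            build_design(bad, ModelSpec(trait="t", relationship=K))


class TestFitGibbs:
    def test_intercept_recovery(self):
        rng = np.random.default_rng(1)
        n = 200
        labels = [f"g{i}" for i in range(n)]
        y = 7.0 + rng.standard_normal(n)
        ph = pd.DataFrame(
            {"genotype": labels, "year": 1, "row": 1, "column": 1, "trait": "t", "value": y}
        )
        K = identity_matrix(labels)
        res = fit_gibbs(build_design(ph, quick_spec(K, seed=2)))
        assert res.fixed_mean[0] == pytest.approx(y.mean(), abs=0.3)

    def test_h2_recovery_single_replicate(self):
        G, ph, _ = hwe_population(seed=11, n=400, m=1200, h2=0.5)
        spec = quick_spec(G, seed=3, n_iter=4000, burn_in=1000, thin=5)
        res = fit_gibbs(build_design(ph, spec))
        assert abs(res.h2_mean - 0.5) < 0.1

    def test_permuted_labels_destroy_signal(self):
        """Breaking the genotype-relationship link collapses the h2
        estimate to its no-signal level (the informative default prior
        keeps that level above zero)."""
        G, ph, _ = hwe_population(seed=12, n=300, m=800, h2=0.6)
        rng = np.random.default_rng(4)
        ph_perm = ph.assign(genotype=rng.permutation(ph["genotype"].to_numpy()))
        res_perm = fit_gibbs(build_design(ph_perm, quick_spec(G, seed=5)))
        res_true = fit_gibbs(build_design(ph, quick_spec(G, seed=5)))
        assert res_perm.h2_mean < res_true.h2_mean - 0.2
        assert res_perm.h2_mean < 0.35

    def test_deterministic_under_seed(self):
        G, ph, _ = hwe_population(seed=13, n=100, m=200)
        r1 = fit_gibbs(build_design(ph, quick_spec(G, seed=6)))
        r2 = fit_gibbs(build_design(ph, quick_spec(G, seed=6)))
        assert np.array_equal(r1.h2_chain, r2.h2_chain)
        assert r1.bv.equals(r2.bv)

    def test_scaling_relationship_matrix_exact_equivariance(self):
        """Scaling K by c with a correspondingly scaled additive prior
        divides the sigma_a^2 chain by exactly c and leaves predicted
        breeding values unchanged (chains are pathwise equivariant)."""
        from polygs.kinship import RelationshipMatrix

        G, ph, _ = hwe_population(seed=14, n=120, m=400, h2=0.5)
        c = 4.0
        Gc = RelationshipMatrix(G.labels, G.values * c, source="G4")
        vary = float(ph["value"].var())
        s0a = 0.5 * vary * (5.0 + 2) / 5.0  # the default mode-matched scale
        r1 = fit_gibbs(
            build_design(ph, quick_spec(G, seed=7, prior_scales={"additive": s0a}))
        )
        r2 = fit_gibbs(
            build_design(ph, quick_spec(Gc, seed=7, prior_scales={"additive": s0a / c}))
        )
        assert np.allclose(
            r1.var_chains["additive"], c * r2.var_chains["additive"], rtol=1e-8
        )
        assert np.allclose(r1.var_chains["residual"], r2.var_chains["residual"])
        assert np.allclose(r1.bv.to_numpy(), r2.bv.to_numpy(), atol=1e-8)

    def test_scaling_direction_under_default_prior(self):
        """Under the default (fixed-scale) prior the estimated additive
        variance still moves inversely with the matrix scale and the BV
        ranking is preserved."""
        from polygs.kinship import RelationshipMatrix

        G, ph, _ = hwe_population(seed=14, n=200, m=600, h2=0.5)
        c = 4.0
        Gc = RelationshipMatrix(G.labels, G.values * c, source="G4")
        r1 = fit_gibbs(build_design(ph, quick_spec(G, seed=7, n_iter=4000, burn_in=1000)))
        r2 = fit_gibbs(build_design(ph, quick_spec(Gc, seed=7, n_iter=4000, burn_in=1000)))
        ratio = r1.var_means["additive"] / r2.var_means["additive"]
        assert 1.5 < ratio <= c * 1.2
        rank_corr = pd.Series(r1.bv).corr(pd.Series(r2.bv), method="spearman")
        assert rank_corr > 0.98

    def test_identity_matches_ridge_regression(self):
        """With K = I the posterior-mean BVs match ridge shrinkage at the
        posterior-mean variance ratio."""
        rng = np.random.default_rng(15)
        n = 150
        labels = [f"g{i}" for i in range(n)]
        a = rng.standard_normal(n)
        y = a + rng.standard_normal(n) * 0.5
        ph = pd.DataFrame(
            {"genotype": labels, "year": 1, "row": 1, "column": 1, "trait": "t", "value": y}
        )
        K = identity_matrix(labels)
        res = fit_gibbs(
            build_design(ph, quick_spec(K, seed=8, n_iter=6000, burn_in=1000, thin=5))
        )
        lam = res.var_means["residual"] / res.var_means["additive"]
        mu = res.fixed_mean[0]
        ridge = (y - mu) / (1.0 + lam)
        assert np.corrcoef(res.bv.to_numpy(), ridge)[0, 1] > 0.99

    def test_chain_length_contract(self):
        G, ph, _ = hwe_population(seed=16, n=60, m=100)
        res = fit_gibbs(build_design(ph, quick_spec(G, seed=9, n_iter=1500, burn_in=500, thin=3)))
        assert res.n_draws == len(res.h2_chain) == 334
        assert all(len(c) == 334 for c in res.var_chains.values())
        assert (res.var_chains["additive"] > 0).all()


class TestHeritabilityAndDic:
    def test_h2_definition_on_chains(self):
        G, ph, _ = hwe_population(seed=17, n=60, m=100)
        res = fit_gibbs(build_design(ph, quick_spec(G, seed=10)))
        chain, mean = heritability(res)
        total = sum(res.var_chains.values())
        assert np.allclose(chain, res.var_chains["additive"] / total)
        assert 0 < mean < 1
        assert ((chain > 0) & (chain < 1)).all()

    def test_variance_ratio_arithmetic(self):
        """The heritability definition on fixed components: additive over
        the sum of all variance components."""
        sa, se, sc_sr = 0.344, 0.206, 0.093
        h2 = sa / (sa + se + sc_sr)
        assert h2 == pytest.approx(0.535, abs=5e-4)

    def test_degenerate_chain_pd_zero(self):
        d = 123.4
        dic_val, p_d = conditional_dic(d, d)
        assert p_d == 0.0 and dic_val == d

    def test_dic_finite_and_pd_positive(self):
        G, ph, _ = hwe_population(seed=18, n=100, m=300, h2=0.5)
        res = fit_gibbs(build_design(ph, quick_spec(G, seed=11)))
        assert np.isfinite(res.dic)
        assert res.p_d > 0

    def test_noise_term_does_not_improve_fit(self):
        """Adding a pure-noise random block cannot reduce mean deviance
        beyond sampling noise."""
        rng = np.random.default_rng(19)
        n = 200
        labels = [f"g{i}" for i in range(n)]
        y = rng.standard_normal(n)
        ph = pd.DataFrame(
            {
                "genotype": labels,
                "year": 1,
                "row": rng.integers(1, 5, n),  # noise factor: no real effect
                "column": 1,
                "trait": "t",
                "value": y,
            }
        )
        K = identity_matrix(labels)
        res_plain = fit_gibbs(build_design(ph, quick_spec(K, seed=12)))
        res_rows = fit_gibbs(
            build_design(ph, quick_spec(K, seed=12, include_row=True))
        )
        assert res_rows.dbar > res_plain.dbar - 10.0


class TestFitEblue:
    def test_exact_on_noiseless_balanced_design(self, tidy_phenotypes):
        # rows in the fixture coincide with genotypes, so exclude the
        # field factors to keep genotype means estimable
        eb = fit_eblue(
            tidy_phenotypes,
            ModelSpec(trait="t", include_row=False, include_column=False),
        )
        # y = 10 + year(0,1) + geno(0,1,2); LSMean averages years
        assert eb["g1"] == pytest.approx(10.5)
        assert eb["g2"] == pytest.approx(11.5)
        assert eb["g3"] == pytest.approx(12.5)

    def test_within_year_adjustment_for_unbalanced_genotype(self):
        """A genotype observed only in year 1 is adjusted by the year
        contrast, not given its raw mean."""
        rows = []
        for year, yeff in ((1, 0.0), (2, 2.0)):
            for g, geff in (("a", 0.0), ("b", 1.0)):
                rows.append(
                    dict(genotype=g, year=year, row=1, column=1, trait="t",
                         value=5.0 + yeff + geff)
                )
        rows.append(dict(genotype="c", year=1, row=1, column=1, trait="t", value=7.0))
        ph = pd.DataFrame(rows)
        eb = fit_eblue(ph, ModelSpec(trait="t", include_row=False, include_column=False))
        # exact decomposition: c's value 7 = mu + c_eff with year-1 effect 0;
        # LSMean adds the average year effect (0+2)/2 = 1
        assert eb["c"] == pytest.approx(8.0)
        assert eb["b"] - eb["a"] == pytest.approx(1.0)
        raw_mean = 7.0
        assert eb["c"] != pytest.approx(raw_mean)

    def test_shift_equivariance(self, tidy_phenotypes):
        eb1 = fit_eblue(tidy_phenotypes)
        shifted = tidy_phenotypes.assign(value=tidy_phenotypes["value"] + 3.0)
        eb2 = fit_eblue(shifted)
        assert np.allclose(eb2.to_numpy() - eb1.to_numpy(), 3.0)

    def test_single_record_genotypes_return_observed_values(self):
        ph = pd.DataFrame(
            {
                "genotype": ["x", "y", "z"],
                "year": 1,
                "row": 1,
                "column": 1,
                "trait": "t",
                "value": [1.0, 2.0, 4.0],
            }
        )
        eb = fit_eblue(ph, ModelSpec(include_row=False, include_column=False))
        assert np.allclose(eb[["x", "y", "z"]].to_numpy(), [1.0, 2.0, 4.0])
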