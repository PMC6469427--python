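"""Study-condition validation benchmarks.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stage(s) at a desk-scale version of the study conditions, and
returns the summary quantities the package's validation suite asserts
against.  They are deliberately part of the library so the test suite
and the reproduction script exercise exactly the same computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import cross_validate, fit_eblue, make_folds
from .genotypes import (
    GenotypeData,
    impute_missing,
    observed_heterozygosity,
    relative_heterozygosity,
)
from .kinship import amatrix_diploid, amatrix_tetraploid, gmatrix
from .model import ModelSpec, build_design, fit_gibbs
from .simulate import (
    SimulationConfig,
    call_genotypes,
    drop_genes,
    gene_dropping_relationship,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_reads,
)

__all__ = [
    "pedigree_oracle_benchmark",
    "gmatrix_benchmark",
    "h2_recovery_benchmark",
    "cv_ordering_benchmark",
    "heterozygosity_benchmark",
]


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def pedigree_oracle_benchmark(seed: int = 1, n_replicates: int = 100_000) -> dict:
    """A4/A2 recursions vs the gene-dropping IBD oracle.

    A random 60-individual, 4-generation pedigree (12 founders, 4
    crosses x 3 progeny per generation); the oracle runs at
    ``n_replicates`` gene drops.  Reports, per matrix, the fraction of
    entries within 3 Monte-Carlo SEs, the maximum deviation in SE
    units, and the maximum deviation on entries the oracle fixes
    exactly (founder pairs; must be zero).
    """
    s_ped, s_gd4, s_gd2 = _seeds(seed, 3)
    cfg = SimulationConfig(
        n_founders=12, n_crosses=4, progeny_per_cross=3, n_generations=4, seed=s_ped
    )
    ped = simulate_pedigree(cfg)
    out = {"n_individuals": ped.n}
    for tag, amatrix, ploidy, s in (
        ("a4", amatrix_tetraploid, 4, s_gd4),
        ("a2", amatrix_diploid, 2, s_gd2),
    ):
        A = amatrix(ped)
        gd = gene_dropping_relationship(ped, n_replicates=n_replicates, seed=s, ploidy=ploidy)
        dev = np.abs(A.values - gd.values)
        stochastic = gd.se > 0
        z = dev[stochastic] / gd.se[stochastic]
        out[f"{tag}_pct_within_3se"] = float(100.0 * np.mean(z <= 3.0))
        out[f"{tag}_max_z"] = float(z.max())
        out[f"{tag}_max_abs_dev"] = float(dev.max())
        out[f"{tag}_exact_entry_max_dev"] = float(dev[~stochastic].max())
    return out


def gmatrix_benchmark(seed: int = 1, n: int = 500, m: int = 5000) -> dict:
    """VanRaden scaling: mean G4 diagonal under Hardy-Weinberg dosages,
    plus the exactness of the hand-computable 3x2 example."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m)
    dosage = rng.binomial(4, p, size=(n, m)).astype(float)
    G = gmatrix(dosage, "G4")
    toy = gmatrix(np.array([[0.0, 4.0], [2.0, 2.0], [4.0, 0.0]]), "G4")
    expected = np.array([[4.0, 0.0, -4.0], [0.0, 0.0, 0.0], [-4.0, 0.0, 4.0]])
    return {
        "g4_mean_diagonal": float(np.diag(G.values).mean()),
        "g4_toy_max_abs_error": float(np.abs(toy.values - expected).max()),
        "n": n,
        "m": m,
    }


def _family_population(seed: int, variance_components: dict, n_markers: int,
                       n_founders=45, n_crosses=35, progeny=13, mean_depth=None):
    """One biparental-cross population under the generator's single-year
    study conditions (founders + progeny all genotyped and phenotyped)."""
    s_ped, s_freq, s_drop, s_reads, s_phen = _seeds(seed, 5)
    cfg = SimulationConfig(
        n_founders=n_founders,
        n_crosses=n_crosses,
        progeny_per_cross=progeny,
        n_markers=n_markers,
        n_years=1,
        field_dims=(40, 40),
        variance_components=variance_components,
        seed=s_ped,
    )
    ped = simulate_pedigree(cfg)
    freqs = np.random.default_rng(s_freq).uniform(0.1, 0.9, n_markers)
    pop = drop_genes(ped, freqs, seed=s_drop)
    reads = None
    if mean_depth is not None:
        reads = simulate_reads(
            pop.true_dosage, mean_depth=mean_depth, depth_dispersion=0.2,
            seq_error=0.005, seed=s_reads,
        )
    phenotypes = simulate_phenotypes(pop, cfg, seed=s_phen)
    return pop, reads, phenotypes


def h2_recovery_benchmark(
    seed: int = 1,
    n_replicates: int = 20,
    n_iter: int = 6000,
    burn_in: int = 1000,
    thin: int = 5,
) -> dict:
    """Posterior-mean heritability recovery at true h2 = 0.3.

    Twenty replicate populations of 500 individuals (45 founders, 35
    crosses x 13), 2,000 markers, single year, variance components
    (additive, row, column, residual) = (0.3, 0.1, 0.1, 0.5).  The
    G4 matrix is built from the true dosages and the full model
    (including the field terms) is fit with scaled-down chains.
    """
    vc = {"additive": 0.3, "row": 0.1, "column": 0.1, "gxe": 0.0, "residual": 0.5}
    estimates = []
    for rep_seed in _seeds(seed, n_replicates):
        pop, _, ph = _family_population(rep_seed, vc, n_markers=2000)
        G = gmatrix(pop.true_dosage.astype(float), "G4", labels=pop.pedigree.ids)
        spec = ModelSpec(
            trait="sim_trait", relationship=G, n_iter=n_iter, burn_in=burn_in,
            thin=thin, seed=rep_seed,
        )
        estimates.append(fit_gibbs(build_design(ph, spec)).h2_mean)
    return {
        "h2_true": 0.3,
        "h2_posterior_means": estimates,
        "h2_mean": float(np.mean(estimates)),
        "h2_sd": float(np.std(estimates, ddof=1)),
        "n": 500,
    }


def cv_ordering_benchmark(
    seed: int = 1,
    n_replicates: int = 5,
    n_markers: int = 400,
    depth: float = 5.0,
    k: int = 10,
) -> dict:
    """Predictive ability under genotype miscalling at low depth.

    Each replicate simulates a 210-individual population, sequences it
    at ``depth`` (5x: severe dosage miscalling), and cross-validates
    three marker matrices on the same folds: G4 from the true dosages,
    G4 from the MAP-called dosages, and Gr from the raw read ratios.
    Reports the per-matrix mean predictive ability across replicates
    and the average per-entry miscall rate.
    """
    vc = {"additive": 1.0, "row": 0.0, "column": 0.0, "gxe": 0.0, "residual": 1.5}
    pa = {"g4_true": [], "g4_called": [], "gr": []}
    miscall = []
    for rep_seed in _seeds(seed, n_replicates):
        pop, reads, ph = _family_population(
            rep_seed, vc, n_markers=n_markers,
            n_founders=30, n_crosses=20, progeny=9, mean_depth=depth,
        )
        ids = pop.pedigree.ids
        called = call_genotypes(reads, ploidy=4, method="binomial_map")
        miscall.append(float(np.nanmean(called != pop.true_dosage)))
        matrices = {
            "g4_true": gmatrix(pop.true_dosage.astype(float), "G4", labels=ids),
            "g4_called": gmatrix(impute_missing(called), "G4", labels=ids),
            "gr": gmatrix(impute_missing(reads.ratio()), "Gr", labels=ids),
        }
        folds = make_folds(sorted(ph["genotype"].unique()), k=k, seed=rep_seed)
        eblues = fit_eblue(ph)
        for name, K in matrices.items():
            spec = ModelSpec(
                trait="sim_trait", relationship=K, n_iter=1500, burn_in=500,
                thin=3, include_row=False, include_column=False, seed=rep_seed,
            )
            cv = cross_validate(
                ph, K, spec, k=k, seed=rep_seed, folds=folds, eblues=eblues
            )
            pa[name].append(cv.pa_mean)
    return {
        "pa_g4_true": float(np.mean(pa["g4_true"])),
        "pa_g4_called": float(np.mean(pa["g4_called"])),
        "pa_gr": float(np.mean(pa["gr"])),
        "pa_gr_minus_g4_called": float(np.mean(pa["gr"]) - np.mean(pa["g4_called"])),
        "pa_g4_true_minus_g4_called": float(
            np.mean(pa["g4_true"]) - np.mean(pa["g4_called"])
        ),
        "miscall_rate": float(np.mean(miscall)),
        "n_replicates": n_replicates,
    }


def heterozygosity_benchmark(seed: int = 1, n_markers: int = 2000) -> dict:
    """Observed heterozygosity across the three parameterizations on one
    synthetic population sequenced at the default 73x depth."""
    vc = {"additive": 1.0, "row": 0.15, "column": 0.15, "gxe": 0.0, "residual": 2.0}
    pop, reads, _ = _family_population(
        seed, vc, n_markers=n_markers, n_founders=30, n_crosses=20, progeny=9,
        mean_depth=73.0,
    )
    ids = pop.pedigree.ids
    markers = pd.DataFrame(index=[f"m{j}" for j in range(n_markers)])
    called4 = call_genotypes(reads, ploidy=4, method="binomial_map")
    called2 = call_genotypes(reads, ploidy=2, method="binomial_map")
    data4 = GenotypeData(individuals=ids, markers=markers, dosage=called4, ploidy_code=4)
    data2 = GenotypeData(individuals=ids, markers=markers, dosage=called2, ploidy_code=2)
    datar = GenotypeData(
        individuals=ids, markers=markers, ratio=reads.ratio(), ploidy_code="ratio"
    )
    h4 = observed_heterozygosity(data4).overall
    h2 = observed_heterozygosity(data2).overall
    hr = observed_heterozygosity(datar).overall
    return {
        "het_diploid": h2,
        "het_tetraploid": h4,
        "het_continuous": hr,
        "het_continuous_vs_diploid_pct": relative_heterozygosity(hr, h2),
        "het_continuous_vs_tetraploid_pct": relative_heterozygosity(hr, h4),
    }
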