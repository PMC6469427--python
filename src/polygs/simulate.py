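"""Synthetic autotetraploid breeding populations.

This module generates every data layer the analysis consumes — pedigree,
true allele dosages, sequencing read counts, called genotypes, and field
phenotypes — under the same genetic model the estimation side assumes:
biparental crosses among tetraploid parents, bivalent pairing without
double reduction (each parent transmits 2 of its 4 allele copies sampled
without replacement), per-entry sequencing depth around a configurable
mean, and a phenotype that decomposes into year, field row/column,
additive, genotype-by-year and residual components.

Defaults emulate a perennial-fruit breeding population: ~124 biparental
crosses among ~146 parents (~1,850 progeny), sequence-capture
genotyping at a mean depth of 73x, and two years of field records.

It also provides a Monte-Carlo gene-dropping estimator of the additive
relationship matrix, used as the independent oracle for the pedigree
recursions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "SimulationConfig",
    "TruePopulation",
    "ReadCountMatrix",
    "simulate_pedigree",
    "drop_genes",
    "gene_dropping_relationship",
    "simulate_reads",
    "call_genotypes",
    "simulate_phenotypes",
    "simulate_population",
]

DEFAULT_VARIANCES = {
    "additive": 1.0,
    "row": 0.15,
    "column": 0.15,
    "gxe": 0.3,
    "residual": 2.0,
}


@dataclass
class SimulationConfig:
    """Study-design parameters for a synthetic breeding population.

    The defaults mirror the population regime the package targets:
    146 founder parents crossed in 124 biparental families of 15
    progeny (~1,860 individuals), tetrasomic inheritance, mean
    sequencing depth 73 reads with mild overdispersion (0.2), per-read
    error 0.005, founder allele frequencies Uniform(0.1, 0.9), and two
    years of phenotypes on a 50 x 40 field grid.  The default variance
    components give a narrow-sense heritability of about 0.28, inside
    the 0.15–0.57 band typical of yield and fruit-quality traits.
    """

    n_founders: int = 146
    n_crosses: int = 124
    progeny_per_cross: int = 15
    n_generations: int = 1
    n_markers: int = 86_000
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    mean_depth: float = 73.0
    depth_dispersion: float = 0.2
    seq_error: float = 0.005
    variance_components: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCES)
    )
    mu: float = 0.0
    year_effects: tuple[float, ...] | None = None
    n_years: int = 2
    field_dims: tuple[int, int] = (50, 40)
    seed: int = 2019

    def __post_init__(self) -> None:
        for name in (
            "n_founders",
            "n_crosses",
            "progeny_per_cross",
            "n_generations",
            "n_markers",
            "n_years",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.founder_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder_freq_range must lie strictly inside (0, 1)")
        if not (0.0 <= self.seq_error <= 1.0):
            raise ValueError("seq_error must be a probability")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be >= 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TruePopulation:
    """Ground truth behind a simulated population."""

    pedigree: Pedigree
    true_dosage: np.ndarray  # individuals x markers, ints 0..4
    true_bv: np.ndarray  # centered additive values, unit-free scale
    founder_freqs: np.ndarray
    allele_labels: np.ndarray | None = None  # individuals x 4 founder-copy ids

    @property
    def n(self) -> int:
        return self.pedigree.n


@dataclass
class ReadCountMatrix:
    """Per-entry alternative/reference read counts (individuals x markers)."""

    alt: np.ndarray
    ref: np.ndarray

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt)
        self.ref = np.asarray(self.ref)
        if self.alt.shape != self.ref.shape:
            raise ValueError("alt and ref count matrices must have the same shape")

    @property
    def depth(self) -> np.ndarray:
        return self.alt + self.ref

    def ratio(self) -> np.ndarray:
        """Alt/(alt+ref); entries with zero depth are NaN (missing)."""
        total = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(total > 0, self.alt / total, np.nan)
        return r


# ----------------------------------------------------------------------
# Pedigree simulation
# ----------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Random biparental crossing design.

    Founders have unknown parents; each generation draws ``n_crosses``
    distinct parent pairs from the previous generation and produces
    ``progeny_per_cross`` offspring per pair.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders to make a cross")
    max_pairs = math.comb(config.n_founders, 2)
    if config.n_crosses > max_pairs:
        raise ValueError(
            f"{config.n_crosses} distinct biparental crosses requested but only "
            f"{max_pairs} pairs are possible among {config.n_founders} parents"
        )
    rng = np.random.default_rng(config.seed)
    ids = [f"F{i:04d}" for i in range(config.n_founders)]
    sire = [UNKNOWN] * config.n_founders
    dam = [UNKNOWN] * config.n_founders
    parents_pool = list(range(config.n_founders))

    for gen in range(1, config.n_generations + 1):
        if len(parents_pool) < 2 or math.comb(len(parents_pool), 2) < config.n_crosses:
            raise ValueError(
                f"generation {gen}: {config.n_crosses} crosses need more distinct "
                f"parent pairs than the {len(parents_pool)} available parents allow"
            )
        pairs: set[tuple[int, int]] = set()
        while len(pairs) < config.n_crosses:
            a, b = rng.choice(len(parents_pool), size=2, replace=False)
            p = (parents_pool[min(a, b)], parents_pool[max(a, b)])
            pairs.add(p)
        new_pool: list[int] = []
        for c, (s, d) in enumerate(sorted(pairs)):
            for j in range(config.progeny_per_cross):
                ids.append(f"G{gen}C{c:03d}P{j:02d}")
                sire.append(s)
                dam.append(d)
                new_pool.append(len(ids) - 1)
        parents_pool = new_pool

    return Pedigree(ids=ids, sire=np.array(sire), dam=np.array(dam), ploidy=4)


# ----------------------------------------------------------------------
# Gene dropping
# ----------------------------------------------------------------------

def _gamete_indices(rng: np.random.Generator, size: int, ploidy: int) -> np.ndarray:
    """Indices of the transmitted copies: ploidy/2 of ploidy, no replacement."""
    if ploidy == 4:
        i1 = rng.integers(0, 4, size=size)
        i2 = (i1 + 1 + rng.integers(0, 3, size=size)) % 4
        return np.stack([i1, i2], axis=-1)
    if ploidy == 2:
        return rng.integers(0, 2, size=(size, 1))
    raise ValueError("only ploidy 2 or 4 gametes are supported")


def drop_genes(
    pedigree: Pedigree,
    founder_freqs: np.ndarray,
    track_ibd: bool = False,
    seed: int = 0,
) -> TruePopulation:
    """Propagate allele dosages through the pedigree.

    Founder dosages are Binomial(4, freq) per marker.  Each parent
    transmits the alternative-allele count of 2 copies drawn without
    replacement from its 4 — Hypergeometric(4, d, 2) given parent
    dosage ``d`` — and the offspring dosage is the sum of the two
    gametic counts.  ``track_ibd`` additionally records, at one neutral
    locus, which founder allele copy each of the 4 copies descends from.

    True breeding values are built from i.i.d. standard-normal marker
    effects on centered dosages and centered; they are rescaled to a
    target additive variance by :func:`simulate_phenotypes`.
    """
    if pedigree.ploidy != 4:
        raise ValueError(
            f"unsupported ploidy {pedigree.ploidy}: gene dropping assumes "
            "tetrasomic inheritance"
        )
    freqs = np.asarray(founder_freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("founder frequencies must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    n, m = pedigree.n, freqs.size
    dosage = np.zeros((n, m), dtype=np.int16)
    labels = np.zeros((n, 4), dtype=np.int64) if track_ibd else None

    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        gametes = []
        for parent in (s, d):
            if parent == UNKNOWN:
                gametes.append(None)
            else:
                gametes.append(
                    rng.hypergeometric(
                        ngood=dosage[parent], nbad=4 - dosage[parent], nsample=2
                    )
                )
        if gametes[0] is None and gametes[1] is None:
            dosage[i] = rng.binomial(4, freqs, size=m)
            if track_ibd:
                labels[i] = 4 * i + np.arange(4)
        elif gametes[0] is None or gametes[1] is None:
            known = gametes[0] if gametes[0] is not None else gametes[1]
            # unknown parent contributes a base-population gamete
            dosage[i] = known + rng.binomial(2, freqs, size=m)
            if track_ibd:
                kp = s if gametes[0] is not None else d
                idx = _gamete_indices(rng, 1, 4)[0]
                labels[i, :2] = labels[kp, idx]
                labels[i, 2:] = 4 * i + np.arange(2, 4)
        else:
            dosage[i] = gametes[0] + gametes[1]
            if track_ibd:
                labels[i, :2] = labels[s, _gamete_indices(rng, 1, 4)[0]]
                labels[i, 2:] = labels[d, _gamete_indices(rng, 1, 4)[0]]

    effects = rng.standard_normal(m)
    centered = dosage - dosage.mean(axis=0)
    bv = centered @ effects
    bv -= bv.mean()
    return TruePopulation(
        pedigree=pedigree,
        true_dosage=dosage,
        true_bv=bv,
        founder_freqs=freqs,
        allele_labels=labels,
    )


def gene_dropping_relationship(
    pedigree: Pedigree,
    n_replicates: int = 100_000,
    seed: int = 0,
    ploidy: int = 4,
    chunk: int = 2000,
) -> RelationshipMatrix:
    """Monte-Carlo additive relationship via founder-allele dropping.

    Founder copies receive globally distinct labels; gametes carry
    ``ploidy/2`` copies sampled without replacement (no double
    reduction).  With ``M_xy`` the number of label matches among the
    ``ploidy**2`` ordered copy pairs of ``x`` and ``y``, the kinship is
    ``theta_xy = E[M_xy] / ploidy**2`` and the returned matrix is
    ``A = ploidy * theta`` (so unrelated non-inbred individuals have
    diagonal 1).  Entry-wise Monte-Carlo standard errors are attached
    as ``.se``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if ploidy not in (2, 4):
        raise ValueError("gene dropping supports ploidy 2 or 4")
    n = pedigree.n
    half = ploidy // 2
    rng = np.random.default_rng(seed)
    # compact founder-copy labels: only base-population gametes spawn labels
    slot_labels: dict[tuple[int, int], np.ndarray] = {}
    next_label = 0
    for i in range(n):
        for slot, parent in ((0, pedigree.sire[i]), (half, pedigree.dam[i])):
            if parent == UNKNOWN:
                slot_labels[(i, slot)] = np.arange(
                    next_label, next_label + half, dtype=np.int32
                )
                next_label += half
    n_labels = max(next_label, 1)
    msum = np.zeros((n, n))
    msumsq = np.zeros((n, n))
    done = 0
    while done < n_replicates:
        r = min(chunk, n_replicates - done)
        geno = np.empty((r, n, ploidy), dtype=np.int32)
        for i in range(n):
            for slot, parent in ((0, pedigree.sire[i]), (half, pedigree.dam[i])):
                if parent == UNKNOWN:
                    geno[:, i, slot : slot + half] = slot_labels[(i, slot)]
                else:
                    idx = _gamete_indices(rng, r, ploidy)
                    geno[:, i, slot : slot + half] = np.take_along_axis(
                        geno[:, parent, :], idx, axis=1
                    )
        flat = (
            np.arange(r * n, dtype=np.int64)[:, None] * n_labels
            + geno.reshape(r * n, ploidy)
        ).ravel()
        counts = (
            np.bincount(flat, minlength=r * n * n_labels)
            .reshape(r, n, n_labels)
            .astype(np.float32)
        )
        match = counts @ counts.transpose(0, 2, 1)
        msum += match.sum(axis=0, dtype=np.float64)
        msumsq += np.square(match, out=match).sum(axis=0, dtype=np.float64)
        done += r

    scale = ploidy / ploidy**2  # A = ploidy * theta, theta = mean(M)/ploidy^2
    mean_m = msum / n_replicates
    A = scale * mean_m
    var_m = np.maximum(msumsq / n_replicates - mean_m**2, 0.0)
    se = scale * np.sqrt(var_m / n_replicates)
    return RelationshipMatrix(
        labels=list(pedigree.ids), values=A, source="gene_drop", se=se
    )


# ----------------------------------------------------------------------
# Sequencing reads and genotype calling
# ----------------------------------------------------------------------

def simulate_reads(
    true_dosage: np.ndarray,
    mean_depth: float = 73.0,
    depth_dispersion: float = 0.2,
    seq_error: float = 0.005,
    seed: int = 0,
) -> ReadCountMatrix:
    """Per-entry read counts from true tetraploid dosages.

    Total depth is negative-binomial with the given mean and
    dispersion ``phi`` (variance ``mu + phi mu^2``; Poisson when
    ``phi = 0``).  Each read reports the alternative allele with
    probability ``pi = (d/4)(1-e) + (1-d/4)e`` where ``e`` is the
    symmetric per-read error rate.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if depth_dispersion < 0:
        raise ValueError("depth_dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    d = np.asarray(true_dosage)
    if depth_dispersion == 0:
        depth = rng.poisson(mean_depth, size=d.shape)
    else:
        r = 1.0 / depth_dispersion
        depth = rng.negative_binomial(r, r / (r + mean_depth), size=d.shape)
    frac = d / 4.0
    pi = frac * (1.0 - seq_error) + (1.0 - frac) * seq_error
    alt = rng.binomial(depth, pi)
    return ReadCountMatrix(alt=alt, ref=depth - alt)


def call_genotypes(
    reads: ReadCountMatrix,
    ploidy: int,
    method: str = "binomial_map",
    seq_error: float = 0.005,
) -> np.ndarray:
    """Assign integer dosages from read counts.

    ``naive_round`` rounds ``ratio * ploidy`` to the nearest class;
    ``binomial_map`` picks the dosage maximizing the binomial read
    likelihood with symmetric error rate ``seq_error``.  Zero-depth
    entries are NaN (missing).
    """
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    depth = reads.depth
    if method == "naive_round":
        ratio = reads.ratio()
        called = np.floor(ratio * ploidy + 0.5)
        return np.clip(called, 0, ploidy)
    if method == "binomial_map":
        e = min(max(seq_error, 1e-12), 0.5)  # keep log-likelihood finite
        d_grid = np.arange(ploidy + 1)
        pi = d_grid / ploidy * (1 - e) + (1 - d_grid / ploidy) * e
        alt = reads.alt[..., None]
        ref = reads.ref[..., None]
        loglik = alt * np.log(pi) + ref * np.log1p(-pi)
        called = np.argmax(loglik, axis=-1).astype(float)
        called[depth == 0] = np.nan
        return called
    raise ValueError(f"unknown calling method {method!r}")


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------

def simulate_phenotypes(
    population: TruePopulation,
    config: SimulationConfig,
    trait: str = "sim_trait",
    seed: int | None = None,
) -> pd.DataFrame:
    """Field-trial records: ``y = mu + year + col + row + a + (year x a) + e``.

    The additive value ``a`` is the population's true breeding value
    rescaled to the configured additive variance.  Row and column
    effects are i.i.d. normal per index, nested within year when more
    than one year is simulated; each genotype gets one random (row,
    column) cell per year.  Returns a tidy table with columns
    ``genotype, year, row, column, trait, value``.
    """
    vc = dict(DEFAULT_VARIANCES)
    vc.update(config.variance_components)
    rng = np.random.default_rng(config.seed + 7_919 if seed is None else seed)
    ids = population.pedigree.ids
    n = len(ids)
    rows, cols = config.field_dims
    if rows * cols < n:
        raise ValueError(
            f"field of {rows} x {cols} cells cannot place {n} genotypes"
        )

    if config.year_effects is not None:
        if len(config.year_effects) != config.n_years:
            raise ValueError("year_effects length must equal n_years")
        year_eff = np.asarray(config.year_effects, dtype=float)
    else:
        year_eff = rng.standard_normal(config.n_years) if config.n_years > 1 else np.zeros(1)

    sd_bv = population.true_bv.std()
    if vc["additive"] > 0 and sd_bv > 0:
        a = population.true_bv / sd_bv * math.sqrt(vc["additive"])
    else:
        a = np.zeros(n)

    records = []
    for y in range(config.n_years):
        cells = rng.permutation(rows * cols)[:n]
        row_idx, col_idx = cells // cols, cells % cols
        row_eff = rng.standard_normal(rows) * math.sqrt(vc["row"])
        col_eff = rng.standard_normal(cols) * math.sqrt(vc["column"])
        gxe = rng.standard_normal(n) * math.sqrt(vc["gxe"]) if config.n_years > 1 else np.zeros(n)
        e = rng.standard_normal(n) * math.sqrt(vc["residual"])
        value = (
            config.mu
            + year_eff[y]
            + row_eff[row_idx]
            + col_eff[col_idx]
            + a
            + gxe
            + e
        )
        records.append(
            pd.DataFrame(
                {
                    "genotype": ids,
                    "year": y + 1,
                    "row": row_idx + 1,
                    "column": col_idx + 1,
                    "trait": trait,
                    "value": value,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


# ----------------------------------------------------------------------
# Convenience: full population in one call
# ----------------------------------------------------------------------

def simulate_population(config: SimulationConfig):
    """Pedigree -> dosages -> reads -> phenotypes under one seed.

    Returns ``(population, reads, phenotypes)``.  Stage seeds are
    spawned from ``config.seed`` so stages are independently
    reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    s_ped, s_drop, s_reads, s_phen = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)
    )
    pedigree = simulate_pedigree(config.with_seed(s_ped))
    lo, hi = config.founder_freq_range
    freqs = np.random.default_rng(s_drop).uniform(lo, hi, size=config.n_markers)
    population = drop_genes(pedigree, freqs, seed=s_drop)
    reads = simulate_reads(
        population.true_dosage,
        mean_depth=config.mean_depth,
        depth_dispersion=config.depth_dispersion,
        seq_error=config.seq_error,
        seed=s_reads,
    )
    phenotypes = simulate_phenotypes(population, config, seed=s_phen)
    return population, reads, phenotypes
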