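"""Genotype parameterizations, marker filters, imputation, heterozygosity.

Autotetraploid markers can enter a prediction model three ways:

* **pseudo-diploid** — all heterozygous classes collapsed to one
  (codes 0, 1, 2);
* **tetraploid** — full allele dosage (codes 0–4, i.e. AAAA..BBBB);
* **continuous** — the alternative-allele read ratio
  ``#A / (#A + #a)`` in [0, 1], with no dosage call at all.

This module holds the in-memory container for all three, the table
filters applied before building relationship matrices, marker-mean
imputation, and observed-heterozygosity summaries (including the
empirical homozygote bounds used to classify continuous values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ReadCountMatrix

__all__ = [
    "GenotypeData",
    "FilterReport",
    "HeterozygositySummary",
    "encode_pseudo_diploid",
    "compute_ratio",
    "filter_markers",
    "impute_missing",
    "observed_heterozygosity",
    "relative_heterozygosity",
]


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeData:
    """Individuals x markers genotype table under one parameterization.

    ``ploidy_code`` is ``2``, ``4`` (integer dosages in ``dosage``) or
    ``"ratio"`` (continuous values in ``ratio``).  Missing entries are
    NaN.  ``markers`` is a metadata frame indexed by marker id with
    columns ``scaffold``, ``position``, ``probe`` and ``biallelic``
    (filled with defaults when absent).
    """

    individuals: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray | None = None
    ratio: np.ndarray | None = None
    reads: ReadCountMatrix | None = None
    ploidy_code: int | str = 4

    def __post_init__(self) -> None:
        n, m = len(self.individuals), len(self.markers)
        if len(set(self.individuals)) != n:
            raise GenotypeError("duplicate individual labels")
        if self.markers.index.duplicated().any():
            raise GenotypeError("duplicate marker labels")
        self.markers = self.markers.copy()
        for col, default in (
            ("scaffold", "scaffold_0"),
            ("position", 0),
            ("probe", None),
            ("biallelic", True),
        ):
            if col not in self.markers.columns:
                self.markers[col] = (
                    self.markers.index if col == "probe" else default
                )
        for name in ("dosage", "ratio"):
            mat = getattr(self, name)
            if mat is not None:
                mat = np.asarray(mat, dtype=float)
                if mat.shape != (n, m):
                    raise GenotypeError(
                        f"{name} matrix shape {mat.shape} != ({n}, {m})"
                    )
                setattr(self, name, mat)
        if self.reads is not None and self.reads.alt.shape != (n, m):
            raise GenotypeError("read count shape does not match labels")
        if self.ploidy_code in (2, 4) and self.dosage is not None:
            mx = np.nanmax(self.dosage) if self.dosage.size else 0
            mn = np.nanmin(self.dosage) if self.dosage.size else 0
            if mx > self.ploidy_code or mn < 0:
                raise GenotypeError(
                    f"dosage entries outside [0, {self.ploidy_code}]"
                )
        if self.ploidy_code == "ratio" and self.ratio is None:
            raise GenotypeError("ratio parameterization requires a ratio matrix")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def values(self) -> np.ndarray:
        """The active matrix for this parameterization."""
        return self.ratio if self.ploidy_code == "ratio" else self.dosage

    def subset_markers(self, keep: np.ndarray) -> "GenotypeData":
        def take(mat):
            return mat[:, keep] if mat is not None else None

        reads = (
            ReadCountMatrix(self.reads.alt[:, keep], self.reads.ref[:, keep])
            if self.reads is not None
            else None
        )
        return GenotypeData(
            individuals=list(self.individuals),
            markers=self.markers.iloc[np.asarray(keep)].copy()
            if np.asarray(keep).dtype != bool
            else self.markers.loc[keep].copy(),
            dosage=take(self.dosage),
            ratio=take(self.ratio),
            reads=reads,
            ploidy_code=self.ploidy_code,
        )


@dataclass
class FilterReport:
    """Tally of markers removed per filtering rule, in application order."""

    n_input: int
    n_pass: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pass + sum(self.removed.values()) != self.n_input:
            raise ValueError("filter report counts are inconsistent")


# ----------------------------------------------------------------------
# Encodings
# ----------------------------------------------------------------------

def encode_pseudo_diploid(dosage4: np.ndarray) -> np.ndarray:
    """Collapse tetraploid dosages to pseudo-diploid codes.

    0 (AAAA) -> 0, {1, 2, 3} (any heterozygote) -> 1, 4 (BBBB) -> 2;
    missing (NaN) is preserved.  Already-pseudo-diploid input restricted
    to {0, 1, 2} passes through unchanged (idempotence).
    """
    d = np.asarray(dosage4, dtype=float)
    obs = ~np.isnan(d)
    if np.any((d[obs] < 0) | (d[obs] > 4) | (d[obs] != np.round(d[obs]))):
        raise GenotypeError("tetraploid dosages must be integers in 0..4")
    out = np.where(d == 0, 0.0, np.where(d == 4, 2.0, 1.0))
    out[~obs] = np.nan
    return out


def compute_ratio(reads: ReadCountMatrix) -> np.ndarray:
    """Continuous genotype: alt/(alt+ref); zero total depth -> missing."""
    if np.any(reads.alt < 0) or np.any(reads.ref < 0):
        raise GenotypeError("read counts must be non-negative")
    return reads.ratio()


# ----------------------------------------------------------------------
# Filtering and imputation
# ----------------------------------------------------------------------

def _maf(data: GenotypeData) -> np.ndarray:
    """Minor allele frequency per marker from mean dosage or mean ratio."""
    mat = data.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(mat, axis=0)
    if data.ploidy_code == "ratio":
        p = mean
    else:
        p = mean / float(data.ploidy_code)
    return np.minimum(p, 1.0 - p)


def filter_markers(
    data: GenotypeData,
    min_mean_depth: float = 40.0,
    max_missing: float = 0.5,
    min_maf: float = 0.05,
    biallelic_only: bool = True,
) -> tuple[GenotypeData, FilterReport]:
    """Sequential marker filters: depth, biallelic, missingness, MAF.

    A marker is charged to the first rule it fails.  Depth is the mean
    sequencing depth across the population (requires read counts; the
    rule is skipped when none are attached).  Boundary values pass:
    mean depth >= threshold, missingness <= threshold, MAF >= threshold.
    """
    if not (0.0 <= max_missing <= 1.0) or not (0.0 <= min_maf <= 0.5):
        raise ValueError("filter thresholds out of range")
    m = data.n_markers
    keep = np.ones(m, dtype=bool)
    removed: dict[str, int] = {}

    if data.reads is not None and min_mean_depth > 0:
        mean_depth = data.reads.depth.mean(axis=0)
        fail = keep & (mean_depth < min_mean_depth)
    else:
        fail = np.zeros(m, dtype=bool)
    removed["depth"] = int(fail.sum())
    keep &= ~fail

    if biallelic_only:
        fail = keep & ~data.markers["biallelic"].to_numpy(bool)
    else:
        fail = np.zeros(m, dtype=bool)
    removed["biallelic"] = int(fail.sum())
    keep &= ~fail

    missing_frac = np.isnan(data.values).mean(axis=0)
    fail = keep & (missing_frac > max_missing)
    removed["missingness"] = int(fail.sum())
    keep &= ~fail

    maf = _maf(data)
    fail = keep & ~(maf >= min_maf)  # NaN MAF (all-missing marker) fails too
    removed["maf"] = int(fail.sum())
    keep &= ~fail

    if not keep.any():
        warnings.warn("all markers removed by filters", stacklevel=2)
    out = data.subset_markers(keep)
    return out, FilterReport(n_input=m, n_pass=int(keep.sum()), removed=removed)


def impute_missing(matrix: np.ndarray) -> np.ndarray:
    """Replace missing entries by their marker (column) mean.

    Observed entries are unchanged, so column means are invariant.
    A fully missing column is an error: run the marker filters first.
    """
    X = np.asarray(matrix, dtype=float).copy()
    obs = ~np.isnan(X)
    empty = ~obs.any(axis=0)
    if empty.any():
        raise GenotypeError(
            f"{int(empty.sum())} fully missing marker column(s); "
            "apply filter_markers before imputation"
        )
    means = np.nanmean(X, axis=0)
    idx = np.nonzero(~obs)
    X[idx] = means[idx[1]]
    return X


# ----------------------------------------------------------------------
# Heterozygosity
# ----------------------------------------------------------------------

@dataclass
class HeterozygositySummary:
    overall: float  # pooled over all non-missing entries
    per_marker: pd.Series  # heterozygote fraction per marker
    per_marker_mean: float  # mean of the per-marker fractions


def observed_heterozygosity(
    data: GenotypeData,
    continuous_bounds: tuple[float, float] = (0.058, 0.908),
) -> HeterozygositySummary:
    """Fraction of heterozygous calls among non-missing entries.

    Heterozygotes are code 1 (pseudo-diploid), codes 1–3 (tetraploid),
    or continuous values strictly between the bounds — values at or
    below the lower bound and at or above the upper bound count as
    homozygous.  Both the pooled fraction and the per-marker vector are
    reported.
    """
    mat = data.values
    if mat is None or mat.size == 0:
        raise GenotypeError("no genotype entries to summarize")
    obs = ~np.isnan(mat)
    if data.ploidy_code == 2:
        het = obs & (mat == 1)
    elif data.ploidy_code == 4:
        het = obs & (mat >= 1) & (mat <= 3)
    else:
        lo, hi = continuous_bounds
        het = obs & (mat > lo) & (mat < hi)
    denom = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_marker = np.where(denom > 0, het.sum(axis=0) / denom, np.nan)
    series = pd.Series(per_marker, index=data.markers.index, name="het_fraction")
    return HeterozygositySummary(
        overall=float(het.sum() / obs.sum()),
        per_marker=series,
        per_marker_mean=float(series.mean()),
    )


def relative_heterozygosity(h_a: float, h_b: float) -> float:
    """Percent excess of heterozygotes in scenario a over scenario b."""
    if h_b <= 0:
        raise ValueError("reference heterozygosity must be positive")
    return 100.0 * (h_a / h_b - 1.0)
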