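"""Linkage-disequilibrium decay and relationship-matrix PCA diagnostics.

LD between marker pairs within a scaffold is the squared Pearson
correlation of their genotype columns (dosages or ratios — the same
statistic applies to every parameterization).  The decay distance is
where a fitted exponential decay curve crosses a threshold
(r^2 = 0.2 by default), with a bootstrap confidence interval over
marker pairs.  Diversity captured by a relationship matrix is
summarized by principal components of the double-centered matrix
(classical PCoA), reporting percent variance explained per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kinship import RelationshipMatrix

__all__ = [
    "LDDecayResult",
    "PCAResult",
    "sample_one_per_probe",
    "pairwise_ld",
    "ld_decay_distance",
    "pca_relationship",
]


def sample_one_per_probe(markers: pd.DataFrame, seed: int = 0) -> list[str]:
    """Pick one marker uniformly at random per probe interval.

    ``markers`` is indexed by marker id with a ``probe`` column.
    Pruning to one SNP per capture probe removes the near-perfect LD
    among SNPs sitting on the same 120-mer target.
    """
    if "probe" not in markers.columns:
        raise ValueError("marker metadata has no 'probe' column")
    rng = np.random.default_rng(seed)
    chosen = []
    for _, group in markers.groupby("probe", sort=True):
        chosen.append(group.index[rng.integers(0, len(group))])
    return sorted(chosen)


def pairwise_ld(
    genotypes: np.ndarray,
    markers: pd.DataFrame,
    max_dist: float | None = None,
) -> pd.DataFrame:
    """r^2 for all within-scaffold marker pairs.

    ``genotypes`` is individuals x markers with no missing entries;
    ``markers`` is indexed by marker id with ``scaffold`` and
    ``position`` columns, aligned to the matrix columns.  Monomorphic
    columns (undefined correlation) are skipped.  Returns a tidy table
    (marker_i, marker_j, scaffold, dist, r2).
    """
    X = np.asarray(genotypes, float)
    if np.isnan(X).any():
        raise ValueError("genotype matrix contains missing entries; impute first")
    if X.shape[1] != len(markers):
        raise ValueError("marker metadata does not match matrix columns")
    records = []
    names = np.asarray(markers.index)
    scaffolds = markers["scaffold"].to_numpy()
    positions = markers["position"].to_numpy(float)
    for scaf in pd.unique(scaffolds):
        idx = np.nonzero(scaffolds == scaf)[0]
        idx = idx[X[:, idx].std(axis=0) > 0]
        if idx.size < 2:
            continue
        corr = np.corrcoef(X[:, idx], rowvar=False)
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                dist = abs(positions[idx[a]] - positions[idx[b]])
                if max_dist is not None and dist > max_dist:
                    continue
                records.append(
                    (
                        names[idx[a]],
                        names[idx[b]],
                        scaf,
                        dist,
                        float(np.clip(corr[a, b] ** 2, 0.0, 1.0)),
                    )
                )
    return pd.DataFrame(
        records, columns=["marker_i", "marker_j", "scaffold", "dist", "r2"]
    )


@dataclass
class LDDecayResult:
    status: str  # "ok", "below_threshold", "not_reached"
    distance_kb: float | None
    ci_low: float | None
    ci_high: float | None
    r0: float | None
    decay_kb: float | None  # exponential length scale lambda


def _fit_decay(dist_kb: np.ndarray, r2: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of r^2 = r0 * exp(-d / lambda); d in Kb."""

    def model(d, r0, lam):
        return r0 * np.exp(-d / lam)

    lam0 = max(np.median(dist_kb), 1e-3)
    popt, _ = curve_fit(
        model,
        dist_kb,
        r2,
        p0=[min(max(r2.max(), 0.05), 1.0), lam0],
        bounds=([1e-6, 1e-6], [1.0, np.inf]),
        maxfev=10_000,
    )
    return float(popt[0]), float(popt[1])


def ld_decay_distance(
    table: pd.DataFrame,
    threshold: float = 0.2,
    n_boot: int = 200,
    seed: int = 0,
) -> LDDecayResult:
    """Distance (Kb) at which the fitted LD decay curve crosses ``threshold``.

    Fits ``r^2(d) = r0 exp(-d/lambda)`` over all pairs and solves for
    the crossing ``d* = lambda ln(r0 / threshold)``.  If every observed
    r^2 lies below the threshold the status is ``below_threshold``
    (distance 0); if the fitted curve only crosses beyond the observed
    distance range the status is ``not_reached``.  The CI is a
    percentile bootstrap over marker pairs.
    """
    if table.empty:
        raise ValueError("empty LD table")
    dist_kb = table["dist"].to_numpy(float) / 1_000.0
    r2 = table["r2"].to_numpy(float)
    if (r2 < threshold).all():
        return LDDecayResult("below_threshold", 0.0, None, None, None, None)

    r0, lam = _fit_decay(dist_kb, r2)
    if r0 <= threshold:
        return LDDecayResult("below_threshold", 0.0, None, None, r0, lam)
    crossing = lam * np.log(r0 / threshold)
    if crossing > dist_kb.max():
        return LDDecayResult("not_reached", None, None, None, r0, lam)

    rng = np.random.default_rng(seed)
    boots = []
    n = len(table)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            b_r0, b_lam = _fit_decay(dist_kb[idx], r2[idx])
        except RuntimeError:  # pragma: no cover - rare fit failure
            continue
        if b_r0 > threshold:
            boots.append(b_lam * np.log(b_r0 / threshold))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = float(min(lo, crossing)), float(max(hi, crossing))
    else:  # pragma: no cover
        lo = hi = float(crossing)
    return LDDecayResult("ok", float(crossing), lo, hi, r0, lam)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    scores: pd.DataFrame  # individuals x components, sqrt(eigenvalue) scaled
    pct_explained: np.ndarray  # per retained component, of positive eigenvalues


def pca_relationship(K: RelationshipMatrix, n_components: int = 2) -> PCAResult:
    """Principal components of a double-centered relationship matrix.

    Percent explained divides each eigenvalue by the sum of the
    positive eigenvalues only (small negative eigenvalues can occur for
    unbent G matrices).  Scores are eigenvectors scaled by the square
    root of their eigenvalue.
    """
    n = K.n
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K.values @ J
    w, V = np.linalg.eigh(Kc)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos_sum = float(w[w > 1e-12].sum())
    if pos_sum <= 0:
        raise ValueError("relationship matrix has no positive centered eigenvalues")
    q = min(n_components, n)
    scores = V[:, :q] * np.sqrt(np.maximum(w[:q], 0.0))
    return PCAResult(
        eigenvalues=w,
        scores=pd.DataFrame(
            scores, index=K.labels, columns=[f"PC{i+1}" for i in range(q)]
        ),
        pct_explained=100.0 * np.maximum(w[:q], 0.0) / pos_sum,
    )
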