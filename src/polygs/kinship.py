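"""Additive relationship matrices for autotetraploid breeding populations.

Five constructions are provided, matching the sources of information a
breeding analysis can draw on:

* ``A2`` — pedigree numerator relationship under a diploid transmission
  model (Henderson's recursion).
* ``A4`` — pedigree relationship under autotetraploid bivalent
  inheritance without double reduction, via the kinship/inbreeding
  recursion for tetrasomic transmission.
* ``G2`` / ``G4`` / ``Gr`` — VanRaden-style marker cross-product
  matrices built from pseudo-diploid codes (0–2), tetraploid dosages
  (0–4), or continuous allele-read ratios in [0, 1].

All of them return a :class:`RelationshipMatrix`, the covariance
structure of breeding values in the mixed model (``a ~ N(0, K sigma_a^2)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree


class KinshipError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    """Symmetric, labeled additive-relationship matrix."""

    labels: list[str]
    values: np.ndarray
    source: str = "unknown"
    se: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise KinshipError("relationship matrix labels must be unique")
        if self.values.shape != (n, n):
            raise KinshipError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise KinshipError("relationship matrix is not symmetric")
        # enforce exact symmetry for downstream eigendecompositions
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.labels)

    def align(self, labels: list[str]) -> "RelationshipMatrix":
        """Reorder/subset to ``labels``; missing ids are an error."""
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise KinshipError(
                f"{len(missing)} ids absent from the relationship matrix, "
                f"e.g. {missing[:5]}"
            )
        idx = np.array([index[l] for l in labels])
        se = self.se[np.ix_(idx, idx)] if self.se is not None else None
        return RelationshipMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            source=self.source,
            se=se,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, source: str = "file") -> "RelationshipMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            labels=[str(c) for c in frame.columns],
            values=frame.to_numpy(float),
            source=source,
        )


# ----------------------------------------------------------------------
# Pedigree-based matrices
# ----------------------------------------------------------------------

def amatrix_diploid(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix under diploid transmission.

    Standard recursion: for individual ``y`` with parents ``s`` and
    ``d``, ``a_xy = (a_xs + a_xd) / 2`` for earlier ``x`` and
    ``a_yy = 1 + a_sd / 2``; an unknown parent contributes zero.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[:i, s]
        if d != UNKNOWN:
            row += 0.5 * A[:i, d]
        A[:i, i] = A[i, :i] = row
        f = 0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + f
    return RelationshipMatrix(labels=list(pedigree.ids), values=A, source="A2")


def amatrix_tetraploid(
    pedigree: Pedigree, double_reduction: float = 0.0
) -> RelationshipMatrix:
    """Additive relationship under autotetraploid bivalent inheritance.

    Works on the kinship scale: ``theta_xy`` is the probability that one
    allele copy drawn at random from ``x`` and one from ``y`` are
    identical by descent, and ``F_i`` the probability that two distinct
    copies of ``i`` are IBD.  Each parent transmits 2 of its 4 copies
    sampled without replacement (no double reduction), so for offspring
    ``i`` of ``s`` x ``d``::

        theta_xi = (theta_xs + theta_xd) / 2
        F_i      = (F_s + F_d) / 6 + (2/3) theta_sd
        theta_ii = (1 + 3 F_i) / 4

    and the additive relationship is ``A = 4 theta`` (diagonal
    ``1 + 3F``).  Unknown parents contribute unrelated base-population
    gametes.
    """
    if double_reduction != 0.0:
        raise NotImplementedError(
            "only the zero-double-reduction transmission model is supported"
        )
    if pedigree.ploidy != 4:
        raise KinshipError("amatrix_tetraploid requires a ploidy-4 pedigree")
    n = pedigree.n
    theta = np.zeros((n, n))
    F = np.zeros(n)
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * theta[:i, s]
        if d != UNKNOWN:
            row += 0.5 * theta[:i, d]
        theta[:i, i] = theta[i, :i] = row
        fs = F[s] if s != UNKNOWN else 0.0
        fd = F[d] if d != UNKNOWN else 0.0
        th_sd = theta[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        F[i] = (fs + fd) / 6.0 + (2.0 / 3.0) * th_sd
        theta[i, i] = 0.25 * (1.0 + 3.0 * F[i])
    return RelationshipMatrix(
        labels=list(pedigree.ids), values=4.0 * theta, source="A4"
    )


# ----------------------------------------------------------------------
# Marker-based matrices
# ----------------------------------------------------------------------

_G_PLOIDY = {"G2": 2, "G4": 4}


def gmatrix(
    coded: np.ndarray,
    parameterization: str,
    labels: list[str] | None = None,
) -> RelationshipMatrix:
    """VanRaden cross-product relationship matrix ``W W' / k``.

    ``coded`` is individuals x markers with no missing entries
    (impute first): 0–2 codes for ``G2``, 0–4 dosages for ``G4``, or
    read ratios in [0, 1] for ``Gr``.  Columns are centered on their
    observed means.  The scale ``k`` is the expected centered
    cross-product under the parameterization's sampling model:
    ``sum 2 p q`` (``G2``), ``sum 4 p q`` (``G4``) with ``p`` the
    observed allele frequency, and the sum of observed column variances
    for ``Gr`` (no ploidy assumption; makes the mean diagonal exactly 1).
    """
    if parameterization not in {"G2", "G4", "Gr"}:
        raise KinshipError(f"unknown G-matrix parameterization {parameterization!r}")
    X = np.asarray(coded, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise KinshipError("need an individuals x markers matrix with >= 2 markers")
    if np.isnan(X).any():
        raise KinshipError("coded matrix contains missing entries; impute first")

    variances = X.var(axis=0)
    poly = variances > 0
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} monomorphic markers before scaling",
            stacklevel=2,
        )
        X = X[:, poly]
        variances = variances[poly]
    if X.shape[1] == 0:
        raise KinshipError("all markers are monomorphic; G matrix undefined")

    means = X.mean(axis=0)
    W = X - means
    if parameterization == "Gr":
        k = float(variances.sum())
    else:
        ploidy = _G_PLOIDY[parameterization]
        p = means / ploidy
        k = float(np.sum(ploidy * p * (1.0 - p)))
    if k <= 0:
        raise KinshipError("zero scaling constant; markers carry no variation")
    G = (W @ W.T) / k
    if labels is None:
        labels = [f"ind{i}" for i in range(X.shape[0])]
    return RelationshipMatrix(labels=list(labels), values=G, source=parameterization)


def identity_matrix(ids: list[str]) -> RelationshipMatrix:
    """Identity relationship (phenotypic-BLUP baseline: unrelated individuals)."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise KinshipError("duplicate ids for identity matrix")
    return RelationshipMatrix(labels=ids, values=np.eye(len(ids)), source="I")


def bend_psd(
    K: RelationshipMatrix, epsilon: float = 1e-6, tol: float = 1e-10
) -> RelationshipMatrix:
    """Shift the diagonal just enough to make ``K`` positive definite.

    If the smallest eigenvalue is below ``tol``, adds
    ``epsilon * mean(diag)`` plus any deficit to the diagonal; the
    off-diagonal entries are never changed.  Already-PD matrices are
    returned unchanged.
    """
    w = np.linalg.eigvalsh(K.values)
    lam_min = float(w[0])
    if lam_min >= tol:
        return K
    shift = epsilon * float(np.mean(np.diag(K.values))) + max(0.0, -lam_min)
    return RelationshipMatrix(
        labels=list(K.labels),
        values=K.values + shift * np.eye(K.n),
        source=K.source,
        se=K.se,
    )
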