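"""Pedigree container and validation.

A pedigree is an ordered list of individuals with at most two known
parents each.  Internally parents are stored as integer indices into the
record order (``-1`` = unknown), which is the representation the
relationship recursions and the gene-dropping simulator consume.
Records are topologically sorted on construction so that every parent
precedes its offspring; a cycle (an individual that is its own ancestor)
is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1

_MISSING_TOKENS = {"", "0", "na", "nan", "none", "unknown", "."}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Ordered parentage records for a (by default autotetraploid) population.

    Parameters
    ----------
    ids
        Unique individual labels, in an order where parents precede
        offspring (use :meth:`from_frame` to sort arbitrary input).
    sire, dam
        Integer arrays of the same length as ``ids``; each entry indexes
        ``ids`` or is ``-1`` for an unknown parent.
    ploidy
        Somatic ploidy of every individual.  The autotetraploid
        machinery requires 4; the diploid A-matrix only uses the
        topology and accepts any value.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    ploidy: int = 4
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate individual ids in pedigree")
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("sire/dam arrays must match the id list length")
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            if np.any(arr >= np.arange(n)):
                bad = int(np.nonzero(arr >= np.arange(n))[0][0])
                raise PedigreeError(
                    f"{name} of {self.ids[bad]!r} does not precede it; "
                    "pedigree must be sorted parents-first (see from_frame)"
                )
            if np.any(arr < UNKNOWN):
                raise PedigreeError(f"invalid {name} index")
        self._index = {ind: i for i, ind in enumerate(self.ids)}

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        """True where both parents are unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def loc(self, individual: str) -> int:
        return self._index[individual]

    # ------------------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, ploidy: int = 4) -> "Pedigree":
        """Build a pedigree from an (id, sire, dam) table in any row order.

        Unknown parents may be encoded as 0, empty, NA or ``None``.
        Parents that are referenced but have no row of their own are
        added as founders.
        """
        cols = list(frame.columns[:3])
        ids_raw = [str(v) for v in frame[cols[0]]]

        def norm(v) -> str | None:
            if pd.isna(v):
                return None
            s = str(v).strip()
            return None if s.lower() in _MISSING_TOKENS else s

        sires = [norm(v) for v in frame[cols[1]]]
        dams = [norm(v) for v in frame[cols[2]]]
        if len(set(ids_raw)) != len(ids_raw):
            raise PedigreeError("duplicate individual ids in pedigree table")

        parents: dict[str, tuple[str | None, str | None]] = {}
        for ind, s, d in zip(ids_raw, sires, dams):
            parents[ind] = (s, d)
        for s, d in list(parents.values()):
            for p in (s, d):
                if p is not None and p not in parents:
                    parents[p] = (None, None)

        # Kahn topological sort; stable under input order.
        order: list[str] = []
        placed: set[str] = set()
        pending = list(parents)
        while pending:
            progress = False
            rest = []
            for ind in pending:
                s, d = parents[ind]
                if (s is None or s in placed) and (d is None or d in placed):
                    order.append(ind)
                    placed.add(ind)
                    progress = True
                else:
                    rest.append(ind)
            if not progress:
                raise PedigreeError(
                    f"pedigree contains a cycle involving: {sorted(rest)[:5]}"
                )
            pending = rest

        idx = {ind: i for i, ind in enumerate(order)}
        sire = np.array(
            [idx[parents[i][0]] if parents[i][0] is not None else UNKNOWN for i in order]
        )
        dam = np.array(
            [idx[parents[i][1]] if parents[i][1] is not None else UNKNOWN for i in order]
        )
        return cls(ids=order, sire=sire, dam=dam, ploidy=ploidy)

    def to_frame(self) -> pd.DataFrame:
        def lbl(a: int) -> str:
            return self.ids[a] if a != UNKNOWN else "0"

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [lbl(s) for s in self.sire],
                "dam": [lbl(d) for d in self.dam],
            }
        )
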