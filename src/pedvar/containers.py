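"""Shared container for labelled square matrices (relatedness and similarity)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabeledMatrix:
    """A dense symmetric matrix whose rows/columns are individual ids.

    Used for the additive relatedness matrix A and for the nongenetic
    similarity matrices (environmental, epiallelic, social).  ``kind`` is a
    free label such as ``"GENETIC"``, ``"ENV"``, ``"EPI"``, ``"SOCIAL"`` or
    ``"IDENTITY"``.
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str = ""
    _pos: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate ids in LabeledMatrix")
        self._pos = {int(i): k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, i, j) -> float:
        """Entry for the pair of individuals (i, j)."""
        return float(self.values[self._pos[int(i)], self._pos[int(j)]])

    def reindex(self, new_ids) -> "LabeledMatrix":
        """Return the matrix over the distinct ids ``new_ids``.

        Ids absent from the matrix are added as fresh levels: diagonal 1,
        zero similarity/relatedness to everyone else.  This is the standard
        convention for individuals with missing data (e.g. phantom founder
        dams carried by a maternal-effect term).
        """
        new_ids = np.asarray(new_ids)
        n = len(new_ids)
        out = np.zeros((n, n))
        pos = np.array([self._pos.get(int(i), -1) for i in new_ids])
        kidx = np.where(pos >= 0)[0]
        out[np.ix_(kidx, kidx)] = self.values[np.ix_(pos[kidx], pos[kidx])]
        miss = np.where(pos < 0)[0]
        out[miss, miss] = 1.0
        return LabeledMatrix(new_ids, out, kind=self.kind)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "") -> "LabeledMatrix":
        ids = np.asarray([int(i) for i in df.index])
        return cls(ids, df.to_numpy(dtype=float), kind=kind)
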