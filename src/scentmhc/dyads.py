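"""Labelled dyadic distance matrices.

A :class:`DyadMatrix` is either square-symmetric (within-sex dyads, zero
diagonal) or rectangular (mixed-sex dyads, rows = males, columns =
females, disjoint label sets). Unfolding a square matrix takes the
strict lower triangle in row-major order (pairs (i, j) with i > j over
the row-label order); a rectangular matrix is flattened row-major. Two
matrices with the same labels therefore unfold onto the same dyad
ordering once aligned with :meth:`DyadMatrix.align_to`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SQUARE = "square"
RECT = "rect"


@dataclass
class DyadMatrix:
    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    kind: str = SQUARE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = tuple(str(i) for i in self.row_ids)
        self.col_ids = tuple(str(i) for i in self.col_ids)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("values shape does not match labels")
        if np.any(self.values < 0):
            raise ValueError("dyadic distances must be nonnegative")
        if self.kind == SQUARE:
            if self.row_ids != self.col_ids:
                raise ValueError("square DyadMatrix requires identical row/col labels")
            if not np.allclose(self.values, self.values.T, atol=1e-10):
                raise ValueError("square DyadMatrix must be symmetric")
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
                raise ValueError("square DyadMatrix must have a zero diagonal")
        elif self.kind == RECT:
            if set(self.row_ids) & set(self.col_ids):
                raise ValueError("rectangular DyadMatrix requires disjoint row/col labels")
        else:
            raise ValueError(f"unknown DyadMatrix kind: {self.kind!r}")

    # -- construction -------------------------------------------------

    @classmethod
    def square(cls, values: np.ndarray, ids: Sequence[str]) -> "DyadMatrix":
        return cls(values, tuple(ids), tuple(ids), SQUARE)

    @classmethod
    def rect(cls, values: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str]) -> "DyadMatrix":
        return cls(values, tuple(row_ids), tuple(col_ids), RECT)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = SQUARE) -> "DyadMatrix":
        return cls(frame.to_numpy(dtype=float), tuple(frame.index.astype(str)),
                   tuple(frame.columns.astype(str)), kind)

    # -- properties ---------------------------------------------------

    @property
    def n_dyads(self) -> int:
        n = len(self.row_ids)
        if self.kind == SQUARE:
            return n * (n - 1) // 2
        return n * len(self.col_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.col_ids))

    # -- alignment and unfolding --------------------------------------

    def align_to(self, other: "DyadMatrix") -> "DyadMatrix":
        """Reorder this matrix onto ``other``'s label order.

        Raises if the label sets differ — comparing matrices over
        different individuals is a hard error, not a silent subset.
        """
        if self.kind != other.kind:
            raise ValueError("cannot align matrices of different kinds")
        if set(self.row_ids) != set(other.row_ids) or set(self.col_ids) != set(other.col_ids):
            raise ValueError("label mismatch between dyadic matrices")
        r = [self.row_ids.index(i) for i in other.row_ids]
        c = [self.col_ids.index(j) for j in other.col_ids]
        return DyadMatrix(self.values[np.ix_(r, c)], other.row_ids, other.col_ids, self.kind)

    def unfold(self) -> np.ndarray:
        """Return the dyad vector (documented ordering, see module docs)."""
        if self.kind == SQUARE:
            i, j = np.tril_indices(len(self.row_ids), k=-1)
            return self.values[i, j]
        return self.values.ravel()

    # -- IO -----------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = SQUARE) -> "DyadMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls.from_frame(frame, kind)


def pairwise_abs_diff(values: np.ndarray) -> np.ndarray:
    """|v_i - v_j| for all pairs; the 1-D Euclidean dyadic distance."""
    v = np.asarray(values, dtype=float)
    return np.abs(v[:, None] - v[None, :])


def split_by_sex(
    values: Sequence[float], ids: Sequence[str], sexes: Sequence[str]
) -> dict[str, DyadMatrix]:
    """Build the FF / MM / MF dyadic |difference| matrices of a scalar trait.

    ``sexes`` entries must be 'F' or 'M'. MF rows are males, columns are
    females, both in input order.
    """
    v = np.asarray(values, dtype=float)
    ids = [str(i) for i in ids]
    sexes = [str(s) for s in sexes]
    bad = sorted({s for s in sexes if s not in {"F", "M"}})
    if bad:
        raise ValueError(f"unknown sex label(s): {bad}; expected 'F' or 'M'")
    f_idx = [k for k, s in enumerate(sexes) if s == "F"]
    m_idx = [k for k, s in enumerate(sexes) if s == "M"]
    full = pairwise_abs_diff(v)
    out: dict[str, DyadMatrix] = {}
    out["FF"] = DyadMatrix.square(full[np.ix_(f_idx, f_idx)], [ids[k] for k in f_idx])
    out["MM"] = DyadMatrix.square(full[np.ix_(m_idx, m_idx)], [ids[k] for k in m_idx])
    out["MF"] = DyadMatrix.rect(
        full[np.ix_(m_idx, f_idx)], [ids[k] for k in m_idx], [ids[k] for k in f_idx]
    )
    return out
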