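"""Exchange containers shared by every pipeline stage.

Two conventions run through the package:

* A *demographic table* is a tidy :class:`pandas.DataFrame` with the key
  columns ``location``, ``age_start``, ``age_end``, ``sex``, ``year`` (any
  subset of these, but always in this order) plus one or more value columns.
  One row per demographic cell; missing values are forbidden.

* A :class:`DrawSet` attaches an ``(n_cells, n_draws)`` matrix of Monte-Carlo
  draws to such a key frame. All uncertainty is carried end-to-end as draws;
  summaries are taken only at the very end (see :mod:`diabem.reporting`).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical ordering for demographic key columns
KEY_COLUMNS = ("location", "age_start", "age_end", "sex", "year")


class AlignmentError(ValueError):
    """Raised when two demographic objects do not share the same cell grid."""


def key_columns_of(frame: pd.DataFrame) -> list[str]:
    """Return the demographic key columns present in *frame*, canonical order."""
    return [c for c in KEY_COLUMNS if c in frame.columns]


def check_aligned(left: pd.DataFrame, right: pd.DataFrame, context: str = "") -> None:
    """Require identical key grids (same cells, same order).

    Raises :class:`AlignmentError` naming the first offending cells.
    """
    lk, rk = key_columns_of(left), key_columns_of(right)
    if lk != rk:
        raise AlignmentError(
            f"{context}: key columns differ: {lk} vs {rk}".strip(": ")
        )
    if len(left) != len(right):
        raise AlignmentError(
            f"{context}: grids have {len(left)} vs {len(right)} cells".strip(": ")
        )
    la = left[lk].reset_index(drop=True)
    ra = right[rk].reset_index(drop=True)
    neq = (la != ra).any(axis=1)
    if neq.any():
        bad_left = la[neq].head(3).to_dict("records")
        bad_right = ra[neq].head(3).to_dict("records")
        raise AlignmentError(
            f"{context}: misaligned cells (first shown): {bad_left} vs {bad_right}".strip(": ")
        )


class DrawSet:
    """A demographic grid whose cells hold vectors of Monte-Carlo draws.

    Parameters
    ----------
    index
        Demographic key frame (one row per cell); copied and re-indexed.
    draws
        Array of shape ``(n_cells, n_draws)``.
    """

    def __init__(self, index: pd.DataFrame, draws: np.ndarray):
        draws = np.asarray(draws, dtype=float)
        if draws.ndim == 1:
            draws = draws[:, None]
        if draws.ndim != 2:
            raise ValueError("draws must be a (n_cells, n_draws) array")
        if len(index) != draws.shape[0]:
            raise ValueError(
                f"index has {len(index)} cells but draws has {draws.shape[0]} rows"
            )
        if draws.shape[1] < 1:
            raise ValueError("need at least one draw")
        if not np.all(np.isfinite(draws)):
            raise ValueError("draws contain non-finite values")
        self.index = index.reset_index(drop=True).copy()
        self.draws = draws

    # -- basic protocol ----------------------------------------------------
    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @property
    def n_cells(self) -> int:
        return self.draws.shape[0]

    def __len__(self) -> int:
        return self.n_cells

    def copy(self) -> "DrawSet":
        return DrawSet(self.index, self.draws.copy())

    @classmethod
    def constant(cls, index: pd.DataFrame, values: np.ndarray, n_draws: int) -> "DrawSet":
        """Build a DrawSet whose draws are all equal to *values* (no uncertainty)."""
        values = np.asarray(values, dtype=float)
        return cls(index, np.repeat(values[:, None], n_draws, axis=1))

    # -- alignment ---------------------------------------------------------
    def _binary(self, other, op: Callable, opname: str) -> "DrawSet":
        if isinstance(other, DrawSet):
            check_aligned(self.index, other.index, context=opname)
            if other.n_draws != self.n_draws:
                raise AlignmentError(
                    f"{opname}: draw counts differ ({self.n_draws} vs {other.n_draws})"
                )
            return DrawSet(self.index, op(self.draws, other.draws))
        return DrawSet(self.index, op(self.draws, other))

    def __add__(self, other):
        return self._binary(other, np.add, "add")

    def __sub__(self, other):
        return self._binary(other, np.subtract, "subtract")

    def __mul__(self, other):
        return self._binary(other, np.multiply, "multiply")

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, np.divide, "divide")

    def map(self, func: Callable[[np.ndarray], np.ndarray]) -> "DrawSet":
        return DrawSet(self.index, func(self.draws))

    def clip(self, lo=None, hi=None) -> "DrawSet":
        return DrawSet(self.index, np.clip(self.draws, lo, hi))

    # -- aggregation -------------------------------------------------------
    def aggregate(self, over: Sequence[str]) -> "DrawSet":
        """Sum draws over the key dimensions in *over* (draw-wise)."""
        keep = [c for c in key_columns_of(self.index) if c not in set(over)]
        if not keep:
            total = self.draws.sum(axis=0, keepdims=True)
            return DrawSet(pd.DataFrame({"location": ["all"]}), total)
        frame = self.index[keep].copy()
        codes, uniques = pd.factorize(
            pd.MultiIndex.from_frame(frame) if len(keep) > 1 else frame[keep[0]]
        )
        out = np.zeros((len(uniques), self.n_draws))
        np.add.at(out, codes, self.draws)
        if len(keep) > 1:
            new_index = pd.DataFrame(list(uniques), columns=keep)
        else:
            new_index = pd.DataFrame({keep[0]: list(uniques)})
        return DrawSet(new_index, out)

    def total(self) -> np.ndarray:
        """Draw-wise grand total over all cells (vector of length n_draws)."""
        return self.draws.sum(axis=0)

    def mean(self) -> pd.DataFrame:
        """Key frame plus the across-draw mean as a ``value`` column."""
        out = self.index.copy()
        out["value"] = self.draws.mean(axis=1)
        return out

    def select(self, **conditions) -> "DrawSet":
        """Subset cells by equality conditions on key columns."""
        mask = np.ones(len(self.index), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.index[col] == val).to_numpy()
        return DrawSet(self.index[mask], self.draws[mask])


def make_grid(
    locations: Iterable,
    age_edges: np.ndarray,
    sexes: Iterable[str] = ("female", "male"),
    years: Iterable[int] = (2021,),
) -> pd.DataFrame:
    """Cartesian demographic key frame over the given dimensions."""
    age_edges = np.asarray(age_edges, dtype=float)
    groups = list(zip(age_edges[:-1], age_edges[1:]))
    rows = [
        (loc, a0, a1, sex, yr)
        for loc in locations
        for sex in sexes
        for yr in years
        for a0, a1 in groups
    ]
    return pd.DataFrame(rows, columns=list(KEY_COLUMNS))
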