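"""Curveball degree-preserving randomization of binary mutation matrices.

The patient×gene incidence matrix is randomized by repeated "trades": two
rows exchange a random subset of the columns where they differ, keeping each
row's total.  Row and column sums are invariant under every trade, and the
stationary distribution is uniform over all binary matrices with the given
margins — the property that distinguishes curveball from naive swap schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd


@dataclass
class BinaryMutationMatrix:
    """Patients (rows) × genes (columns) 0/1 incidence."""

    rows: list[str]
    cols: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.rows), len(self.cols)):
            raise ValueError("cells shape does not match row/column ids")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be 0/1")
        if len(set(self.rows)) != len(self.rows) or len(set(self.cols)) != len(self.cols):
            raise ValueError("row/column ids must be unique")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryMutationMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.rows, columns=self.cols)


def curveball_trade(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One trade between two random rows; returns a new matrix.

    Columns where the rows differ are redistributed uniformly at random,
    preserving each row's count; shared columns are untouched.  With fewer
    than two rows the input is returned unchanged.
    """
    out = np.array(matrix, dtype=np.int8, copy=True)
    _trade_inplace(out, rng)
    return out


def _trade_inplace(m: np.ndarray, rng: np.random.Generator) -> None:
    n_rows = m.shape[0]
    if n_rows < 2:
        return
    i, j = rng.choice(n_rows, size=2, replace=False)
    ri, rj = m[i], m[j]
    diff = np.flatnonzero(ri != rj)
    if diff.size == 0:
        return
    a = int(ri[diff].sum())  # ones row i holds among the contested columns
    perm = rng.permutation(diff)
    ri[diff] = 0
    rj[diff] = 0
    ri[perm[:a]] = 1
    rj[perm[a:]] = 1


def curveball_randomize(
    matrix: np.ndarray,
    rng: np.random.Generator,
    n_trades: int | None = None,
) -> np.ndarray:
    """Apply ``n_trades`` successive trades (default 5 × n_rows, the
    published mixing heuristic).  Margins are conserved exactly."""
    out = np.array(matrix, dtype=np.int8, copy=True)
    if n_trades is None:
        n_trades = 5 * out.shape[0]
    for _ in range(n_trades):
        _trade_inplace(out, rng)
    return out


def permuted_ensemble(
    matrix: np.ndarray,
    rng: np.random.Generator,
    n_matrices: int = 10_000,
    n_trades: int | None = None,
) -> Iterator[np.ndarray]:
    """Stream independent randomizations, each from a fresh burn-in of the
    observed matrix, so ensemble members are exchangeable.  Memory stays at
    one matrix."""
    for _ in range(n_matrices):
        yield curveball_randomize(matrix, rng, n_trades)
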