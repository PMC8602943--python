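"""Rectangular cell grid: short-range neighborhoods, no-flux boundaries,
and the synchronous division protocol.

Cells are indexed flat, row-major (index = row * n_cols + col).  The
communication neighborhood of a cell is every cell within ``hops`` steps
on the lattice graph, self excluded; with 4-connectivity this is the set
of cells at Manhattan distance <= hops, giving 12 neighbors for interior
cells at the default hops=2.  No-flux boundaries simply truncate the
neighborhood — no wrap-around, no ghost cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["Lattice", "DivisionSchedule", "divide", "snapshot_frame"]


def _offsets(hops: int, connectivity: str) -> list[tuple[int, int]]:
    if connectivity == "von_neumann":
        dist = lambda di, dj: abs(di) + abs(dj)
    elif connectivity == "moore":
        dist = lambda di, dj: max(abs(di), abs(dj))
    else:
        raise ValueError(f"unknown connectivity {connectivity!r}")
    return [(di, dj)
            for di in range(-hops, hops + 1)
            for dj in range(-hops, hops + 1)
            if 0 < dist(di, dj) <= hops]


@dataclass(frozen=True)
class Lattice:
    """An ``n_rows x n_cols`` grid with hop-limited neighborhoods.

    ``connectivity`` chooses what one hop means: ``"von_neumann"``
    (4-connected, the default) or ``"moore"`` (8-connected).  The boundary
    condition is always no-flux.
    """

    n_rows: int
    n_cols: int
    hops: int = 2
    connectivity: str = "von_neumann"
    boundary: str = field(default="no-flux", init=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.hops < 1:
            raise ValueError("hops must be >= 1")
        _offsets(self.hops, self.connectivity)  # validates connectivity

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"({row}, {col}) not on a {self.shape} grid")
        return row * self.n_cols + col

    def rowcol(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.n_cells:
            raise IndexError(f"index {index} not on a {self.shape} grid")
        return divmod(index, self.n_cols)

    def positions(self) -> np.ndarray:
        """(n_cells, 2) array of (col, row) coordinates in lattice units
        (1 unit = 1 cell diameter)."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        return np.column_stack([cols, rows]).astype(float)

    def neighborhood(self, index: int) -> frozenset[int]:
        """Flat indices of all cells within ``hops`` of ``index``, self
        excluded and truncated at the boundary."""
        r, c = self.rowcol(index)
        out = []
        for di, dj in _offsets(self.hops, self.connectivity):
            rr, cc = r + di, c + dj
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(rr * self.n_cols + cc)
        return frozenset(out)

    def neighbor_lists(self) -> list[list[int]]:
        return [sorted(self.neighborhood(i)) for i in range(self.n_cells)]

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Boolean neighborhood adjacency as a sparse CSR matrix."""
        rows, cols = [], []
        for i, ns in enumerate(self.neighbor_lists()):
            rows.extend([i] * len(ns))
            cols.extend(ns)
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(self.n_cells, self.n_cells))

    def sensing_matrix(self) -> sparse.csr_matrix:
        """Row-stochastic operator averaging a per-cell field over each
        cell's neighborhood (the aggregation of the sensing rule).

        Rows of isolated cells (possible only on degenerate grids) are
        left all-zero; the simulator rejects such grids up front.
        """
        adj = self.adjacency_matrix()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        return sparse.diags(inv) @ adj


@dataclass(frozen=True)
class DivisionSchedule:
    """Alternating-axis synchronous division schedule.

    The default reproduces the five-cycle growth experiment: starting from
    a 5x10 grid, divisions along alternating axes sequentially yield
    10x10, 10x20, 20x20, 20x40 and 40x40 lattices.  ``axis='horizontal'``
    doubles the number of rows (cleavage plane horizontal, daughters
    stacked vertically is the other reading; here the axis names the grid
    axis being doubled as printed in the shape sequence) and
    ``axis='vertical'`` doubles the number of columns.
    """

    n_cycles: int = 5
    start_shape: tuple[int, int] = (5, 10)
    first_axis: str = "horizontal"

    def __post_init__(self) -> None:
        if self.first_axis not in ("horizontal", "vertical"):
            raise ValueError("first_axis must be 'horizontal' or 'vertical'")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def axes(self) -> list[str]:
        other = "vertical" if self.first_axis == "horizontal" else "horizontal"
        return [self.first_axis if k % 2 == 0 else other
                for k in range(self.n_cycles)]

    def shapes(self) -> list[tuple[int, int]]:
        """Grid shapes after each of the ``n_cycles`` divisions."""
        r, c = self.start_shape
        out = []
        for axis in self.axes():
            if axis == "horizontal":
                r *= 2
            else:
                c *= 2
            out.append((r, c))
        return out


def divide(lattice: Lattice, arrays, axis: str):
    """Synchronous division of every cell along one grid axis.

    Each mother cell is replaced by two adjacent daughters that carry
    exact copies of the mother's entries in every array of ``arrays``
    (per-cell states, per-cell parameters, any frozen inputs).  Arrays
    must be flat row-major with leading dimension ``lattice.n_cells``;
    trailing dimensions are preserved.

    Returns ``(new_lattice, new_arrays)`` with the chosen axis doubled.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    r, c = lattice.shape
    new_arrays = []
    for arr in arrays:
        arr = np.asarray(arr)
        if arr.shape[0] != lattice.n_cells:
            raise ValueError(
                f"array leading dimension {arr.shape[0]} does not match "
                f"lattice cell count {lattice.n_cells}")
        grid = arr.reshape((r, c) + arr.shape[1:])
        rep_axis = 0 if axis == "horizontal" else 1
        doubled = np.repeat(grid, 2, axis=rep_axis)
        new_arrays.append(doubled.reshape((2 * lattice.n_cells,) + arr.shape[1:]))
    new_shape = (2 * r, c) if axis == "horizontal" else (r, 2 * c)
    new_lat = Lattice(*new_shape, hops=lattice.hops,
                      connectivity=lattice.connectivity)
    return new_lat, new_arrays


def snapshot_frame(lattice: Lattice, states: np.ndarray, labels=None,
                   cycle: int | None = None) -> pd.DataFrame:
    """Long-form snapshot of a population: row, col, N, G, F, label, cycle."""
    states = np.asarray(states, float)
    rows, cols = np.divmod(np.arange(lattice.n_cells), lattice.n_cols)
    df = pd.DataFrame({
        "row": rows, "col": cols,
        "N": states[:, 0], "G": states[:, 1], "F": states[:, 2],
    })
    df["label"] = labels if labels is not None else ""
    df["cycle"] = cycle if cycle is not None else -1
    return df
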