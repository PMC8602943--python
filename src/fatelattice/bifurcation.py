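"""Two-cell coupled system: fixed points, stability and branch scans.

The minimal system of two mutually sensing cells (each cell's sensed FGF4
is the other cell's secreted FGF4) exhibits an inhomogeneous steady state
(IHSS) — a stable fixed point in which the two cells occupy mutually
exclusive NANOG-high / GATA6-high expression states that exists only by
virtue of the coupling.  The two cell-states of the stable IHSS serve as
the anchor states of the initial-condition construction mu_ics(p).

Continuation is implemented as dense multi-start root finding with
warm-started tracking across the parameter grid; fold geometry is
recovered by grid refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import (CellState, ModelParams, transcribed_jacobian_blocks,
                         transcribed_rhs)

__all__ = [
    "FixedPoint",
    "BranchDiagram",
    "two_cell_rhs",
    "two_cell_jacobian",
    "find_fixed_points",
    "branch_scan",
    "anchor_states",
]

_DEDUP_TOL = 1e-5
_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class FixedPoint:
    """A root of the 6-dimensional two-cell system.

    ``x`` is ordered (N1, G1, F1, N2, G2, F2).  ``stability`` is derived
    from the Jacobian eigenvalue real parts ('stable', 'unstable' or
    'saddle'); ``kind`` is 'HSS' when the two cells coincide within
    tolerance and 'IHSS' otherwise.
    """

    x: tuple[float, ...]
    stability: str
    kind: str
    eigenvalues: tuple[complex, ...]

    @property
    def cell1(self) -> CellState:
        return CellState(*self.x[:3])

    @property
    def cell2(self) -> CellState:
        return CellState(*self.x[3:])

    def swapped(self) -> "FixedPoint":
        return replace(self, x=tuple(self.x[3:]) + tuple(self.x[:3]))


def _kin(params: ModelParams) -> dict:
    return dict(alpha_n=params.alpha_n, alpha_nf=params.alpha_nf,
                alpha_g=params.alpha_g, alpha_f=params.alpha_f,
                beta=params.beta, eta=params.eta, gamma=params.gamma,
                delta=params.delta, deg_n=params.deg_n, deg_g=params.deg_g,
                deg_f=params.deg_f, lam=params.lam)


def _sensed_pair(x: np.ndarray, coupling: str, params: ModelParams):
    if coupling == "mutual":
        return x[5], x[2]  # cell 1 senses F2, cell 2 senses F1
    if coupling == "external":
        return params.f_ext, params.f_ext
    raise ValueError(f"unknown coupling {coupling!r}")


def two_cell_rhs(x: np.ndarray, params: ModelParams,
                 coupling: str = "mutual") -> np.ndarray:
    """Deterministic right-hand side of the two-cell system.

    ``coupling='mutual'`` means each cell senses the other's secreted
    FGF4 (the neighborhood mean over a single neighbor);
    ``coupling='external'`` replaces sensing by the fixed input
    ``params.f_ext``, decoupling the cells.
    """
    x = np.asarray(x, float)
    s1, s2 = _sensed_pair(x, coupling, params)
    kin = _kin(params)
    out = np.empty(6)
    out[0:3] = transcribed_rhs(x[0], x[1], x[2], s1, **kin)
    out[3:6] = transcribed_rhs(x[3], x[4], x[5], s2, **kin)
    return out


def two_cell_jacobian(x: np.ndarray, params: ModelParams,
                      coupling: str = "mutual") -> np.ndarray:
    """Analytic 6x6 Jacobian of :func:`two_cell_rhs`."""
    x = np.asarray(x, float)
    s1, s2 = _sensed_pair(x, coupling, params)
    kin = _kin(params)
    J = np.zeros((6, 6))
    for cell, (n, g, f, s) in enumerate(((x[0], x[1], x[2], s1),
                                         (x[3], x[4], x[5], s2))):
        b = transcribed_jacobian_blocks(n, g, f, s, **kin)
        o = 3 * cell
        J[o + 0, o + 0] = b[("N", "N")]
        J[o + 0, o + 1] = b[("N", "G")]
        J[o + 1, o + 1] = b[("G", "G")]
        J[o + 1, o + 0] = b[("G", "N")]
        J[o + 2, o + 2] = b[("F", "F")]
        J[o + 2, o + 1] = b[("F", "G")]
        if coupling == "mutual":
            # dN_i/dt depends on the partner's F through the sensed input
            J[o + 0, (o + 5) % 6] = b[("N", "S")]
    return J


def _classify_stability(eigvals: np.ndarray) -> str:
    re_parts = eigvals.real
    if np.all(re_parts < -1e-8):
        return "stable"
    if np.all(re_parts > 1e-8):
        return "unstable"
    return "saddle"


def _make_fixed_point(x: np.ndarray, params: ModelParams,
                      coupling: str, hss_tol: float = 1e-6) -> FixedPoint:
    eig = np.linalg.eigvals(two_cell_jacobian(x, params, coupling))
    # an IHSS is a coupling-maintained state by definition: with the
    # cells decoupled ('external'), mixed product states are not IHSS and
    # every entry is reported as HSS
    if coupling == "external":
        kind = "HSS"
    else:
        kind = "HSS" if np.max(np.abs(x[:3] - x[3:])) < hss_tol else "IHSS"
    return FixedPoint(x=tuple(float(v) for v in x),
                      stability=_classify_stability(eig), kind=kind,
                      eigenvalues=tuple(complex(v) for v in eig))


def find_fixed_points(params: ModelParams, coupling: str = "mutual",
                      n_starts: int = 200,
                      rng: np.random.Generator | None = None,
                      extra_starts: np.ndarray | None = None,
                      ) -> list[FixedPoint]:
    """Deduplicated fixed points of the two-cell system from multi-start
    root finding with the analytic Jacobian.

    The swap counterpart of every inhomogeneous root is reported as well
    (the system is equivariant under exchanging the two cells).
    Non-converged starts are dropped and counted (``.n_failed`` attribute
    on the returned list is not kept; failures simply reduce coverage —
    ``n_starts`` should stay >= 100).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    scale = max(params.alpha_n + params.alpha_nf, params.alpha_g,
                params.alpha_f) / min(params.deg_n, params.deg_g, params.deg_f)
    starts = rng.uniform(0.0, scale, size=(n_starts, 6))
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([np.atleast_2d(extra_starts), starts])
    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = optimize.root(two_cell_rhs, x0, args=(params, coupling),
                            jac=two_cell_jacobian, method="hybr")
        if not sol.success:
            continue
        x = sol.x
        if np.any(x < -1e-9):
            continue
        x = np.clip(x, 0.0, None)
        if np.max(np.abs(two_cell_rhs(x, params, coupling))) > _RESIDUAL_TOL:
            continue
        if not any(np.max(np.abs(x - r)) < _DEDUP_TOL for r in roots):
            roots.append(x)
    # add swap counterparts of asymmetric roots
    for x in list(roots):
        xs = np.concatenate([x[3:], x[:3]])
        if not any(np.max(np.abs(xs - r)) < _DEDUP_TOL for r in roots):
            roots.append(xs)
    return [_make_fixed_point(x, params, coupling) for x in roots]


@dataclass
class BranchDiagram:
    """Fixed points tracked across a parameter grid.

    ``table`` is tidy: one row per (parameter value, fixed point) with the
    six state coordinates, stability, kind and a branch id assigned by
    state-space continuity (nearest predecessor within a jump tolerance;
    a lost branch simply ends — folds appear as branch endpoints).
    """

    param_name: str
    grid: np.ndarray
    table: pd.DataFrame

    def branches(self) -> dict[int, pd.DataFrame]:
        return {int(b): df for b, df in self.table.groupby("branch")}


_STATE_COLS = ["N1", "G1", "F1", "N2", "G2", "F2"]


def branch_scan(param_name: str, grid, params: ModelParams,
                coupling: str = "mutual", n_starts: int = 200,
                rng: np.random.Generator | None = None,
                jump_tol: float = 0.5) -> BranchDiagram:
    """Track fixed points across a monotone parameter grid.

    At each grid value the previous solutions are used as warm starts in
    addition to fresh random starts.
    """
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or len(grid) < 2 or not (np.all(np.diff(grid) > 0)
                                               or np.all(np.diff(grid) < 0)):
        raise ValueError("grid must be a monotone 1-D array of length >= 2")
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    prev: np.ndarray | None = None
    branch_ends: dict[int, np.ndarray] = {}
    next_branch = 0
    for value in grid:
        p = replace(params, **{param_name: value})
        fps = find_fixed_points(p, coupling, n_starts, rng, extra_starts=prev)
        prev = np.array([fp.x for fp in fps]) if fps else None
        new_ends: dict[int, np.ndarray] = {}
        for fp in fps:
            x = np.array(fp.x)
            best, best_d = None, np.inf
            for b, end in branch_ends.items():
                d = np.max(np.abs(end - x))
                if d < best_d:
                    best, best_d = b, d
            if best is not None and best_d < jump_tol and best not in new_ends:
                b = best
            else:
                b = next_branch
                next_branch += 1
            new_ends[b] = x
            rows.append({param_name: value, "branch": b,
                         **dict(zip(_STATE_COLS, fp.x)),
                         "stability": fp.stability, "kind": fp.kind})
        branch_ends = new_ends
    return BranchDiagram(param_name=param_name, grid=grid,
                         table=pd.DataFrame(rows))


def anchor_states(params: ModelParams,
                  rng: np.random.Generator | None = None,
                  n_starts: int = 200) -> tuple[CellState, CellState]:
    """The two opposite-fate anchor states used by mu_ics(p).

    Returns ``(mu_Gneg_Npos, mu_Gpos_Nneg)``: the NANOG-high and
    GATA6-high cell-states of the stable IHSS of the two-cell system.
    """
    fps = find_fixed_points(params, "mutual", n_starts, rng)
    stable_ihss = [fp for fp in fps
                   if fp.kind == "IHSS" and fp.stability == "stable"]
    if not stable_ihss:
        raise ValueError(
            "no stable IHSS at these parameters; check the parameter set "
            "(the coupled system must support an inhomogeneous state)")
    fp = stable_ihss[0]
    c1, c2 = fp.cell1, fp.cell2
    npos, gpos = (c1, c2) if c1.n - c1.g >= c2.n - c2.g else (c2, c1)
    return npos, gpos
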