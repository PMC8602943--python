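"""Population-level integration of the coupled lattice model.

The stochastic model adds multiplicative noise ``sigma * X * dW`` to every
species of the deterministic circuit and is advanced with the Milstein
scheme at fixed step ``dt``.  Cell-to-cell heterogeneity enters as
independent Gaussian perturbations (s.d. ``heterogeneity_sd``) of every
kinetic parameter of every cell; integration constants (dt, sigma) and the
global time scale lam are shared by the whole population.

Communication modes:

* ``wildtype`` — each cell senses the mean secreted FGF4 of its lattice
  neighborhood (hops <= 2 by default),
* ``mutant`` — no communication; every cell senses the constant ``f_ext``,
* ``wildtype_plus_external`` — neighborhood mean plus ``f_ext_add``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import DivisionSchedule, Lattice, divide
from .model_core import KINETIC_FIELDS, MODES, CellState, ModelParams, transcribed_rhs

__all__ = [
    "SimulationConfig",
    "PopulationResult",
    "CycleSnapshot",
    "sample_heterogeneous_params",
    "sample_initial_conditions",
    "drift",
    "milstein_update",
    "milstein_step",
    "integrate",
    "relax_deterministic",
    "run_division_experiment",
]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one population run.

    ``t_end`` is the duration of one stochastic phase in model time units
    (with lam=50 the deterministic relaxation time is ~0.02 units, so the
    default 20 units leaves population summaries stationary).  ``init_p``
    places the initial-condition mean on the segment between the
    NANOG-high and GATA6-high anchor states, partitioning it in
    proportion p; ``init_sd`` is the spread of the per-coordinate
    Gaussians in state units.
    """

    shape: tuple[int, int] = (10, 10)
    mode: str = "wildtype"
    params: ModelParams = field(default_factory=ModelParams)
    heterogeneity_sd: float = 0.02
    init_p: float = 0.5
    init_sd: float = 0.05
    t_end: float = 20.0
    seed: int = 0
    n_realizations: int = 1
    relax_tol: float = 1e-6
    relax_t_max: float = 50.0
    hops: int = 2
    connectivity: str = "von_neumann"

    def __post_init__(self) -> None:
        if not 0.0 <= self.init_p <= 1.0:
            raise ValueError("init_p must lie in [0, 1]")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    def make_lattice(self) -> Lattice:
        return Lattice(*self.shape, hops=self.hops,
                       connectivity=self.connectivity)


@dataclass
class CycleSnapshot:
    """End-of-cycle state of a division experiment (post-relaxation)."""

    cycle: int
    lattice: Lattice
    states: np.ndarray
    converged: bool


@dataclass
class PopulationResult:
    final_states: np.ndarray
    cell_params: dict[str, np.ndarray]
    seed: int
    snapshots: list[CycleSnapshot] = field(default_factory=list)

    def cell_state(self, i: int) -> CellState:
        return CellState(*self.final_states[i])


# ---------------------------------------------------------------------------
# sampling

def sample_heterogeneous_params(base: ModelParams, sd: float, n: int,
                                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-cell kinetic parameters: Normal(base, sd), truncated at 0.

    Returns a mapping from kinetic field name to an array of length ``n``.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    out = {}
    for name in KINETIC_FIELDS:
        base_val = getattr(base, name)
        if sd == 0:
            out[name] = np.full(n, base_val)
        else:
            out[name] = np.clip(rng.normal(base_val, sd, size=n), 0.0, None)
    return out


def sample_initial_conditions(p: float, sd: float, n: int,
                              anchors: tuple[CellState, CellState],
                              rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` initial states around mu_ics(p).

    The mean is placed on the line segment connecting the GATA6-;NANOG+
    anchor (p=0 end) and the GATA6+;NANOG- anchor (p=1 end), partitioning
    it in proportion p; each coordinate is sampled independently
    Normal(mean, sd), truncated at 0.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    npos, gpos = (np.asarray(a, float) for a in anchors)
    mu = (1.0 - p) * npos + p * gpos
    return np.clip(rng.normal(mu, sd, size=(n, 3)), 0.0, None)


# ---------------------------------------------------------------------------
# stepping

def drift(states: np.ndarray, sensed: np.ndarray,
          cell_params: dict[str, np.ndarray], lam: float) -> np.ndarray:
    """Deterministic right-hand side for the whole population, (n, 3)."""
    n_, g_, f_ = states[:, 0], states[:, 1], states[:, 2]
    dn, dg, df = transcribed_rhs(n_, g_, f_, sensed, lam=lam,
                                 **{k: cell_params[k] for k in KINETIC_FIELDS})
    return np.column_stack([dn, dg, df])


def milstein_update(states: np.ndarray, f: np.ndarray, dt: float,
                    sigma: float, dw: np.ndarray) -> np.ndarray:
    """The Milstein update rule for multiplicative noise sigma*X*dW:

    X <- X + f dt + sigma X dW + 0.5 sigma^2 X (dW^2 - dt),

    clamped at 0 (multiplicative noise preserves the origin exactly, but
    a finite step can overshoot below zero).  With sigma=0 this is
    exactly the explicit Euler step.
    """
    new = states + f * dt + sigma * states * dw \
        + 0.5 * sigma**2 * states * (dw**2 - dt)
    return np.clip(new, 0.0, None)


def milstein_step(states: np.ndarray, sensed: np.ndarray,
                  cell_params: dict[str, np.ndarray], dt: float, sigma: float,
                  rng: np.random.Generator, lam: float) -> np.ndarray:
    """One Milstein step for every cell and species (drift from the
    deterministic circuit, one Brownian increment per cell and species)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    f = drift(states, sensed, cell_params, lam)
    if sigma == 0:
        return np.clip(states + f * dt, 0.0, None)
    dw = rng.normal(0.0, np.sqrt(dt), size=states.shape)
    return milstein_update(states, f, dt, sigma, dw)


def _check_finite(states: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(states)):
        cell, var = np.argwhere(~np.isfinite(states))[0]
        raise FloatingPointError(
            f"non-finite state at step {step}, cell {int(cell)}, "
            f"variable {'NGF'[int(var)]}")


def _sensed_fn(mode: str, lattice: Lattice, params: ModelParams,
               frozen: np.ndarray | None = None):
    """Build a function F -> sensed-input array for one communication rule."""
    if frozen is not None:
        frozen = np.asarray(frozen, float)
        return lambda F: frozen
    if mode == "mutant":
        return lambda F: np.full(lattice.n_cells, params.f_ext)
    M = lattice.sensing_matrix()
    deg = np.asarray(lattice.adjacency_matrix().sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("communicating mode on a lattice with isolated cells")
    if mode == "wildtype":
        return lambda F: M @ F
    return lambda F: M @ F + params.f_ext_add  # wildtype_plus_external


def integrate(config: SimulationConfig, lattice: Lattice | None = None,
              initial_states: np.ndarray | None = None,
              cell_params: dict[str, np.ndarray] | None = None,
              rng: np.random.Generator | None = None,
              anchors: tuple[CellState, CellState] | None = None,
              frozen_sensed: np.ndarray | None = None) -> PopulationResult:
    """Advance all cells synchronously for ``config.t_end`` time units.

    Sensed inputs are recomputed from current neighbor FGF4 levels at
    every step in communicating modes.  If ``initial_states`` is omitted
    they are drawn around mu_ics(config.init_p) using ``anchors`` (which
    are then required).  Identical seeds give bit-identical results.
    """
    if lattice is None:
        lattice = config.make_lattice()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = lattice.n_cells
    if cell_params is None:
        cell_params = sample_heterogeneous_params(
            config.params, config.heterogeneity_sd, n, rng)
    if initial_states is None:
        if anchors is None:
            raise ValueError("anchors are required when initial_states is None")
        initial_states = sample_initial_conditions(
            config.init_p, config.init_sd, n, anchors, rng)
    states = np.array(initial_states, float, copy=True)
    if states.shape != (n, 3):
        raise ValueError(f"initial states shape {states.shape} != ({n}, 3)")
    p = config.params
    sensed_of = _sensed_fn(config.mode, lattice, p, frozen_sensed)
    n_steps = int(round(config.t_end / p.dt))
    for step in range(n_steps):
        sensed = sensed_of(states[:, 2])
        states = milstein_step(states, sensed, cell_params, p.dt, p.sigma,
                               rng, p.lam)
        _check_finite(states, step)
    return PopulationResult(final_states=states, cell_params=cell_params,
                            seed=config.seed)


def relax_deterministic(states: np.ndarray, lattice: Lattice,
                        cell_params: dict[str, np.ndarray],
                        params: ModelParams, mode: str = "wildtype",
                        frozen_sensed: np.ndarray | None = None,
                        tol: float = 1e-6, t_max: float = 50.0,
                        dt: float | None = None) -> tuple[np.ndarray, bool]:
    """Integrate with sigma=0 until ``max |rhs| < tol`` or ``t_max``.

    Returns (steady states, converged flag); non-convergence is flagged,
    never silent.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    dt = params.dt if dt is None else dt
    states = np.array(states, float, copy=True)
    sensed_of = _sensed_fn(mode, lattice, params, frozen_sensed)
    n_steps = int(round(t_max / dt))
    for step in range(n_steps):
        sensed = sensed_of(states[:, 2])
        f = drift(states, sensed, cell_params, params.lam)
        if np.max(np.abs(f)) < tol:
            return states, True
        states = np.clip(states + f * dt, 0.0, None)
        _check_finite(states, step)
    sensed = sensed_of(states[:, 2])
    f = drift(states, sensed, cell_params, params.lam)
    return states, bool(np.max(np.abs(f)) < tol)


# ---------------------------------------------------------------------------
# division experiment

_SWITCH_RE = re.compile(r"^switch_off_after_cycle_(\d+)$")


def _parse_comm(comm: str) -> tuple[str, int | None]:
    if comm in ("always", "never"):
        return comm, None
    m = _SWITCH_RE.match(comm)
    if m:
        return "switch", int(m.group(1))
    raise ValueError(
        f"comm must be 'always', 'never' or 'switch_off_after_cycle_<k>', "
        f"got {comm!r}")


def run_division_experiment(config: SimulationConfig,
                            schedule: DivisionSchedule | None = None,
                            comm: str = "always",
                            anchors: tuple[CellState, CellState] | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> list[CycleSnapshot]:
    """Growing-population experiment with synchronous divisions.

    Each cycle runs a stochastic phase on the current grid, doubles the
    grid along the scheduled axis (daughters inherit the mother's state
    and parameter set exactly), relaxes the collective state
    deterministically, and records a snapshot.  ``comm`` selects
    communication throughout (``always``), none at all (``never``:
    mutant-mode sensing at the configured f_ext), or the hybrid model
    (``switch_off_after_cycle_k``: wild-type communication up to and
    including cycle k, after which each cell's sensed input is frozen at
    its value at the switch and inherited by its daughters).

    Cell states are initialized with Gaussians at mu_ics(config.init_p)
    (the proportioning midpoint 0.5 by default).
    """
    if schedule is None:
        schedule = DivisionSchedule()
    kind, k_switch = _parse_comm(comm)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if anchors is None:
        from .bifurcation import anchor_states
        anchors = anchor_states(config.params)

    lattice = Lattice(*schedule.start_shape, hops=config.hops,
                      connectivity=config.connectivity)
    cell_params = sample_heterogeneous_params(
        config.params, config.heterogeneity_sd, lattice.n_cells, rng)
    states = sample_initial_conditions(
        config.init_p, config.init_sd, lattice.n_cells, anchors, rng)

    mode = "mutant" if kind == "never" else config.mode
    cfg = replace(config, mode=mode)
    frozen: np.ndarray | None = None
    snapshots: list[CycleSnapshot] = []
    for cycle, axis in zip(range(1, schedule.n_cycles + 1), schedule.axes()):
        res = integrate(cfg, lattice, states, cell_params, rng,
                        frozen_sensed=frozen)
        states = res.final_states
        param_arrays = [cell_params[k] for k in KINETIC_FIELDS]
        arrays = [states] + param_arrays + ([frozen] if frozen is not None else [])
        lattice, new_arrays = divide(lattice, arrays, axis)
        states = new_arrays[0]
        cell_params = dict(zip(KINETIC_FIELDS, new_arrays[1:len(KINETIC_FIELDS) + 1]))
        if frozen is not None:
            frozen = new_arrays[-1]
        states, converged = relax_deterministic(
            states, lattice, cell_params, cfg.params, mode,
            frozen_sensed=frozen, tol=config.relax_tol,
            t_max=config.relax_t_max)
        snapshots.append(CycleSnapshot(cycle, lattice, states.copy(), converged))
        if kind == "switch" and cycle == k_switch:
            frozen = np.asarray(_sensed_fn(config.mode, lattice,
                                           config.params)(states[:, 2]))
    return snapshots
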