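"""Cell-intrinsic NANOG/GATA6/FGF4 circuit and the neighborhood sensing rule.

Each cell carries three dimensionless species: NANOG (``N``), GATA6 (``G``)
and secreted FGF4 (``F``).  NANOG and GATA6 repress each other; GATA6
additionally represses FGF4 production, and extracellular FGF4 sensed from
the neighborhood represses NANOG production.  All species degrade linearly
and the whole right-hand side is scaled by a single kinetic constant
``lam`` that sets the time unit.

Everything in this module is a pure function of its arguments; the lattice
and the integrators live elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "CellState",
    "SensedInput",
    "ModelParams",
    "KINETIC_FIELDS",
    "MODES",
    "transcribed_rhs",
    "transcribed_jacobian_blocks",
    "deterministic_rhs",
    "sensed_fgf",
]


class CellState(NamedTuple):
    """Expression state (N, G, F) of a single cell, all components >= 0."""

    n: float
    g: float
    f: float


class SensedInput(NamedTuple):
    """Extracellular FGF4 concentration sensed by one cell."""

    value: float


#: Parameters that are biological traits of a cell and therefore subject to
#: cell-to-cell heterogeneity.  Integration constants (dt, sigma) and the
#: global time scale lam are deliberately excluded.
KINETIC_FIELDS = (
    "alpha_n",
    "alpha_nf",
    "alpha_g",
    "alpha_f",
    "beta",
    "eta",
    "gamma",
    "delta",
    "deg_n",
    "deg_g",
    "deg_f",
)

MODES = ("wildtype", "mutant", "wildtype_plus_external")


@dataclass
class ModelParams:
    """Rate constants, Hill coefficients and integration constants.

    Defaults are the reference parameter set: production rates
    alpha_n=2.5, alpha_nf=0.5, alpha_g=3, alpha_f=3; all four Hill
    coefficients equal 2; degradation rates 1 with lam=50 acting as the
    scaling kinetic parameter; multiplicative noise sigma=0.1 integrated
    at dt=0.01.  ``f_ext`` is the external FGF4 input used by the
    non-communicating (mutant) mode and ``f_ext_add`` the additive input
    of the supplemented wild-type mode.
    """

    alpha_n: float = 2.5
    alpha_nf: float = 0.5
    alpha_g: float = 3.0
    alpha_f: float = 3.0
    beta: float = 2.0
    eta: float = 2.0
    gamma: float = 2.0
    delta: float = 2.0
    lam: float = 50.0
    deg_n: float = 1.0
    deg_g: float = 1.0
    deg_f: float = 1.0
    sigma: float = 0.1
    dt: float = 0.01
    f_ext: float = 1.2
    f_ext_add: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_n", "alpha_nf", "alpha_g", "alpha_f",
                     "deg_n", "deg_g", "deg_f", "lam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("beta", "eta", "gamma", "delta"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    # -- flat key/value serialization ------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def transcribed_rhs(n, g, f, sensed, *, alpha_n, alpha_nf, alpha_g, alpha_f,
                    beta, eta, gamma, delta, deg_n, deg_g, deg_f, lam):
    """The three deterministic right-hand sides, written down in one place.

    Any correction to the functional form of the circuit is a one-place
    edit here.  Hill-coefficient/arm mapping:

    * ``beta``  — repression of NANOG production by GATA6,
    * ``gamma`` — repression of NANOG production by sensed FGF4,
    * ``eta``   — repression of GATA6 production by NANOG,
    * ``delta`` — repression of FGF4 production by GATA6.

    NANOG production is the sum of a GATA6-repressed term (``alpha_n``)
    and an FGF4-repressed term (``alpha_nf``); GATA6 and FGF4 each have a
    single repressed production term; every species degrades linearly and
    the whole right-hand side is scaled by ``lam``:

        dN/dt = lam * (alpha_n /(1 + G**beta) + alpha_nf/(1 + S**gamma) - deg_n*N)
        dG/dt = lam * (alpha_g /(1 + N**eta)                            - deg_g*G)
        dF/dt = lam * (alpha_f /(1 + G**delta)                          - deg_f*F)

    Accepts scalars or broadcasting numpy arrays; returns the triple
    (dN/dt, dG/dt, dF/dt).
    """
    dn = lam * (alpha_n / (1.0 + g**beta) + alpha_nf / (1.0 + sensed**gamma)
                - deg_n * n)
    dg = lam * (alpha_g / (1.0 + n**eta) - deg_g * g)
    df = lam * (alpha_f / (1.0 + g**delta) - deg_f * f)
    return dn, dg, df


def transcribed_jacobian_blocks(n, g, f, sensed, *, alpha_n, alpha_nf,
                                alpha_g, alpha_f, beta, eta, gamma, delta,
                                deg_n, deg_g, deg_f, lam):
    """Analytic partial derivatives of :func:`transcribed_rhs`.

    Returns the nonzero partials as a dict keyed by ('N','G'), ('N','S'),
    etc., kept next to the transcription so the two cannot drift apart.
    Valid for Hill coefficients >= 1 (the g**(beta-1) factors are then
    finite at 0).
    """
    g, n, sensed = np.asarray(g, float), np.asarray(n, float), np.asarray(sensed, float)
    hg = 1.0 + g**beta
    hs = 1.0 + sensed**gamma
    hn = 1.0 + n**eta
    hgd = 1.0 + g**delta
    return {
        ("N", "N"): -lam * deg_n * np.ones_like(n),
        ("N", "G"): -lam * alpha_n * beta * g ** (beta - 1.0) / hg**2,
        ("N", "S"): -lam * alpha_nf * gamma * sensed ** (gamma - 1.0) / hs**2,
        ("G", "G"): -lam * deg_g * np.ones_like(g),
        ("G", "N"): -lam * alpha_g * eta * n ** (eta - 1.0) / hn**2,
        ("F", "F"): -lam * deg_f * np.ones_like(f),
        ("F", "G"): -lam * alpha_f * delta * g ** (delta - 1.0) / hgd**2,
    }


def _kinetic_kwargs(params: ModelParams) -> dict:
    kw = {name: getattr(params, name) for name in KINETIC_FIELDS}
    kw["lam"] = params.lam
    return kw


def deterministic_rhs(state: CellState, sensed: SensedInput,
                      params: ModelParams) -> tuple[float, float, float]:
    """Evaluate (dN/dt, dG/dt, dF/dt) for one cell.

    Raises ``ValueError`` on non-finite or negative inputs.
    """
    vals = (*state, sensed[0] if isinstance(sensed, tuple) else float(sensed))
    if not all(np.isfinite(v) for v in vals):
        raise ValueError(f"non-finite input: state={state}, sensed={sensed}")
    if any(v < 0 for v in vals):
        raise ValueError(f"negative input: state={state}, sensed={sensed}")
    n, g, f, s = vals
    dn, dg, df = transcribed_rhs(n, g, f, s, **_kinetic_kwargs(params))
    return float(dn), float(dg), float(df)


def sensed_fgf(neighbor_f, mode: str, params: ModelParams) -> SensedInput:
    """Extracellular FGF4 sensed by one cell from its neighborhood.

    * ``wildtype`` — unweighted arithmetic mean of the neighbors' secreted
      FGF4 (self excluded; the neighbor list must not be empty).
    * ``mutant`` — communication is off; the cell senses the constant
      external input ``params.f_ext`` regardless of neighbors.
    * ``wildtype_plus_external`` — wild-type mean plus the additive
      external input ``params.f_ext_add``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "mutant":
        return SensedInput(float(params.f_ext))
    arr = np.asarray(neighbor_f, dtype=float)
    if arr.size == 0:
        raise ValueError("empty neighbor list in a communicating mode "
                         "(isolated cell in a coupled simulation)")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("neighbor FGF4 levels must be finite and >= 0")
    value = float(arr.mean())
    if mode == "wildtype_plus_external":
        value += float(params.f_ext_add)
    return SensedInput(value)
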