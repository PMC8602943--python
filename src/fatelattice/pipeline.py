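"""Config-driven experiment recipes tying the stages together.

Two recipes mirror the model analyses: ``recipe_proportioning`` (final
cell-type proportions versus initial-condition proportion p and versus
external FGF4 dose, for communicating and non-communicating populations)
and ``recipe_divisions`` (cluster-radius distributions per division cycle
for continuous, absent and switched-off communication).  Both return tidy
DataFrames and are reproducible from a seed via a :class:`RunManifest`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import anchor_states
from .identity import GPOS, NPOS, UNASSIGNED, classify_simulation, proportions
from .lattice import DivisionSchedule
from .model_core import ModelParams
from .simulator import SimulationConfig, integrate, run_division_experiment
from .spatial_stats import (PointPattern, cluster_radius,
                            scaled_fraction_profile)

__all__ = [
    "RunManifest",
    "recipe_proportioning",
    "recipe_divisions",
    "division_summary",
    "DEFAULT_P_VALUES",
]

#: Initial-condition proportions used for the quantifications.
DEFAULT_P_VALUES = (0.0, 0.4, 0.5, 0.6, 1.0)


@dataclass
class RunManifest:
    """Traceability record for one recipe invocation."""

    recipe: str
    config: dict
    seed: int
    package_version: str = __version__
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    outputs: dict = field(default_factory=dict)

    def add_output(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _realization_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def recipe_proportioning(config: SimulationConfig | None = None,
                         p_values=DEFAULT_P_VALUES,
                         modes=("wildtype", "mutant",
                                "wildtype_plus_external"),
                         f_ext_values=(0.0, 0.6, 1.2, 1.8, 2.4),
                         n_realizations: int = 10,
                         seed: int | None = None) -> pd.DataFrame:
    """Final cell-type proportions across initial conditions and modes.

    Sweeps p over ``p_values`` for every mode, and additionally sweeps
    the external input over ``f_ext_values`` for the non-communicating
    (mutant) model at p = 0.5 (the dose-dependence analysis).  Returns
    one row per (condition, realization) with the Gpos/Npos fractions of
    the N-vs-G classification of the final states.
    """
    if config is None:
        config = SimulationConfig()
    if seed is None:
        seed = config.seed
    anchors = anchor_states(config.params)
    rows = []

    def run(mode: str, p: float, f_ext: float | None, cond: str,
            cond_key: int) -> None:
        params = (config.params if f_ext is None
                  else replace(config.params, f_ext=f_ext))
        cfg = replace(config, mode=mode, init_p=p, params=params)
        for r in range(n_realizations):
            rng = _realization_rng(seed, cond_key, int(p * 1000),
                                   int(0 if f_ext is None else f_ext * 1000), r)
            res = integrate(cfg, rng=rng, anchors=anchors)
            labels = classify_simulation(res.final_states)
            frac = proportions(labels)
            rows.append({"condition": cond, "mode": mode, "p": p,
                         "f_ext": params.f_ext if mode == "mutant" else np.nan,
                         "realization": r,
                         "frac_gpos": frac[GPOS], "frac_npos": frac[NPOS],
                         "frac_unassigned": frac[UNASSIGNED]})

    for mi, mode in enumerate(modes):
        for p in p_values:
            run(mode, p, None, f"p_sweep:{mode}", mi)
    if "mutant" in modes and f_ext_values is not None:
        for f_ext in f_ext_values:
            run("mutant", 0.5, f_ext, "dose_sweep:mutant", 1000)
    return pd.DataFrame(rows)


def recipe_divisions(config: SimulationConfig | None = None,
                     schedule: DivisionSchedule | None = None,
                     comms=("always", "never", "switch_off_after_cycle_3"),
                     n_realizations: int = 100,
                     seed: int | None = None,
                     radius_step: float = 1.0) -> pd.DataFrame:
    """Cluster-radius distributions per division cycle and communication
    condition.

    Each realization runs the five-cycle division experiment initialized
    at mu_ics(0.5), classifies the relaxed end-of-cycle states by N vs G,
    and evaluates the scaled-fraction cluster radius on the snapshot
    pattern (lattice spacing 1, so radii are in cell diameters;
    ``radius_step`` sets the profile grid).  Snapshots whose pattern has
    a single fate are recorded with NaN radius.
    """
    if config is None:
        config = SimulationConfig(init_p=0.5)
    if schedule is None:
        schedule = DivisionSchedule()
    if seed is None:
        seed = config.seed
    anchors = anchor_states(config.params)
    rows = []
    for ci, comm in enumerate(comms):
        for r in range(n_realizations):
            rng = _realization_rng(seed, ci, r)
            snaps = run_division_experiment(config, schedule, comm,
                                            anchors=anchors, rng=rng)
            for snap in snaps:
                labels = classify_simulation(snap.states)
                pattern = PointPattern.from_lattice(snap.lattice, labels)
                frac_npos = float(np.mean(labels == NPOS))
                try:
                    profile = scaled_fraction_profile(pattern,
                                                      step=radius_step)
                    cr = cluster_radius(profile)
                    radius, censored = float(cr), cr.censored
                except ValueError:
                    radius, censored = np.nan, True
                rows.append({"comm": comm, "cycle": snap.cycle,
                             "realization": r, "cluster_radius": radius,
                             "censored": censored, "frac_npos": frac_npos,
                             "relax_converged": snap.converged})
    return pd.DataFrame(rows)


def division_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of the cluster radius per
    communication condition and cycle (box-plot summary)."""
    def q(frame, p):
        return frame["cluster_radius"].quantile(p)

    out = (df.groupby(["comm", "cycle"])
             .apply(lambda g: pd.Series({
                 "median": g["cluster_radius"].median(),
                 "q25": q(g, 0.25), "q75": q(g, 0.75),
                 "n": len(g),
                 "n_censored": int(g["censored"].sum())}),
                    include_groups=False)
             .reset_index())
    return out
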