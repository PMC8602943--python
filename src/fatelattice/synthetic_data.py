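"""Synthetic generators for every input class the analyses consume.

The generators emulate the statistical structure of the study's imaging
and flow-cytometry data — ~14 µm nearest-neighbor spacing on confluent
fields, bimodal two-channel (GATA6, NANOG) expression, and
plateau-then-exponential intensity decay with additive noise — so every
analysis stage has a closed generator -> stage -> recovery loop without
any external data.  Every generator is seeded and returns its ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .identity import GPOS, NPOS
from .range_fit import plateau_decay_model
from .spatial_stats import PointPattern

__all__ = [
    "PatternSpec",
    "ExpressionSpec",
    "generate_point_pattern",
    "generate_expression_table",
    "generate_intensity_profile",
]


@dataclass
class PatternSpec:
    """Specification of a synthetic labeled point pattern.

    ``label_model`` is one of ``random`` (iid Npos with probability
    ``label_param``), ``blocks`` (square blocks of side ``label_param``
    spacings with iid block labels), ``disc`` (Npos disc of radius
    ``label_param`` spacings in a Gpos sea) or ``halfplane``.
    ``packing`` is hexagonal by default (closer to confluent epithelial
    neighbor statistics); ``square`` is retained as an option.
    """

    n_cells: int = 400
    spacing: float = 14.0          # target nearest-neighbor spacing, µm
    label_model: str = "random"
    label_param: float = 0.5
    jitter_sd: float = 0.04        # fraction of spacing
    packing: str = "hex"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.label_model == "random" and not 0 < self.label_param < 1:
            raise ValueError("random label model needs p in (0, 1)")
        if self.packing not in ("hex", "square"):
            raise ValueError("packing must be 'hex' or 'square'")


def generate_point_pattern(spec: PatternSpec) -> PointPattern:
    """Jittered hexagonal (or square) packing at the target spacing with
    labels drawn from the requested label model."""
    rng = np.random.default_rng(spec.seed)
    a = spec.spacing
    n_side = int(np.ceil(np.sqrt(spec.n_cells)))
    pts = []
    for i in range(n_side + 1):
        for j in range(n_side + 1):
            if spec.packing == "hex":
                x = (j + 0.5 * (i % 2)) * a
                y = i * a * np.sqrt(3) / 2
            else:
                x, y = j * a, i * a
            pts.append((x, y))
    pos = np.array(pts)[: spec.n_cells]
    if len(pos) < spec.n_cells:
        raise ValueError("infeasible density for the requested cell count")
    pos = pos + rng.normal(0.0, spec.jitter_sd * a, size=pos.shape)

    m = spec.label_model
    if m == "random":
        is_n = rng.random(len(pos)) < spec.label_param
    elif m == "blocks":
        side = spec.label_param * a
        cells = np.floor(pos / side).astype(int)
        keys, inv = np.unique(cells, axis=0, return_inverse=True)
        block_lab = rng.random(len(keys)) < 0.5
        is_n = block_lab[inv]
    elif m == "disc":
        center = pos.mean(axis=0)
        is_n = np.linalg.norm(pos - center, axis=1) <= spec.label_param * a
    elif m == "halfplane":
        is_n = pos[:, 0] <= np.median(pos[:, 0])
    else:
        raise ValueError(f"unknown label model {m!r}")
    labels = np.where(is_n, NPOS, GPOS).astype(object)
    return PointPattern(pos, labels)


@dataclass
class ExpressionSpec:
    """Two-component bimodal (GATA6, NANOG) expression mixture.

    Component 0 is the GATA6-high population, component 1 NANOG-high.
    ``outlier_fraction`` adds uniform background points over an enlarged
    bounding box with label 'outlier_truth' in the ground truth.
    """

    mean_gpos: tuple[float, float] = (8.0, 1.0)
    mean_npos: tuple[float, float] = (1.0, 8.0)
    cov_gpos: tuple = ((1.0, 0.0), (0.0, 1.0))
    cov_npos: tuple = ((1.0, 0.0), (0.0, 1.0))
    gpos_weight: float = 0.5
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gpos_weight < 1:
            raise ValueError("gpos_weight must lie in (0, 1)")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")


def generate_expression_table(spec: ExpressionSpec, n: int) -> pd.DataFrame:
    """Draw ``n`` cells; returns columns gata6, nanog, true_label."""
    rng = np.random.default_rng(spec.seed)
    n_out = int(round(spec.outlier_fraction * n))
    n_core = n - n_out
    n_g = rng.binomial(n_core, spec.gpos_weight)
    g_draw = rng.multivariate_normal(spec.mean_gpos, spec.cov_gpos, size=n_g)
    n_draw = rng.multivariate_normal(spec.mean_npos, spec.cov_npos,
                                     size=n_core - n_g)
    xy = np.vstack([g_draw, n_draw])
    truth = np.array([GPOS] * n_g + [NPOS] * (n_core - n_g), dtype=object)
    if n_out:
        lo = xy.min(axis=0) - 5.0
        hi = xy.max(axis=0) + 5.0
        out = rng.uniform(lo, hi, size=(n_out, 2)) + rng.choice(
            [-1.0, 1.0], size=(n_out, 2)) * (hi - lo)
        xy = np.vstack([xy, out])
        truth = np.concatenate([truth, np.array(["outlier_truth"] * n_out,
                                                dtype=object)])
    perm = rng.permutation(len(xy))
    df = pd.DataFrame({"gata6": xy[perm, 0], "nanog": xy[perm, 1],
                       "true_label": truth[perm]})
    return df


def generate_intensity_profile(plateau: float, decay: float,
                               amplitude: float, baseline: float,
                               noise_sd: float, n_cells: int = 500,
                               max_distance: float = 90.0,
                               seed: int = 0) -> pd.DataFrame:
    """Per-cell (distance, intensity) samples along the piecewise
    plateau-plus-decay model with additive Gaussian noise."""
    if plateau < 0 or decay <= 0:
        raise ValueError("lengths must be >= 0 (decay > 0)")
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, max_distance, size=n_cells)
    y = plateau_decay_model(d, plateau, decay, amplitude, baseline)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_cells)
    return pd.DataFrame({"distance_um": d, "intensity": y})
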