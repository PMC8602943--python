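"""Spatial statistics on labeled point patterns.

Implements the neighbor-graph and cluster analyses used on imaging fields
and on simulation snapshots alike: trimmed-Delaunay neighbor graphs and
first/second-neighbor distance statistics, neighborhood composition
within a fixed radius, and the scaled-fraction cluster-radius statistic.

Positions are in µm for imaging-like data; simulation snapshots use
lattice units with spacing 1, so cluster radii come out directly in cell
diameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, Voronoi, QhullError, distance
from shapely.geometry import LineString
from sklearn.mixture import GaussianMixture

from .identity import GPOS, NPOS

__all__ = [
    "PointPattern",
    "NeighborGraph",
    "NeighborDistanceStats",
    "ClusterProfile",
    "ClusterRadius",
    "jitter_positions",
    "build_neighbor_graph",
    "neighbor_distance_stats",
    "neighborhood_composition",
    "scaled_fraction_profile",
    "cluster_radius",
]


@dataclass
class PointPattern:
    """Cell positions plus categorical fate labels.

    ``positions`` is (n, 2); ``labels`` holds 'Npos', 'Gpos' or any other
    tag (other tags are ignored by the fate-specific statistics).
    """

    positions: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions must have equal length")

    @property
    def n(self) -> int:
        return len(self.positions)

    @classmethod
    def from_lattice(cls, lattice, labels) -> "PointPattern":
        """Snapshot pattern in lattice units (1 unit = 1 cell diameter)."""
        return cls(lattice.positions(), labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_um": self.positions[:, 0],
                             "y_um": self.positions[:, 1],
                             "label": self.labels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PointPattern":
        return cls(df[["x_um", "y_um"]].to_numpy(float),
                   df["label"].to_numpy(object))


def jitter_positions(positions: np.ndarray, eps: float = 0.01,
                     seed: int = 0) -> np.ndarray:
    """Break duplicate or cocircular configurations with a seeded uniform
    jitter of +/- ``eps`` (µm or lattice units) per coordinate."""
    rng = np.random.default_rng(seed)
    return np.asarray(positions, float) + rng.uniform(-eps, eps,
                                                      np.shape(positions))


@dataclass
class NeighborGraph:
    """Trimmed-Delaunay adjacency and derived second-neighbor links.

    First-neighbor links are Delaunay edges whose connecting segment
    passes through the shared Voronoi edge of the two cells; second
    neighbors are unlinked pairs that share a first neighbor.  Pairs are
    stored once with i < j.
    """

    n: int
    first_pairs: np.ndarray    # (m1, 2) int
    first_dists: np.ndarray
    second_pairs: np.ndarray   # (m2, 2) int
    second_dists: np.ndarray

    def adjacency_sets(self) -> list[set[int]]:
        adj = [set() for _ in range(self.n)]
        for i, j in self.first_pairs:
            adj[i].add(int(j))
            adj[j].add(int(i))
        return adj


def _ridge_segment(vor: Voronoi, ridge_idx: int, length: float) -> np.ndarray:
    """Endpoints of a Voronoi ridge, extending infinite ridges to a far
    point along the outward normal (the standard construction)."""
    (i, j) = vor.ridge_points[ridge_idx]
    v1, v2 = vor.ridge_vertices[ridge_idx]
    if v1 >= 0 and v2 >= 0:
        return np.array([vor.vertices[v1], vor.vertices[v2]])
    finite = vor.vertices[v2 if v1 < 0 else v1]
    t = vor.points[j] - vor.points[i]
    t = t / np.linalg.norm(t)
    normal = np.array([-t[1], t[0]])
    midpoint = vor.points[[i, j]].mean(axis=0)
    center = vor.points.mean(axis=0)
    direction = np.sign(np.dot(midpoint - center, normal)) * normal
    if not np.any(direction):
        direction = normal
    return np.array([finite, finite + direction * length])


def build_neighbor_graph(points: PointPattern) -> NeighborGraph:
    """Physically adjacent neighbor links from a trimmed Delaunay graph.

    A Delaunay edge is kept only if the segment between the two points
    intersects the (possibly unbounded) Voronoi edge shared by their
    Voronoi cells.  Degenerate (collinear) inputs raise with guidance to
    jitter the positions first.
    """
    pos = points.positions
    if points.n < 3:
        raise ValueError("need at least 3 points for triangulation")
    try:
        Delaunay(pos)  # raises early on degenerate input
        vor = Voronoi(pos)
    except QhullError as exc:
        raise ValueError(
            "degenerate point configuration (collinear or duplicate "
            "positions); jitter the positions (see jitter_positions) "
        ) from exc
    span = np.ptp(pos, axis=0).max() * 10 + 1.0
    kept = []
    for r, (i, j) in enumerate(vor.ridge_points):
        seg = LineString([pos[i], pos[j]])
        ridge = _ridge_segment(vor, r, span)
        if seg.intersects(LineString(ridge)):
            kept.append((min(i, j), max(i, j)))
    first_pairs = np.array(sorted(set(kept)), dtype=int).reshape(-1, 2)
    first_dists = np.linalg.norm(pos[first_pairs[:, 0]] - pos[first_pairs[:, 1]],
                                 axis=1)
    adj = [set() for _ in range(points.n)]
    for i, j in first_pairs:
        adj[i].add(int(j))
        adj[j].add(int(i))
    linked = {tuple(p) for p in first_pairs}
    second = set()
    for k in range(points.n):
        members = sorted(adj[k])
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                a, b = members[a_idx], members[b_idx]
                if (a, b) not in linked:
                    second.add((a, b))
    second_pairs = np.array(sorted(second), dtype=int).reshape(-1, 2)
    second_dists = (np.linalg.norm(pos[second_pairs[:, 0]]
                                   - pos[second_pairs[:, 1]], axis=1)
                    if len(second_pairs) else np.empty(0))
    return NeighborGraph(n=points.n, first_pairs=first_pairs,
                         first_dists=first_dists, second_pairs=second_pairs,
                         second_dists=second_dists)


@dataclass
class NeighborDistanceStats:
    first_mean: float
    first_sd: float
    second_mean: float
    second_sd: float
    method: str = "gmm"   # or "robust" fallback


def _lower_component(dists: np.ndarray, seed: int) -> tuple[float, float]:
    gm = GaussianMixture(n_components=2, n_init=5, random_state=seed)
    gm.fit(dists.reshape(-1, 1))
    k = int(np.argmin(gm.means_.ravel()))
    return float(gm.means_.ravel()[k]), float(np.sqrt(gm.covariances_.ravel()[k]))


def neighbor_distance_stats(graph: NeighborGraph,
                            seed: int = 0) -> NeighborDistanceStats:
    """Mean and s.d. of nearest and second-nearest neighbor distances.

    Each pooled link-distance distribution is fit with a one-dimensional
    two-component Gaussian mixture; the lower-mean component separates
    the true neighbor distances from higher-order contamination from
    erroneously kept links.  With fewer than 20 links per class the fit
    falls back to median/MAD with a warning.
    """
    if len(graph.first_dists) >= 20 and len(graph.second_dists) >= 20:
        m1, s1 = _lower_component(graph.first_dists, seed)
        m2, s2 = _lower_component(graph.second_dists, seed)
        return NeighborDistanceStats(m1, s1, m2, s2, method="gmm")
    warnings.warn("fewer than 20 links per class; falling back to median/MAD")
    mad = lambda d: 1.4826 * np.median(np.abs(d - np.median(d)))
    return NeighborDistanceStats(
        float(np.median(graph.first_dists)), float(mad(graph.first_dists)),
        float(np.median(graph.second_dists)) if len(graph.second_dists) else np.nan,
        float(mad(graph.second_dists)) if len(graph.second_dists) else np.nan,
        method="robust")


def _fate_subset(points: PointPattern) -> tuple[np.ndarray, np.ndarray]:
    sel = np.isin(points.labels.astype(str), (NPOS, GPOS))
    return points.positions[sel], points.labels[sel]


def neighborhood_composition(points: PointPattern, radius: float = 31.7,
                             n_null: int = 100, seed: int = 0
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell fate composition within a Euclidean radius (default
    31.7 µm, encompassing most nearest and second-nearest neighbors).

    Only Gpos/Npos cells enter.  Returns ``(per_cell, null)``: per-cell
    fractions of each label among neighbors within the radius (self
    excluded; cells with empty neighborhoods are excluded and counted in
    ``per_cell.attrs['n_empty']``), and the random baseline from
    ``n_null`` label permutations with fixed positions.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pos, labels = _fate_subset(points)
    d = distance.squareform(distance.pdist(pos))
    np.fill_diagonal(d, np.inf)
    within = d <= radius
    counts = within.sum(axis=1)
    ok = counts > 0
    is_n = (labels == NPOS).astype(float)

    def frac_table(lab_n: np.ndarray) -> np.ndarray:
        return (within[ok] @ lab_n) / counts[ok]

    fn = frac_table(is_n)
    per_cell = pd.DataFrame({
        "label": labels[ok], "n_neighbors": counts[ok],
        "frac_npos": fn, "frac_gpos": 1.0 - fn,
    })
    per_cell["frac_same"] = np.where(per_cell["label"] == NPOS,
                                     per_cell["frac_npos"],
                                     per_cell["frac_gpos"])
    per_cell.attrs["n_empty"] = int((~ok).sum())
    rng = np.random.default_rng(seed)
    null_rows = []
    for _ in range(n_null):
        perm = rng.permutation(len(labels))
        fn_null = frac_table(is_n[perm])
        same = np.where(labels[ok][..., ] == NPOS, fn_null, 1 - fn_null)
        # baseline conditioned on the *observed* label of the seed cell
        null_rows.append({"frac_npos": fn_null.mean(),
                          "frac_same": same.mean()})
    return per_cell, pd.DataFrame(null_rows)


@dataclass
class ClusterProfile:
    """Scaled fraction of Npos cells versus neighborhood radius.

    Raw fractions are computed among Gpos/Npos cells only, averaged over
    Npos seed cells (the seed counts itself, so the raw fraction at r=0
    is exactly 1); the overall Npos fraction is subtracted and the result
    renormalized so the scaled fraction is 1 at zero distance.
    """

    radii: np.ndarray
    scaled: np.ndarray
    global_fraction: float
    n_seeds: int


class ClusterRadius(float):
    """Cluster radius (0.5-crossing of the scaled fraction); ``censored``
    is True when the profile never crosses 0.5 within the radius grid, in
    which case the value is the maximal radius (a lower bound)."""

    censored: bool

    def __new__(cls, value: float, censored: bool = False):
        obj = super().__new__(cls, value)
        obj.censored = censored
        return obj


def scaled_fraction_profile(points: PointPattern, radii=None,
                            step: float = 1.0,
                            average: str = "per_seed") -> ClusterProfile:
    """Scaled fraction of Npos cells in neighborhoods of increasing radius.

    ``radii`` defaults to a grid from 0 to half the field diagonal in
    ``step`` units (1 µm for imaging fields; lattice snapshots use their
    spacing of one cell diameter).  ``average='per_seed'`` averages the
    per-seed fractions before scaling; ``'pooled'`` pools counts over all
    seeds first.
    """
    pos, labels = _fate_subset(points)
    is_n = labels == NPOS
    fglob = float(is_n.mean()) if len(labels) else np.nan
    if not 0.0 < fglob < 1.0:
        raise ValueError("pattern must contain both Npos and Gpos cells")
    if average not in ("per_seed", "pooled"):
        raise ValueError("average must be 'per_seed' or 'pooled'")
    if radii is None:
        half_diag = 0.5 * float(np.linalg.norm(np.ptp(pos, axis=0)))
        radii = np.arange(0.0, half_diag + step, step)
    radii = np.asarray(radii, float)
    d = distance.cdist(pos[is_n], pos)          # seeds x all fate cells
    order = np.argsort(d, axis=1)
    d_sorted = np.take_along_axis(d, order, axis=1)
    n_sorted = np.take_along_axis(np.broadcast_to(is_n, d.shape).astype(float),
                                  order, axis=1)
    cum_n = np.cumsum(n_sorted, axis=1)
    scaled = np.empty_like(radii)
    for k, r in enumerate(radii):
        idx = np.sum(d_sorted <= r, axis=1)     # cells within r per seed (>=1: self)
        npos_within = cum_n[np.arange(d.shape[0]), idx - 1]
        if average == "per_seed":
            frac = float(np.mean(npos_within / idx))
        else:
            frac = float(npos_within.sum() / idx.sum())
        scaled[k] = (frac - fglob) / (1.0 - fglob)
    return ClusterProfile(radii=radii, scaled=scaled, global_fraction=fglob,
                          n_seeds=int(is_n.sum()))


def cluster_radius(profile: ClusterProfile) -> ClusterRadius:
    """Distance at which the scaled fraction first drops to 0.5, located
    by linear interpolation between adjacent radii; right-censored at the
    maximal radius when the profile never crosses."""
    r, s = profile.radii, profile.scaled
    below = np.flatnonzero((s[1:] < 0.5) & (s[:-1] >= 0.5))
    if len(below) == 0:
        return ClusterRadius(float(r[-1]), censored=True)
    i = int(below[0])
    t = (s[i] - 0.5) / (s[i] - s[i + 1])
    return ClusterRadius(float(r[i] + t * (r[i + 1] - r[i])), censored=False)
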