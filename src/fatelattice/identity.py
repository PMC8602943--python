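"""Cell-type assignment from continuous expression.

Two rules are implemented.  Simulation output is classified by directly
comparing the final NANOG and GATA6 levels of each cell (N > G is
NANOG-positive, G > N GATA6-positive).  Measured two-channel data is
classified with a two-component bivariate Gaussian mixture: cells with a
posterior probability > 0.9 for one component get that component's type,
and outliers are removed per component as points whose Euclidean distance
from the component mean exceeds four interquartile ranges of the
component's distance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "NPOS", "GPOS", "UNASSIGNED", "OUTLIER",
    "TypeAssignment",
    "classify_simulation",
    "fit_gmm2",
    "assign_types",
    "remove_outliers",
    "proportions",
]

NPOS = "Npos"        # GATA6-; NANOG+
GPOS = "Gpos"        # GATA6+; NANOG-
UNASSIGNED = "unassigned"
OUTLIER = "outlier"


def classify_simulation(states: np.ndarray) -> np.ndarray:
    """Label simulated cells by comparing NANOG and GATA6 levels.

    ``states`` is (n, >=2) with columns (N, G, ...).  Exact ties are
    measure-zero and labeled unassigned.
    """
    states = np.asarray(states, float)
    if not np.all(np.isfinite(states[:, :2])):
        raise ValueError("states must be finite")
    n, g = states[:, 0], states[:, 1]
    labels = np.full(len(states), UNASSIGNED, dtype=object)
    labels[n > g] = NPOS
    labels[g > n] = GPOS
    return labels


@dataclass
class TypeAssignment:
    """A fitted two-component mixture over (GATA6, NANOG) space.

    ``posteriors`` is (n, 2) ordered (Gpos component, Npos component);
    the two columns sum to one per cell.  The Gpos component is the one
    with the higher GATA6 mean (ties broken by higher NANOG for Npos).
    """

    means: np.ndarray          # (2, 2), rows (Gpos, Npos), cols (gata6, nanog)
    covariances: np.ndarray    # (2, 2, 2)
    weights: np.ndarray        # (2,)
    posteriors: np.ndarray     # (n, 2)
    log_transformed: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.posteriors)


def _as_xy(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        xy = table[["gata6", "nanog"]].to_numpy(float)
    else:
        xy = np.asarray(table, float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected columns (gata6, nanog)")
    if not np.all(np.isfinite(xy)):
        raise ValueError("expression values must be finite")
    return xy


def fit_gmm2(table, seed: int = 0, n_init: int = 5,
             log_transform: bool = False) -> TypeAssignment:
    """Maximum-likelihood two-component full-covariance Gaussian mixture
    in (GATA6, NANOG) space.

    Uses ``n_init`` seeded restarts and keeps the best likelihood;
    deterministic given ``seed``.  ``log_transform`` fits on
    log10-intensities (requires strictly positive values).
    """
    xy = _as_xy(table)
    if len(xy) < 10:
        raise ValueError("need at least 10 cells for mixture fitting")
    if np.allclose(xy.std(axis=0), 0):
        raise ValueError("degenerate input: no spread in expression space")
    fit_xy = xy
    if log_transform:
        if np.any(xy <= 0):
            raise ValueError("log transform requires strictly positive values")
        fit_xy = np.log10(xy)
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         n_init=n_init, random_state=seed)
    try:
        gm.fit(fit_xy)
    except Exception as exc:  # singular covariance etc.
        raise ValueError(f"degenerate input for mixture fit: {exc}") from exc
    post = gm.predict_proba(fit_xy)
    means, covs, w = gm.means_, gm.covariances_, gm.weights_
    # component identity: higher gata6 mean is Gpos; ties by higher nanog
    # for the Npos component
    if (means[0, 0], -means[0, 1]) >= (means[1, 0], -means[1, 1]):
        order = [0, 1]
    else:
        order = [1, 0]
    return TypeAssignment(means=means[order], covariances=covs[order],
                          weights=w[order], posteriors=post[:, order],
                          log_transformed=log_transform)


def assign_types(fit: TypeAssignment, threshold: float = 0.9) -> np.ndarray:
    """Label cells whose winning-component posterior exceeds ``threshold``;
    all others are unassigned."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    labels = np.full(fit.n_cells, UNASSIGNED, dtype=object)
    labels[fit.posteriors[:, 0] > threshold] = GPOS
    labels[fit.posteriors[:, 1] > threshold] = NPOS
    return labels


def remove_outliers(table, labels: np.ndarray,
                    fit: TypeAssignment) -> np.ndarray:
    """Flow-cytometry outlier rule: within each assigned component, flag
    cells whose Euclidean distance to the component mean exceeds 4x the
    interquartile range of that component's distance distribution.

    Returns a boolean mask (True = outlier).  Components with fewer than
    4 assigned members are skipped with a warning.
    """
    import warnings

    xy = _as_xy(table)
    if fit.log_transformed:
        xy = np.log10(xy)
    mask = np.zeros(len(xy), dtype=bool)
    for comp, lab in ((0, GPOS), (1, NPOS)):
        sel = labels == lab
        if sel.sum() < 4:
            warnings.warn(f"component {lab} has < 4 members; "
                          "outlier removal skipped for it")
            continue
        d = np.linalg.norm(xy[sel] - fit.means[comp], axis=1)
        q1, q3 = np.percentile(d, [25, 75])
        iqr = q3 - q1
        mask[np.flatnonzero(sel)[d > 4 * iqr]] = True
    return mask


def proportions(labels: np.ndarray,
                outlier_mask: np.ndarray | None = None) -> dict[str, float]:
    """Fractions of Gpos / Npos / unassigned among non-outlier cells."""
    labels = np.asarray(labels, dtype=object)
    if outlier_mask is not None:
        labels = labels[~np.asarray(outlier_mask, bool)]
    labels = labels[labels != OUTLIER]
    if len(labels) == 0:
        raise ValueError("no non-outlier cells")
    n = len(labels)
    return {GPOS: float(np.sum(labels == GPOS)) / n,
            NPOS: float(np.sum(labels == NPOS)) / n,
            UNASSIGNED: float(np.sum(labels == UNASSIGNED)) / n}
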