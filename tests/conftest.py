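import numpy as np
import pytest

from fatelattice.bifurcation import anchor_states
from fatelattice.model_core import ModelParams


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def anchors(params):
    """The two opposite-fate anchor states of the stable two-cell IHSS,
    computed once per session."""
    return anchor_states(params, rng=np.random.default_rng(11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# --- shared independent oracles -----------------------------------------

def brute_force_trimmed_edges(pos: np.ndarray) -> set[tuple[int, int]]:
    """Independent geometric oracle for the trimmed neighbor graph.

    The segment between two points crosses their perpendicular bisector
    exactly at its midpoint, so the link passes through the shared
    Voronoi edge iff the midpoint is strictly closer to the two endpoints
    than to every other point.
    """
    n = len(pos)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            m = 0.5 * (pos[i] + pos[j])
            d_own = np.linalg.norm(m - pos[i])
            d_all = np.linalg.norm(pos - m, axis=1)
            others = np.delete(d_all, [i, j])
            if np.all(others > d_own + 1e-12):
                edges.add((i, j))
    return edges


def milstein_strong_order_slopes(sigma=0.5, T=1.0, n_paths=2000,
                                 dts=(0.02, 0.01, 0.005), seed=99):
    """Strong-convergence slopes of Milstein and Euler-Maruyama on
    geometric Brownian motion dX = sigma X dW against the exact solution
    driven by the same Brownian path."""
    from fatelattice.simulator import milstein_update

    dts = np.asarray(dts, float)
    rng = np.random.default_rng(seed)
    fine_dt = dts.min()
    n_fine = int(T / fine_dt)
    dw_fine = rng.normal(0, np.sqrt(fine_dt), size=(n_paths, n_fine))
    exact = np.exp(-0.5 * sigma**2 * T + sigma * dw_fine.sum(axis=1))
    errs_mil, errs_em = [], []
    for dt in dts:
        k = int(round(dt / fine_dt))
        dw = dw_fine.reshape(n_paths, -1, k).sum(axis=2)
        x_mil = np.ones(n_paths)
        x_em = np.ones(n_paths)
        for step in range(dw.shape[1]):
            inc = dw[:, step]
            x_mil = milstein_update(x_mil, np.zeros(n_paths), dt, sigma, inc)
            x_em = np.clip(x_em + sigma * x_em * inc, 0, None)
        errs_mil.append(np.mean(np.abs(x_mil - exact)))
        errs_em.append(np.mean(np.abs(x_em - exact)))
    slope_mil = np.polyfit(np.log(dts), np.log(errs_mil), 1)[0]
    slope_em = np.polyfit(np.log(dts), np.log(errs_em), 1)[0]
    return float(slope_mil), float(slope_em)
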