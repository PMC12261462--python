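"""Synthetic time-series single-cell data with known latent dynamics.

Cells follow a latent SDE dz = b(z,t) dt + eps dW (Euler-Maruyama on a fine
grid), optionally killed inside a death window, and are observed through a
fixed linear latent-to-gene map followed by softplus plus Gaussian gene
noise. Because the drift, the death schedule, the loading matrix and the
driver-gene set are all known, every downstream stage (bridge drifts, kill
rates, drift-gene ranking, perturbation) can be scored against ground truth
without external datasets.

Drift choices
-------------
linear     b(z,t) = v (constant advance along coordinate 0)
bistable   double-well gradient on coordinate 0, OU pull on the rest
branching  coordinate 0 advances at unit speed while coordinate 1 falls into
           one of two wells (+/-1): a known bifurcation with known direction
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data_io import TimeSeriesExpression

__all__ = ["SyntheticTruth", "simulate_timeseries", "heldout_split", "EvalStore"]


@dataclass
class SyntheticTruth:
    latent_paths: dict[int, np.ndarray]   # t -> (n_t, n_fine+1, d) paths ending at t
    true_drift: Callable[[np.ndarray, float], np.ndarray]
    counts: list[int]                     # realized n_t
    loading_matrix: np.ndarray            # d x g
    noise_sd: float
    driver_genes: np.ndarray              # indices loading on the drifting coord
    seed: int


@dataclass
class EvalStore:
    """Held-out timepoints kept aside for scoring only."""
    timepoints: list[int]
    matrices: dict[int, np.ndarray]
    cell_ids: dict[int, list[str]]


def _make_drift(kind: str, d: int, speed: float) -> Callable:
    if kind == "linear":
        v = np.zeros(d)
        v[0] = speed

        def b(z, t):
            return np.broadcast_to(v, z.shape)
        return b
    if kind == "bistable":
        def b(z, t):
            out = -0.5 * z
            out[:, 0] = z[:, 0] * (1.0 - z[:, 0] ** 2)
            return out
        return b
    if kind == "branching":
        if d < 2:
            raise ValueError("branching drift needs d >= 2")

        def b(z, t):
            out = -0.5 * z
            out[:, 0] = speed
            out[:, 1] = z[:, 1] * (1.0 - z[:, 1] ** 2)  # two-well gradient
            return out
        return b
    raise ValueError(f"unknown drift_spec {kind!r}")


def simulate_timeseries(d: int, g: int, T: int, counts: list[int],
                        drift_spec: str = "linear",
                        death_window: tuple[float, float, float] | None = None,
                        seed: int = 0, eps: float = 0.1, speed: float = 1.0,
                        n_driver: int = 5, noise_sd: float = 0.05,
                        dt_fine: float = 0.01, init_sd: float = 0.3,
                        ) -> tuple[TimeSeriesExpression, SyntheticTruth]:
    """Simulate latent-SDE-driven time-series expression with known truth.

    ``counts[t]`` is the target number of cells observed at timepoint t. With
    ``death_window=(t_a, t_b, rate)`` cells are killed at hazard ``rate``
    while inside the window (``rate="auto"`` calibrates the hazard so that the
    prescribed count decline over the window is matched in expectation);
    realized counts then match ``counts`` in expectation, binomially. Without
    a death window realized counts are exact.
    """
    if len(counts) != T + 1:
        raise ValueError(f"counts must have length T+1={T + 1}")
    if any(c < 1 for c in counts):
        raise ValueError("all counts must be >= 1")
    if death_window is not None and any(
            b > a for a, b in zip(counts[:-1], counts[1:])):
        raise ValueError("death_window models pure death; counts must be "
                         "non-increasing (requested growth is incompatible)")

    rng = np.random.default_rng(seed)
    drift = _make_drift(drift_spec, d, speed)

    # survival probability up to time t under the window hazard
    if death_window is not None:
        t_a, t_b, rate = death_window
        if rate == "auto":
            lo = min(range(T + 1), key=lambda i: counts[i] / counts[0])
            frac = counts[lo] / counts[0]
            dur = max(t_b - t_a, dt_fine)
            rate = -np.log(max(frac, 1e-12)) / dur

        def survival(t):
            exposure = max(0.0, min(t, t_b) - t_a)
            return float(np.exp(-rate * exposure))
    else:
        def survival(t):
            return 1.0

    # latent -> gene map: drivers load on coordinate 0 only, the remaining
    # genes on the other coordinates (full row rank by construction)
    n_driver = min(n_driver, g)
    L = np.zeros((d, g))
    L[0, :n_driver] = rng.uniform(1.5, 2.5, size=n_driver)
    if d > 1 and g > n_driver:
        L[1:, n_driver:] = rng.normal(0.0, 1.0, size=(d - 1, g - n_driver))
    else:
        L[0, n_driver:] = rng.normal(0.0, 1.0, size=g - n_driver)
    if np.linalg.matrix_rank(L) < min(d, g):
        L += 1e-3 * rng.normal(size=L.shape)
    driver_genes = np.arange(n_driver)

    timepoints = list(range(T + 1))
    matrices: dict[int, np.ndarray] = {}
    cell_ids: dict[int, list[str]] = {}
    latent_paths: dict[int, np.ndarray] = {}
    realized: list[int] = []

    for t in timepoints:
        n_start = counts[t] if survival(t) >= 1.0 else int(
            np.ceil(counts[t] / survival(t)))
        n_fine = max(1, int(round(t / dt_fine))) if t > 0 else 0
        z = rng.normal(0.0, init_sd, size=(n_start, d))
        path = np.empty((n_start, n_fine + 1, d))
        path[:, 0] = z
        alive = np.ones(n_start, dtype=bool)
        for k in range(n_fine):
            tk = k * dt_fine
            z = z + drift(z, tk) * dt_fine \
                + eps * np.sqrt(dt_fine) * rng.standard_normal(z.shape)
            path[:, k + 1] = z
            if death_window is not None and t_a <= tk < t_b:
                p = 1.0 - np.exp(-rate * dt_fine)
                alive &= rng.random(n_start) >= p * alive
        z_obs = path[alive, -1]
        if z_obs.shape[0] < 1:  # degenerate draw: keep at least one cell
            z_obs = path[:1, -1]
            alive[:1] = True
        noise = rng.normal(0.0, noise_sd, size=(z_obs.shape[0], g))
        X = np.logaddexp(0.0, z_obs @ L + noise)  # softplus keeps X > 0
        matrices[t] = X
        cell_ids[t] = [f"t{t}_c{i}" for i in range(X.shape[0])]
        latent_paths[t] = path[alive]
        realized.append(X.shape[0])

    data = TimeSeriesExpression(
        timepoints, matrices, [f"g{j:04d}" for j in range(g)], cell_ids,
        meta={"source": "synthetic", "seed": seed, "drift_spec": drift_spec,
              "log1p": True, "target_counts": list(counts)})
    truth = SyntheticTruth(latent_paths, drift, realized, L, noise_sd,
                           driver_genes, seed)
    return data, truth


def heldout_split(data: TimeSeriesExpression, holdout: set[int]
                  ) -> tuple[TimeSeriesExpression, EvalStore]:
    """Remove ``holdout`` timepoints from training; keep them for scoring.

    The boundary marginals at 0 and T anchor the bridge, so neither may be
    held out.
    """
    holdout = set(int(t) for t in holdout)
    if not holdout <= set(data.timepoints):
        raise ValueError(f"holdout {sorted(holdout)} not all measured")
    if 0 in holdout or data.T in holdout:
        raise ValueError("cannot hold out boundary timepoints 0 or T")
    keep = [t for t in data.timepoints if t not in holdout]
    train = TimeSeriesExpression(
        keep, {t: data.matrices[t].copy() for t in keep},
        list(data.gene_names), {t: list(data.cell_ids[t]) for t in keep},
        dict(data.meta, holdout=sorted(holdout)))
    store = EvalStore(sorted(holdout),
                      {t: data.matrices[t].copy() for t in holdout},
                      {t: list(data.cell_ids[t]) for t in holdout})
    return train, store
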