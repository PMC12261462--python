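"""Unbalanced dynamics: kill rates, birth/death updates, population loss.

The state space is augmented with a single cemetery state: live cells can be
killed (latent -> cemetery) and dead slots revived (cemetery -> latent). The
per-cell prior kill rate is data-derived: the fraction of latent features
deviating by more than two standard deviations from the mean of the next
measured timepoint, floored to 0 when fewer than 20% of features deviate. A
small neural net K_omega(t) modulates the prior multiplicatively; its loss
matches the cumulative predicted birth/death mass per measured timepoint to
the empirical normalized change (n_i - n_0) / max_i n_i, with penalties on
transition probabilities exceeding 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._nn import MLP, Adam, Tensor
from .vae import sinusoidal_encode

__all__ = ["KillRateField", "PopulationTarget", "prior_kill_rate",
           "transition_probs", "update_statuses", "empirical_mass_change",
           "population_loss", "make_prior_from_stats", "make_killer",
           "train_kill_net"]

DEVIATION_SDS = 2.0       # "more than two standard deviations"
PRIOR_FLOOR = 0.20        # fractions below 20% are set to 0


def prior_kill_rate(Z_t: np.ndarray, Z_next: np.ndarray) -> np.ndarray:
    """Fraction of features deviating > 2 sd from the next timepoint's mean.

    Values below the 20% floor are set to 0. ``Z_next`` must contain at
    least 2 cells (sd undefined otherwise).
    """
    Z_t = np.atleast_2d(np.asarray(Z_t, float))
    Z_next = np.atleast_2d(np.asarray(Z_next, float))
    if Z_next.shape[0] < 2:
        raise ValueError("next timepoint needs >= 2 cells to define an sd")
    mu = Z_next.mean(axis=0)
    sd = Z_next.std(axis=0, ddof=1)
    dev = np.abs(Z_t - mu) > DEVIATION_SDS * sd
    frac = dev.mean(axis=1)
    frac[frac < PRIOR_FLOOR] = 0.0
    return frac


class StatsPriorKillRate:
    """Prior kill-rate field k(Z, t) from per-timepoint latent (mean, sd).

    For a query time t, the NEXT measured timepoint's statistics are used;
    beyond the last timepoint the terminal statistics apply.
    """

    def __init__(self, stats: dict[int, tuple[np.ndarray, np.ndarray]],
                 timepoints: list[int]):
        self.stats = {int(t): (np.asarray(m, float), np.asarray(s, float))
                      for t, (m, s) in stats.items()}
        self.timepoints = sorted(int(t) for t in timepoints)

    def __call__(self, Z: np.ndarray, t: float) -> np.ndarray:
        nxt = next((m for m in self.timepoints if m > t + 1e-9),
                   self.timepoints[-1])
        mu, sd = self.stats[nxt]
        dev = np.abs(np.atleast_2d(Z) - mu) > DEVIATION_SDS * sd
        frac = dev.mean(axis=1)
        frac[frac < PRIOR_FLOOR] = 0.0
        return frac


def make_prior_from_stats(stats, timepoints) -> StatsPriorKillRate:
    return StatsPriorKillRate(stats, timepoints)


class KillNet:
    """Positive time-modulation K_omega: softplus MLP on sinusoidal time
    (optionally concatenated with the latent state).

    ``scale`` multiplies the softplus output; 0 switches the modulation off
    exactly (softplus alone is strictly positive).
    """

    def __init__(self, time_dim: int = 8, hidden: tuple[int, ...] = (32,),
                 state_dim: int = 0, seed: int = 0, scale: float = 1.0):
        self.time_dim = time_dim
        self.state_dim = state_dim
        self.scale = scale
        rng = np.random.default_rng(seed)
        self.mlp = MLP([time_dim + state_dim, *hidden, 1], rng,
                       activation="silu")

    @property
    def params(self):
        return self.mlp.params

    def _inputs(self, t: float, Z: np.ndarray | None, n: int) -> np.ndarray:
        tau = np.broadcast_to(sinusoidal_encode(t, self.time_dim),
                              (n, self.time_dim))
        if self.state_dim:
            if Z is None:
                raise ValueError("state-dependent kill net needs Z")
            return np.hstack([tau, Z])
        return np.asarray(tau, float).copy()

    def forward_graph(self, t: float, Z: np.ndarray | None, n: int) -> Tensor:
        return self.mlp.forward(Tensor(self._inputs(t, Z, n))).softplus() \
            * self.scale

    def __call__(self, t: float, Z: np.ndarray | None = None,
                 n: int = 1) -> np.ndarray:
        if Z is not None:
            n = np.atleast_2d(Z).shape[0]
        return self.forward_graph(t, Z, n).data[:, 0]


@dataclass
class KillRateField:
    """Prior kill rate k(z,t), learned modulation K_omega, birth rate b."""

    prior_k: Callable[[np.ndarray, float], np.ndarray]
    net: KillNet
    birth_rate: float = 0.0
    jitter_sd: float = 0.05

    def posterior(self, Z: np.ndarray, t: float) -> np.ndarray:
        """k' = k(z,t) * K_omega(t) >= 0."""
        return self.prior_k(Z, t) * self.net(t, Z if self.net.state_dim else None,
                                             np.atleast_2d(Z).shape[0])


@dataclass
class PopulationTarget:
    """Measured counts n_t; intermediates I_t exclude t=0."""

    timepoints: list[int]
    counts: list[int]

    def __post_init__(self):
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be >= 1")
        if len(self.timepoints) != len(self.counts):
            raise ValueError("timepoints/counts length mismatch")

    @property
    def intermediates(self) -> list[int]:
        return [t for t in self.timepoints if t != self.timepoints[0]]

    @property
    def normalizer(self) -> float:
        return float(max(self.counts))


def empirical_mass_change(target: PopulationTarget, i: int) -> float:
    """(n_i - n_0) / max_i n_i for a measured intermediate timepoint."""
    if i not in target.timepoints:
        raise ValueError(f"timepoint {i} is not measured")
    n0 = target.counts[0]
    ni = target.counts[target.timepoints.index(i)]
    return (ni - n0) / target.normalizer


def transition_probs(field: KillRateField, Z: np.ndarray, t: float,
                     dt: float):
    """Per-step death/birth probabilities, clamped to [0, 1].

    p_die = clamp(k(z,t) K_omega dt); p_born = clamp(b K_omega dt). The raw
    (unclamped) values are returned too, for the excess-probability penalty.
    """
    Z = np.atleast_2d(Z)
    n = Z.shape[0]
    K = field.net(t, Z if field.net.state_dim else None, n)
    raw_die = field.prior_k(Z, t) * K * dt
    raw_born = field.birth_rate * K * dt
    return (np.clip(raw_die, 0.0, 1.0), np.clip(raw_born, 0.0, 1.0),
            raw_die, raw_born)


def update_statuses(A: np.ndarray, p_die: np.ndarray, p_born: np.ndarray,
                    rng: np.random.Generator, Z: np.ndarray | None = None,
                    jitter_sd: float = 0.05):
    """One birth/death step: live cells die w.p. p_die, dead slots revive
    w.p. p_born.

    A revived slot's state is a jittered copy of a uniformly chosen live
    cell (the cemetery has no geometry, so re-entry must borrow one); pass
    ``Z`` to apply the re-initialization. Returns (A', events, Z').
    """
    A = np.asarray(A, float)
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("statuses must be binary")
    p_die = np.broadcast_to(np.asarray(p_die, float), A.shape)
    p_born = np.broadcast_to(np.asarray(p_born, float), A.shape)
    live = A > 0
    u = rng.random(A.shape)
    died = live & (u < p_die)
    born = (~live) & (u < p_born)
    A_new = A.copy()
    A_new[died] = 0.0
    A_new[born] = 1.0
    events = [(int(c), "death") for c in np.where(died)[0]]
    Z_new = Z
    if born.any():
        donors = np.where(live & ~died)[0]
        if donors.size == 0:
            born[:] = False
            A_new = A.copy()
            A_new[died] = 0.0
        else:
            if Z is not None:
                Z_new = Z.copy()
                src = rng.choice(donors, size=int(born.sum()))
                scale = jitter_sd * max(Z[donors].std(), 1e-8)
                Z_new[born] = Z[src] + rng.normal(0.0, scale,
                                                  size=Z[src].shape)
            events.extend((int(c), "birth") for c in np.where(born)[0])
    if A_new.sum() == 0 and p_born.max() == 0:
        import warnings
        warnings.warn("population extinct with zero birth probability")
    return A_new, events, Z_new


def make_killer(field: KillRateField):
    """Adapter with the simulate() killer signature."""

    def killer(Z, t, dt, A, rng):
        p_die, p_born, _, _ = transition_probs(field, Z, t, dt)
        A_new, events, Z_new = update_statuses(A, p_die, p_born, rng, Z=Z,
                                               jitter_sd=field.jitter_sd)
        return A_new, (Z if Z_new is None else Z_new), events

    return killer


def population_loss(field: KillRateField, path, target: PopulationTarget,
                    node_of: Callable[[float], int]) -> tuple[Tensor, float]:
    """Discretized population-matching loss for K_omega.

    For each measured intermediate i, the cumulative predicted per-cell mass
    change sum_{t<=i} E_cells[(1-A_t) clamp(p_born) - A_t clamp(p_die)] must
    match (n_i - n_0)/max_i n_i; absolute mismatches are accumulated, plus
    the excess of raw transition probabilities over their clamped values.
    Gradients flow to omega only (statuses and states are constants).
    Returns (graph scalar, detached value).
    """
    if not target.intermediates:
        import warnings
        warnings.warn("no intermediate timepoints: population loss is 0")
        return Tensor(0.0), 0.0
    dt = float(path.times[1] - path.times[0])
    n = path.Z.shape[1]
    goal_nodes = {node_of(float(i)): i for i in target.intermediates}
    last_node = max(goal_nodes)

    total = None
    penalty = None
    cum = None
    for idx in range(len(path.nodes)):
        k = int(path.nodes[idx])
        if k > last_node:
            break
        Zk = path.Z[idx]
        Ak = path.A[idx]
        t_k = float(path.times[idx])
        Kw = field.net.forward_graph(t_k, Zk if field.net.state_dim else None,
                                     n)[:, 0]
        raw_die = Tensor(field.prior_k(Zk, t_k) * dt) * Kw
        raw_born = Tensor(np.full(n, field.birth_rate * dt)) * Kw
        p_die = raw_die.clamp01_st()
        p_born = raw_born.clamp01_st()
        step = (Tensor(1.0 - Ak) * p_born - Tensor(Ak) * p_die).mean()
        cum = step if cum is None else cum + step
        pen = (raw_die - p_die).sum() * (1.0 / n) \
            + (raw_born - p_born).sum() * (1.0 / n)
        penalty = pen if penalty is None else penalty + pen
        if k in goal_nodes:
            mismatch = (cum - empirical_mass_change(target, goal_nodes[k])).abs()
            total = mismatch if total is None else total + mismatch
    loss = total + penalty
    return loss, loss.item()


def train_kill_net(field: KillRateField, model, rho0, target: PopulationTarget,
                   steps: int = 100, lr: float = 1e-2, resim_every: int = 5,
                   rng: np.random.Generator | None = None,
                   log: list | None = None) -> KillRateField:
    """Fit K_omega by simulating forward paths with the current killer and
    minimizing the population loss; drifts are frozen."""
    from .bridge import simulate
    rng = rng or np.random.default_rng()
    opt = Adam(field.net.params, lr=lr)
    path = None
    for step in range(steps):
        if path is None or step % resim_every == 0:
            z0 = rho0(rng) if callable(rho0) else np.asarray(rho0, float)
            path = simulate(model, z0, "forward", killer=make_killer(field),
                            seed=int(rng.integers(0, 2 ** 31 - 1)))
        opt.zero_grad()
        loss, val = population_loss(field, path, target, model.node_of)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite population loss at {step}")
        loss.backward()
        opt.step()
        if log is not None:
            log.append({"step": step, "loss": val})
    return field
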