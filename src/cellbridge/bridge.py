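"""Diffusion Schrödinger bridge core.

Forward and backward SDE drifts Q and Q_hat are small neural fields
approximating eps * grad log Psi and eps * grad log Psi_hat of the bridge's
potential pair; the potentials themselves are never materialized. Paths are
simulated with Euler-Maruyama on a uniform grid over [0, T]; the drifts are
trained by the alternating (IPF) likelihood scheme whose per-step integrand is

    1/2 ||Q||^2 + eps * div(Q) + <Q, Q_hat_frozen>

summed over live cells and grid steps and scaled by dt. Each half-iteration
trains one drift on paths simulated with the other drift frozen, pulling the
simulated marginal toward the opposite boundary.

The drift fields use a single tanh hidden layer so the divergence term has an
exact analytic trace that participates in the autodiff graph (no
second-order backprop is needed): for Q(u) = tanh(u W1 + b1) W2 + b2 with
u = [z || tau(t)],  div_z Q = sum_k (1 - a_k^2) * M_k, where a = tanh(h) and
M_k = sum_i W1[i, k] W2[k, i] over the z-rows of W1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Tensor
from ._ot import w2_distance
from .vae import sinusoidal_encode

__all__ = ["DriftNet", "BridgeModel", "TrajectorySample", "drift",
           "simulate", "divergence", "loss_div_forward", "loss_div_backward",
           "ipf_round"]


class DriftNet:
    """One-hidden-layer tanh vector field on (z, sinusoidal time).

    The output layer is zero-initialized, so an untrained field is
    identically zero and an untrained bridge is the base SDE.
    """

    def __init__(self, d: int, hidden: int = 64, time_dim: int = 8,
                 seed: int = 0):
        self.d = d
        self.hidden = hidden
        self.time_dim = time_dim
        rng = np.random.default_rng(seed)
        fan_in = d + time_dim
        self.W1 = Tensor(rng.normal(0, np.sqrt(2.0 / (fan_in + hidden)),
                                    size=(fan_in, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = Tensor(np.zeros((hidden, d)), requires_grad=True)
        self.b2 = Tensor(np.zeros(d), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _with_time(self, Z: np.ndarray, t: float) -> np.ndarray:
        tau = sinusoidal_encode(t, self.time_dim)
        return np.hstack([Z, np.broadcast_to(tau, (Z.shape[0], self.time_dim))])

    def forward_graph(self, Z: np.ndarray, t: float) -> Tensor:
        u = Tensor(self._with_time(np.asarray(Z, float), t))
        return (u @ self.W1 + self.b1).tanh() @ self.W2 + self.b2

    def __call__(self, Z: np.ndarray, t: float) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != self.d:
            raise ValueError(f"expected (n, {self.d}) latent states, "
                             f"got {Z.shape}")
        return self.forward_graph(Z, t).data

    def div_graph(self, Z: np.ndarray, t: float) -> Tensor:
        """Exact divergence wrt z as a graph node (gradients reach W1, W2)."""
        u = Tensor(self._with_time(np.asarray(Z, float), t))
        a = (u @ self.W1 + self.b1).tanh()
        s = 1.0 - a * a                        # tanh'(h), shape (n, H)
        M = (self.W1[:self.d, :] * self.W2.T).sum(axis=0)  # (H,)
        return (s * M).sum(axis=1)

    def div_exact(self, Z: np.ndarray, t: float) -> np.ndarray:
        return self.div_graph(Z, t).data

    def jvp(self, Z: np.ndarray, t: float, v: np.ndarray) -> np.ndarray:
        """Directional derivative J(z) v, one probe v shared across cells."""
        u = self._with_time(np.asarray(Z, float), t)
        h = u @ self.W1.data + self.b1.data
        s = 1.0 - np.tanh(h) ** 2
        return (s * (v @ self.W1.data[:self.d])) @ self.W2.data

    def state(self):
        return {"W1": self.W1.data.copy(), "b1": self.b1.data.copy(),
                "W2": self.W2.data.copy(), "b2": self.b2.data.copy()}

    def load_state(self, d):
        for name in ("W1", "b1", "W2", "b2"):
            getattr(self, name).data = np.asarray(d[name], float).copy()


def drift(net: DriftNet, Z: np.ndarray, t: float) -> np.ndarray:
    """Evaluate a drift field; deterministic in (params, Z, t)."""
    return net(Z, t)


@dataclass
class BridgeModel:
    """Drift pair plus the fixed SDE constants.

    f is the base drift (scalar or length-d vector, default 0); eps the
    diffusion coefficient; the time grid is uniform with n_steps intervals
    on [0, T].
    """

    d: int
    T: float
    eps: float = 0.1
    n_steps: int = 100
    f: float | np.ndarray = 0.0
    hidden: int = 64
    time_dim: int = 8
    seed: int = 0
    fwd: DriftNet = field(init=False)
    bwd: DriftNet = field(init=False)

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        self.fwd = DriftNet(self.d, self.hidden, self.time_dim, seed=self.seed)
        self.bwd = DriftNet(self.d, self.hidden, self.time_dim,
                            seed=self.seed + 1)

    @property
    def dt(self) -> float:
        return self.T / self.n_steps

    @property
    def t_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.T, self.n_steps + 1)

    def node_of(self, t: float) -> int:
        """Grid node nearest to time t."""
        return int(round(t / self.dt))

    def base_drift(self, Z: np.ndarray) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.f, float), Z.shape)


@dataclass
class TrajectorySample:
    """Discretized latent path with per-cell live/dead statuses.

    Z[k] is the state at grid node nodes[k] (ascending physical time); A[k]
    the binary statuses; events logs (node, cell, 'birth'|'death').
    """

    Z: np.ndarray                # (n_nodes, n, d)
    A: np.ndarray                # (n_nodes, n) in {0, 1}
    nodes: np.ndarray            # grid node indices, ascending
    times: np.ndarray            # physical times of the nodes
    direction: str               # 'forward' | 'backward'
    events: list
    noise_seed: int

    def state_at_node(self, node: int) -> tuple[np.ndarray, np.ndarray]:
        k = int(np.where(self.nodes == node)[0][0])
        return self.Z[k], self.A[k]


def simulate(model: BridgeModel, Z0: np.ndarray, direction: str,
             killer=None, seed: int = 0, start_node: int = 0
             ) -> TrajectorySample:
    """Euler-Maruyama simulation of the forward or backward SDE.

    forward:  z_{k+1} = z_k + [f + eps Q(z_k, t_k)] dt + eps sqrt(dt) eta,
              from node ``start_node`` up to n_steps, Z0 ~ rho_0.
    backward: z_{k-1} = z_k - [f - eps Q_hat(z_k, t_k)] dt + eps sqrt(dt) eta,
              from n_steps down to 0 in physical time, Z0 ~ rho_T.

    ``killer(Z, t, dt, A, rng) -> (A', Z', events)`` applies the birth/death
    status update at every step (forward direction only).
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    Z0 = np.asarray(Z0, dtype=float)
    n, d = Z0.shape
    if d != model.d:
        raise ValueError(f"latent dim mismatch: {d} != {model.d}")
    rng = np.random.default_rng(seed)
    dt = model.dt
    sig = model.eps * np.sqrt(dt)

    if direction == "forward":
        nodes = np.arange(start_node, model.n_steps + 1)
    else:
        nodes = np.arange(start_node, model.n_steps + 1)
    n_nodes = len(nodes)
    Z = np.empty((n_nodes, n, d))
    A = np.ones((n_nodes, n))
    events: list = []

    z = Z0.copy()
    a = np.ones(n)

    if direction == "forward":
        for i, k in enumerate(nodes):
            Z[i] = z
            A[i] = a
            if i == n_nodes - 1:
                break
            t_k = k * dt
            b = model.base_drift(z) + model.eps * model.fwd(z, t_k)
            z = z + b * dt + sig * rng.standard_normal(z.shape)
            if not np.all(np.isfinite(z)):
                raise FloatingPointError(
                    f"non-finite state in forward simulation at node {k}")
            if killer is not None:
                a, z, ev = killer(z, t_k + dt, dt, a, rng)
                events.extend((int(k + 1), c, kind) for c, kind in ev)
                if a.sum() == 0:
                    import warnings
                    warnings.warn("all cells dead; stopping path early")
                    for j in range(i + 1, n_nodes):
                        Z[j] = z
                        A[j] = a
                    break
    else:
        # fill nodes from n_steps down to start_node (descending physical time)
        for i in range(n_nodes - 1, -1, -1):
            k = nodes[i]
            Z[i] = z
            A[i] = a
            if i == 0:
                break
            t_k = k * dt
            b = model.base_drift(z) - model.eps * model.bwd(z, t_k)
            z = z - b * dt + sig * rng.standard_normal(z.shape)
            if not np.all(np.isfinite(z)):
                raise FloatingPointError(
                    f"non-finite state in backward simulation at node {k}")

    return TrajectorySample(Z=Z, A=A, nodes=nodes, times=nodes * dt,
                            direction=direction, events=events,
                            noise_seed=seed)


def divergence(vfield, Z: np.ndarray, t: float = 0.0, method: str = "auto",
               d_exact: int = 16, n_probes: int = 8,
               rng: np.random.Generator | None = None,
               exhaustive: bool = False) -> np.ndarray:
    """Per-cell divergence (trace of the z-Jacobian) of a vector field.

    ``vfield`` is a DriftNet (analytic trace / analytic JVP probes) or any
    callable z -> v(z) (central finite differences, exact for affine fields).
    method 'auto' uses the exact trace when d <= d_exact, else Hutchinson
    with ``n_probes`` Rademacher probes; ``exhaustive=True`` enumerates all
    2^d sign vectors, which makes the Hutchinson estimate exact.
    """
    Z = np.asarray(Z, dtype=float)
    n, d = Z.shape
    if method == "auto":
        method = "exact" if d <= d_exact else "hutchinson"

    is_net = isinstance(vfield, DriftNet)

    def fd_jvp(v):
        h = 1e-5
        if is_net:
            return vfield.jvp(Z, t, v)
        return (vfield(Z + h * v) - vfield(Z - h * v)) / (2 * h)

    if method == "exact":
        if is_net:
            return vfield.div_exact(Z, t)
        out = np.zeros(n)
        for i in range(d):
            e = np.zeros(d)
            e[i] = 1.0
            out += fd_jvp(e)[:, i]
        return out
    if method == "hutchinson":
        if exhaustive or n_probes >= 2 ** d:
            probes = np.array(np.meshgrid(*([[-1.0, 1.0]] * d)),
                              ).reshape(d, -1).T
        else:
            rng = rng or np.random.default_rng()
            probes = rng.choice([-1.0, 1.0], size=(n_probes, d))
        acc = np.zeros(n)
        for v in probes:
            acc += (fd_jvp(v) * v).sum(axis=1)
        return acc / len(probes)
    raise ValueError(f"unknown method {method!r}")


def _loss_div(train_net: DriftNet, frozen_net: DriftNet,
              path: TrajectorySample, eps: float, dt: float) -> Tensor:
    """dt * sum over non-terminal nodes and live cells of the integrand."""
    total = None
    for k in range(len(path.nodes) - 1):
        Zk = path.Z[k]
        t_k = float(path.times[k])
        mask = Tensor(path.A[k])
        Q = train_net.forward_graph(Zk, t_k)
        qhat = frozen_net(Zk, t_k)            # frozen: plain numpy constant
        term = (Q * Q).sum(axis=1) * 0.5 \
            + eps * train_net.div_graph(Zk, t_k) \
            + (Q * Tensor(qhat)).sum(axis=1)
        contrib = (mask * term).sum()
        total = contrib if total is None else total + contrib
    return total * dt


def loss_div_forward(model: BridgeModel, path: TrajectorySample) -> Tensor:
    """Likelihood loss for the forward drift Q; needs a backward-simulated path."""
    if path.direction != "backward":
        raise ValueError("loss_div_forward requires a backward-simulated path")
    return _loss_div(model.fwd, model.bwd, path, model.eps, model.dt)


def loss_div_backward(model: BridgeModel, path: TrajectorySample) -> Tensor:
    """Likelihood loss for the backward drift Q_hat; needs a forward path."""
    if path.direction != "forward":
        raise ValueError("loss_div_backward requires a forward-simulated path")
    return _loss_div(model.bwd, model.fwd, path, model.eps, model.dt)


def _draw(rho, rng: np.random.Generator) -> np.ndarray:
    return rho(rng) if callable(rho) else np.asarray(rho, float)


def ipf_round(model: BridgeModel, rho0, rhoT, inner_steps: int = 200,
              lr: float = 1e-3, resim_every: int = 10, killer=None,
              joint_hook=None, rng: np.random.Generator | None = None,
              diagnostics: list | None = None) -> BridgeModel:
    """One IPF iteration: a forward pass then a backward pass.

    forward pass: simulate the backward SDE from rho_T and minimize the
    forward-drift loss (Q_hat frozen); ``joint_hook(model, fwd_path, rng)``
    is called after each re-simulation so a caller can co-train a VAE.
    backward pass: simulate the forward SDE from rho_0 (with the killer's
    birth/death updates if given) and minimize the backward-drift loss.
    Appends a boundary-matching record (W2 between simulated and target
    boundary samples) to ``diagnostics`` if provided.
    """
    rng = rng or np.random.default_rng()

    def seed32():
        return int(rng.integers(0, 2 ** 31 - 1))

    # -- forward pass: train theta on backward paths -----------------------
    opt = Adam(model.fwd.params, lr=lr)
    path = None
    for step in range(inner_steps):
        if path is None or step % resim_every == 0:
            path = simulate(model, _draw(rhoT, rng), "backward", seed=seed32())
            if joint_hook is not None:
                fwd_path = simulate(model, _draw(rho0, rng), "forward",
                                    killer=killer, seed=seed32())
                joint_hook(model, fwd_path, rng)
        opt.zero_grad()
        loss = loss_div_forward(model, path)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"diverging forward loss at step {step}")
        loss.backward()
        opt.step()

    # -- backward pass: train theta_hat on forward paths -------------------
    opt = Adam(model.bwd.params, lr=lr)
    path = None
    for step in range(inner_steps):
        if path is None or step % resim_every == 0:
            path = simulate(model, _draw(rho0, rng), "forward",
                            killer=killer, seed=seed32())
        opt.zero_grad()
        loss = loss_div_backward(model, path)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"diverging backward loss at step {step}")
        loss.backward()
        opt.step()

    if diagnostics is not None:
        f_path = simulate(model, _draw(rho0, rng), "forward", killer=killer,
                          seed=seed32())
        b_path = simulate(model, _draw(rhoT, rng), "backward", seed=seed32())
        zT = f_path.Z[-1][f_path.A[-1] > 0]
        diagnostics.append({
            "w2_terminal": w2_distance(zT, _draw(rhoT, rng)),
            "w2_initial": w2_distance(b_path.Z[0], _draw(rho0, rng)),
        })
    return model
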