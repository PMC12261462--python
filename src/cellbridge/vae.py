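"""Time-conditioned variational autoencoder.

The encoder maps a cell's expression concatenated with a sinusoidal encoding
of its timepoint to a diagonal Gaussian N(mu, sigma^2) over a d-dimensional
latent space; the decoder maps (z || t) back to expression. Training
minimizes MSE reconstruction plus beta * KL(q(z|x) || N(0, I)). Because t is
a real-valued input, the trained model encodes and decodes at unmeasured
times as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam, Tensor, concat

__all__ = ["EncoderOutput", "VaeModel", "sinusoidal_encode", "encode",
           "sample_latent", "decode", "vae_loss", "pretrain"]


def sinusoidal_encode(t: float, dim: int) -> np.ndarray:
    """Transformer-style sin/cos features of a scalar time.

    Feature pairs (sin(t*w_i), cos(t*w_i)) at geometrically spaced
    frequencies w_i = 10000^(-2i/dim); deterministic and bounded by 1.
    """
    if dim < 2 or dim % 2 != 0:
        raise ValueError("time encoding dim must be an even integer >= 2")
    half = dim // 2
    freqs = 10000.0 ** (-2.0 * np.arange(half) / dim)
    ang = float(t) * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)])


@dataclass
class EncoderOutput:
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu/sigma shape mismatch")
        if not np.all(self.sigma > 0):
            raise ValueError("sigma must be positive")


@dataclass
class VaeModel:
    """Encoder/decoder MLPs plus the latent and time-encoding dimensions.

    The encoder outputs 2d units (mu, then pre-softplus sigma); sigma is a
    per-dimension diagonal. beta >= 0 weights the KL term.
    """

    n_genes: int
    latent_dim: int = 16
    time_dim: int = 16
    hidden: tuple[int, ...] = (128, 128)
    beta: float = 0.01
    seed: int = 0
    encoder: MLP = field(init=False)
    decoder: MLP = field(init=False)

    def __post_init__(self):
        if self.latent_dim >= self.n_genes:
            raise ValueError("latent_dim must be < n_genes")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        rng = np.random.default_rng(self.seed)
        self.encoder = MLP([self.n_genes + self.time_dim, *self.hidden,
                            2 * self.latent_dim], rng, activation="silu")
        self.decoder = MLP([self.latent_dim + self.time_dim, *self.hidden,
                            self.n_genes], rng, activation="silu")

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    def _with_time(self, M: np.ndarray, t: float) -> np.ndarray:
        tau = sinusoidal_encode(t, self.time_dim)
        return np.hstack([M, np.broadcast_to(tau, (M.shape[0], self.time_dim))])

    # graph-mode passes used during training -------------------------------
    def encode_graph(self, X: np.ndarray, t: float) -> tuple[Tensor, Tensor]:
        out = self.encoder.forward(Tensor(self._with_time(X, t)))
        d = self.latent_dim
        mu = out[:, :d]
        sigma = out[:, d:].softplus()
        return mu, sigma

    def decode_graph(self, Z: Tensor, t: float) -> Tensor:
        n = Z.shape[0]
        tau = sinusoidal_encode(t, self.time_dim)
        taut = Tensor(np.broadcast_to(tau, (n, self.time_dim)).copy())
        return self.decoder.forward(concat([Z, taut], axis=1))


def encode(model: VaeModel, X: np.ndarray, t: float) -> EncoderOutput:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_genes:
        raise ValueError(f"expected {model.n_genes} genes, got {X.shape[1]}")
    mu, sigma = model.encode_graph(X, t)
    return EncoderOutput(mu.data.copy(), sigma.data.copy())


def sample_latent(out: EncoderOutput, rng: np.random.Generator | None = None,
                  noise: np.ndarray | None = None) -> np.ndarray:
    """Reparameterized draw z = mu + sigma * eta, eta ~ N(0, I)."""
    if noise is None:
        noise = (rng or np.random.default_rng()).standard_normal(out.mu.shape)
    return out.mu + out.sigma * noise


def decode(model: VaeModel, Z: np.ndarray, t: float) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != model.latent_dim:
        raise ValueError(f"expected latent dim {model.latent_dim}, "
                         f"got {Z.shape[1]}")
    return model.decode_graph(Tensor(Z), t).data.copy()


def _kl_graph(mu: Tensor, sigma: Tensor) -> Tensor:
    # KL(N(mu, sigma^2) || N(0, I)) = 1/2 sum(mu^2 + sigma^2 - 1 - log sigma^2)
    per_cell = ((mu * mu + sigma * sigma - 1.0 - sigma.log() * 2.0)
                * 0.5).sum(axis=1)
    return per_cell.mean()


def vae_loss(model: VaeModel, X: np.ndarray, t: float, beta: float,
             noise: np.ndarray | None = None,
             rng: np.random.Generator | None = None
             ) -> tuple[Tensor, dict[str, float]]:
    """Eq.-style VAE objective: MSE(X, X_hat) + beta * KL, with components.

    Returns the graph-mode scalar (call .backward() to train) and a dict of
    the detached component values. MSE is the mean over cells and genes; KL
    is the mean over cells of the per-cell closed-form diagonal-Gaussian KL.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    X = np.asarray(X, dtype=float)
    mu, sigma = model.encode_graph(X, t)
    if noise is None:
        noise = (rng or np.random.default_rng()).standard_normal(mu.shape)
    z = mu + sigma * Tensor(noise)
    xhat = model.decode_graph(z, t)
    mse = ((xhat - Tensor(X)) ** 2.0).mean()
    kl = _kl_graph(mu, sigma)
    total = mse + beta * kl
    return total, {"mse": mse.item(), "kl": kl.item(), "total": total.item()}


def pretrain(model: VaeModel, data, epochs: int = 200, lr: float = 1e-3,
             batch_size: int = 128, seed: int = 0, patience: int = 30,
             beta_warmup: int = 0, log: list | None = None) -> VaeModel:
    """Minibatch Adam on the VAE objective over all measured timepoints.

    Batches are stratified by timepoint so each carries a single valid t for
    the time encoding. Early-stops when the epoch loss has not improved by
    0.1% for ``patience`` epochs. With ``beta_warmup`` > 0 the KL weight
    ramps linearly from 0 to model.beta over that many epochs.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr)
    best, stale = np.inf, 0
    for epoch in range(epochs):
        beta = model.beta if beta_warmup <= 0 else \
            model.beta * min(1.0, (epoch + 1) / beta_warmup)
        batches = []
        for t in data.timepoints:
            idx = rng.permutation(data.n_cells(t))
            for s in range(0, len(idx), batch_size):
                batches.append((t, idx[s:s + batch_size]))
        order = rng.permutation(len(batches))
        ep_loss = 0.0
        for bi in order:
            t, idx = batches[bi]
            X = data.matrix(t)[idx]
            opt.zero_grad()
            loss, comp = vae_loss(model, X, float(t), beta, rng=rng)
            if not np.isfinite(comp["total"]):
                raise RuntimeError(f"non-finite VAE loss at epoch {epoch}, "
                                   f"timepoint {t}: {comp}")
            loss.backward()
            opt.step()
            ep_loss += comp["total"] * len(idx)
        ep_loss /= sum(data.counts)
        if log is not None:
            log.append({"epoch": epoch, "loss": ep_loss, "beta": beta})
        if ep_loss < best * 0.999:
            best, stale = ep_loss, 0
        else:
            stale += 1
            if stale >= patience:
                break
    return model
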