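# cellbridge

Continuous single-cell trajectories from discrete time-series snapshots.

Single-cell sequencing destroys the cells it measures, so a time-course
experiment yields unaligned cross-sections X_t ∈ R^{n_t×g} at a handful of
timepoints — and the population itself grows and shrinks between them as
cells divide and die. `cellbridge` reconstructs the continuous stochastic
process behind such data for anyone studying differentiation, development,
or disease progression with time-series scRNA-seq: it predicts expression at
unmeasured timepoints, recovers relative cell-population changes, ranks the
genes driving the deterministic trend, and simulates in-silico
perturbations.

## Model

A time-conditioned variational autoencoder maps each cell (concatenated
with a sinusoidal time encoding) to a d-dimensional latent space,
z ~ N(μ_φ(x‖t), σ²_φ(x‖t)), trained with MSE reconstruction plus
β·KL(q‖N(0, I)). In that latent space, an unbalanced diffusion Schrödinger
bridge connects the boundary timepoints: a forward/backward SDE pair

    dZ→ = [f + ε Q_θ(Z→, t)] dt + ε dW,      Z→₀ ~ ρ₀
    dZ← = [f − ε Q̂_θ̂(Z←, t)] dt + ε dW̄,     Z←₀ ~ ρ_T

whose neural drifts Q ≈ ε∇log Ψ, Q̂ ≈ ε∇log Ψ̂ are trained by iterative
proportional fitting: each half-iteration simulates one SDE (Euler–Maruyama,
100-step grid) and minimizes the likelihood integrand
½‖Q‖² + ε∇·Q + ⟨Q, Q̂_frozen⟩ for the other drift. Population changes enter
through a cemetery state: a data-derived prior kill rate (fraction of latent
features > 2 sd from the next measured timepoint's mean, floored below 20%)
is modulated by a learned positive network K_ω(t), trained so cumulative
predicted birth/death mass matches the empirical (n_i − n_0)/max_i n_i at
each measured timepoint. The VAE is co-trained in the forward pass via
L_joint = W2(Z_φ,t, Z→_t) + W2(X_t, p_ϕ(Z_φ,t)).

All networks run on a compact numpy autodiff engine included in the package
(`cellbridge._nn`); optimal transport uses scipy (exact assignment/LP for
small point sets, log-domain Sinkhorn above). See `docs/methods.md` for the
full account.

## Worked example

Everything is testable without downloads: the synthetic generator draws
latent SDE paths with a known drift, known death schedule and known
latent-to-gene map.

```python
import numpy as np
import cellbridge as cb
from cellbridge import trainer, downstream, vae

# 5 timepoints, 300 cells each, 50 genes; population halves in a death
# window over t in [1, 3]
data, truth = cb.simulate_timeseries(
    d=2, g=50, T=4, counts=[300, 300, 200, 150, 150],
    drift_spec="linear", speed=2.0, eps=0.3,
    death_window=(1.0, 3.0, "auto"), seed=21)

cfg = cb.TrainConfig(seed=9, latent_dim=4, vae_hidden=(64, 64),
                     vae_epochs=80, n_steps=40, ipf_rounds=3,
                     inner_steps=60, drift_lr=2e-3, kill_steps=120,
                     kill_lr=2e-2, eps=0.3)
vae_model, bridge_model, kill_field, report = trainer.fit(data, cfg)

_, A, _ = downstream.reconstruct_trajectory(
    vae_model, bridge_model, data.matrix(0), seed=3, field=kill_field)
nodes = [bridge_model.node_of(float(t)) for t in data.timepoints]
print(np.round(downstream.population_ratios(A[nodes]), 3))
print(np.round(downstream.population_ratios(truth.counts), 3))
```

prints

```
[1.    0.68  0.762 0.9  ]
[1.    0.677 0.793 0.839]
```

— the predicted relative population-change ratios (consecutive n_t/n_{t−1},
normalized by their maximum, from the live/dead statuses of the
reconstructed trajectory) against the ground-truth ratios: the model
recovers the decline through the death window within a few percent at every
timepoint without ever being told the intermediate counts' timing.

Held-out prediction works the same way:

```python
train, store = cb.heldout_split(data, {2})
vae_model, bridge_model, kill_field, _ = trainer.fit(train, cfg)
print(trainer.evaluate_heldout(vae_model, bridge_model, kill_field,
                               train, store, replicates=3, seed=7))
```

which reports the gene-space 2-Wasserstein distance between decoded
predictions and the held-out snapshot (mean ± sd over sampling replicates)
next to a naive baseline that copies the previous measured timepoint.

A CLI mirrors the library: `cellbridge simulate | preprocess | train |
evaluate | reconstruct | drift-genes | population | perturb | de`, each
writing a manifest (config hash, seed, input checksums) into its output
directory.

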