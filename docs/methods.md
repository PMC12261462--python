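# Methods

## Problem and model

Time-series scRNA-seq gives cross-sectional snapshots X_t ∈ R^{n_t×g} of an
evolving, unaligned cell population at integer timepoints t ∈ {0..T}. The
package reconstructs a continuous stochastic trajectory between these
snapshots, with three coupled components:

1. **Time-conditioned VAE.** An encoder q_φ(x‖τ(t)) = N(μ, diag σ²) maps a
   cell concatenated with a sinusoidal time encoding τ(t) into a
   d-dimensional latent space (d ≪ g); a decoder p_ϕ(z‖τ(t)) maps back.
   Training minimizes MSE(X, X̂) + β·KL(q‖N(0, I)) with the closed-form
   diagonal-Gaussian KL. Because t enters as a real-valued feature, encoding
   and decoding are defined at unmeasured times as well.

2. **Diffusion Schrödinger bridge in latent space.** The bridge is the pair
   of SDEs
   dZ→ = [f + εQ(Z→, t)]dt + ε dW (forward, Z→₀ ~ ρ₀) and its reversal with
   drift [f − εQ̂] started from ρ_T, where ρ₀, ρ_T are the encoder
   posteriors at the boundary timepoints, f and ε are fixed constants, and
   Q ≈ ε∇log Ψ, Q̂ ≈ ε∇log Ψ̂ are neural vector fields standing in for the
   gradients of the bridge potential pair (the potentials themselves are
   never materialized). Paths are discretized by Euler–Maruyama on a uniform
   grid (default 100 steps; per-step noise sd ε√Δt). Training alternates IPF
   half-iterations: each trains one drift on paths simulated with the other
   drift frozen, with the per-step likelihood integrand
   ½‖Q‖² + ε∇·Q + ⟨Q, Q̂_frozen⟩ masked by live-cell statuses, summed over
   the non-terminal grid nodes, and scaled by Δt. By the integration-by-
   parts identity E_p[ε∇·Q] = −ε E_p[⟨Q, ∇log p⟩], the minimizer of one
   half-iteration is Q* = ε∇log p_t − Q̂ on the simulated marginals, whose
   induced forward SDE is exactly the time reversal of the sampled backward
   process — this is what drives the boundary marginals together across
   rounds.

3. **Unbalanced dynamics.** The latent space is augmented with a single
   cemetery state. A data-derived prior kill rate k(z, t) is the fraction of
   latent features deviating by more than two standard deviations from the
   mean of the *next measured* timepoint's latent ensemble, floored to 0
   below 20% deviating. A small positive network K_ω(t) (softplus MLP on
   sinusoidal time; optionally state-dependent) modulates it: the per-step
   death probability is clamp(k·K_ω·Δt) and the birth probability
   clamp(b·K_ω·Δt) with birth rate b. K_ω is trained so the cumulative
   predicted per-cell mass change at each measured intermediate timepoint i
   matches the empirical normalized change (n_i − n_0)/max_i n_i, plus a
   penalty on raw transition probabilities exceeding 1 (the clamp uses a
   straight-through gradient). The mass-change terms are means over cells:
   the empirical target is a normalized fraction, so the predicted side must
   be an expectation per cell rather than a cell count for the two to be
   commensurate.

The VAE is co-trained during the IPF forward pass through a joint loss: the
2-Wasserstein distance between encoder latents and forward-path states at
each measured grid node, plus the W2 between data and its reconstruction.
Gradients of the W2 terms are taken at a fixed optimal coupling (exact
assignment on equal-size subsamples), which is the correct subgradient of
the squared distance.

## Numerical choices

- **All networks run on a small numpy reverse-mode autodiff engine**
  (`_nn.py`) with Adam. Everything is float64 and deterministic given the
  seeded numpy generators; `fit` is reproducible bit-for-bit under a fixed
  seed and single-threaded BLAS.
- **Drift fields have one tanh hidden layer** (zero-initialized output, so
  the untrained bridge is the base SDE). With one hidden layer the
  divergence has an exact analytic form, div Q = Σ_k tanh′(h_k)·M_k with
  M_k = Σ_i W1[i,k]W2[k,i] over the z-rows of W1, which participates in the
  autodiff graph directly — training the ε∇·Q term then needs only
  first-order backprop, no double backward. Encoder/decoder/kill nets are
  two-hidden-layer SiLU MLPs by default.
- **Divergence estimators.** Exact analytic trace for drift nets (O(hidden)
  cost, used whenever d ≤ 16); central finite differences for arbitrary
  callables (exact for affine fields); Hutchinson with Rademacher probes for
  high dimension. Averaging over *all* 2^d sign vectors cancels every
  off-diagonal Jacobian term, making the Hutchinson estimate exact; the
  exhaustive mode is used wherever an exact cross-check is wanted and d is
  small.
- **2-Wasserstein distance.** Exact Hungarian assignment when |A| = |B| ≤
  512 (equal uniform weights make assignment optimal); exact transport LP
  (HiGHS, sparse constraints) for unequal small sets; log-domain Sinkhorn
  with a small cost-scaled regularizer above that. The reported value is
  the square root of the optimal squared-Euclidean cost.
- **Backward simulation** steps physical time downward:
  z_{k−1} = z_k − [f − εQ̂(z_k, t_k)]Δt + ε√Δt·η, so forward and backward
  paths share one grid and the likelihood losses evaluate both drifts at
  aligned (state, time) pairs.
- **Clamps and ties.** ⌈x⌋ = clip(x, 0, 1) with straight-through gradient;
  constant genes z-score to 0; HVG ties at the cutoff are broken by
  normalized-dispersion rank; held-out integer timepoints map to the
  nearest grid node (exact when T divides the grid).
- **Births** re-enter at a jittered copy of a uniformly chosen live cell
  (jitter sd = 0.05 × the live cells' latent sd): the cemetery state has no
  geometry, and copying live cells preserves the current marginal. Birth
  rate b defaults to 0 unless measured counts increase anywhere, then 1,
  with K_ω modulating both directions.
- **Degenerate inputs.** Zero-total cells are a hard error before depth
  scaling; a constant anchor gene is a hard error in the correlation
  filter; an all-dead population with zero birth probability stops the path
  early with a warning.

## Preprocessing pipeline

Depth scaling to a common per-cell total (default: the median total over
training cells), then log1p; a meta flag guards against re-application.
HVG selection is Seurat-flavor mean-binned normalized dispersion on pooled
training cells only; the boolean mask is then applied to held-out data
(no leakage). The optional anchor-correlation filter removes every gene
with Pearson r above the threshold on pooled log-normalized cells —
including the anchor itself (r = 1). The default order is filter-then-HVG;
both steps are plain functions, so the order is the caller's choice.
Z-scoring uses the unbiased (ddof = 1) sd, computed on training cells and
reusable on held-out cells via the recorded (mean, sd). Timepoint labels
are relabeled to consecutive integers from 0 (numeric labels sort
numerically; duration-style labels like `8h`, `1d`, `3d` sort by duration);
the original mapping is kept in `meta`.

## Synthetic study systems

The generator draws independent latent Euler–Maruyama paths of a chosen
drift (constant advance, a double-well, or a branching field that advances
coordinate 0 at unit speed while coordinate 1 falls into one of two wells),
optionally kills cells at a constant hazard inside a death window
(`rate="auto"` calibrates the hazard to the prescribed count decline), and
maps latents to genes by a fixed full-row-rank linear loading followed by
softplus plus Gaussian gene noise. Driver genes load exclusively on the
advancing coordinate, so the drift-gene ground truth is unambiguous. The
generator emulates the *structure* the model assumes — smooth latent SDE
dynamics, time-varying population size, a low-dimensional latent-to-gene
map. It does not emulate scRNA-seq count noise (dropout, overdispersion),
library-size confounding, or batch effects; tests passing on it show the
machinery recovers known dynamics under the model's own assumptions, not
that it is robust to real technical noise.

Default study conditions used by the tests and the acceptance script:
300 cells per timepoint and 50 genes (5 drivers) on 5 timepoints, 40 grid
steps, ε = 0.3; the two-Gaussian bridge task uses N(−2, 0.1) → N(2, 0.1),
ε = 0.5, 20 grid steps, 500 points per side; the population scenario uses
counts [300, 300, 200, 150, 150] with a death window on t ∈ [1, 3]. These
sizes keep a full pipeline run to minutes on one CPU while leaving the
statistical margins (driver recovery, baseline comparisons) wide.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `latent_dim` d | 16 | latent dimension (≪ g) |
| `beta` β | 0.01 | KL weight, linear warm-up over 20 epochs |
| `eps` ε | 0.1 | diffusion coefficient; the single most performance-sensitive constant |
| `f` | 0 | base drift (constant) |
| `n_steps` | 100 | Euler–Maruyama grid intervals on [0, T] |
| `ipf_rounds` | 6 | IPF iterations (one forward + one backward pass each) |
| `inner_steps` | 200 | Adam steps per half-pass (paths re-simulated every `resim_every`) |
| `lambda_joint`, `lambda_omega` | 1.0 | joint/population loss weights |
| `birth_rate` b | auto | 0, or 1 when measured counts grow |

## Perturbation analysis

In-silico perturbation adds a signed level to one gene *in the scaled
(z-scored) gene space* before encoding, simulates perturbed and unperturbed
groups to T with shared noise (common random numbers), classifies all
latent states at measured grid nodes with an MLP trained on encoder means,
and compares per-timepoint assignment counts across trials with a two-sided
t-test. At level 0 the two groups are bit-identical by construction, so the
test is degenerate and its p-value is reported as 1 (no evidence of a
shift). Perturbation pushes cells off the data manifold; the encoder's
response is only reliable in the direction the training data supports —
overexpression of a driver behaves as expected, while large
*under*-expression can leave the expression range the encoder ever saw and
produce incoherent assignments. This is a known limitation, shared with any
encoder-based perturbation scheme.

## Known limitations

- The alternating IPF scheme has no global convergence guarantee with
  neural drifts and finite inner steps; the boundary-matching W2
  diagnostics logged per round are the practical check.
- The kill mechanism can only revive slots that died earlier along the
  path, so a trajectory's population cannot exceed its initial size;
  relative ratios are unaffected.
- Whether the prior kill rate's "features" are genes or latent dimensions
  is a modeling choice; latent features are the default (the kill decision
  happens in latent space during simulation), with the state-dependent
  kill-net flag exposing the alternative input.
- Drift-gene p-values come from a one-sample Wilcoxon signed-rank test on
  per-cell projected drift with BH adjustment — a documented default, one
  of several defensible tests for "is this gene's mean projected drift
  nonzero".
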