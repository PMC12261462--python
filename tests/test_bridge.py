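"""Bridge core: Euler-Maruyama, divergence estimators, likelihood losses, IPF."""

import numpy as np
import pytest
from scipy import stats as sps

from cellbridge import bridge as br
from cellbridge._ot import w2_distance


def _const_drift_model(c, d=2, T=1.0, eps=1.0, n_steps=10, forward=True):
    m = br.BridgeModel(d=d, T=T, eps=eps, n_steps=n_steps, seed=0)
    net = m.fwd if forward else m.bwd
    net.b2.data = np.asarray(c, float) / m.eps  # eps * Q = c
    return m


# ----------------------------------------------------------- simulation -----

def test_degenerate_sde_is_constant():
    m = br.BridgeModel(d=2, T=1.0, eps=1e-300, n_steps=10, seed=0)
    Z0 = np.random.default_rng(0).normal(size=(5, 2))
    path = br.simulate(m, Z0, "forward", seed=1)
    assert np.allclose(path.Z, Z0[None], atol=1e-12)


def test_increment_variance_matches_eps2_dt():
    m = br.BridgeModel(d=2, T=1.0, eps=1.0, n_steps=20, seed=0)
    path = br.simulate(m, np.zeros((10_000, 2)), "forward", seed=3)
    inc = np.diff(path.Z, axis=0).ravel()
    var = inc.var()
    target = m.eps ** 2 * m.dt
    se = np.sqrt(2.0 / (inc.size - 1)) * target   # SE of a variance estimate
    assert abs(var - target) < 3 * se


def test_constant_drift_recovers_cT_exactly():
    c = np.array([0.5, -1.0])
    m = _const_drift_model(c, T=2.0, eps=1.0, n_steps=10)
    m.eps = 1e-300  # suppress both noise and the eps*Q scaling -> use f
    m.f = c
    m.fwd.b2.data[:] = 0.0
    path = br.simulate(m, np.zeros((3, 2)), "forward", seed=0)
    assert np.allclose(path.Z[-1] - path.Z[0], c * m.T, atol=1e-10)


def test_no_killer_conserves_cell_count_and_statuses():
    m = br.BridgeModel(d=2, T=1.0, eps=0.5, n_steps=15, seed=1)
    path = br.simulate(m, np.zeros((40, 2)), "forward", seed=2)
    assert np.all(path.A == 1.0)
    assert path.Z.shape == (16, 40, 2)


def test_forward_backward_distributionally_identical_when_driftless():
    """Zero drifts, f=0: both directions are the same Gaussian random walk."""
    m = br.BridgeModel(d=1, T=1.0, eps=0.8, n_steps=20, seed=0)
    rng = np.random.default_rng(5)
    Z0 = rng.normal(size=(5000, 1))
    fwd = br.simulate(m, Z0.copy(), "forward", seed=10)
    bwd = br.simulate(m, Z0.copy(), "backward", seed=11)
    stat = sps.ks_2samp(fwd.Z[-1].ravel(), bwd.Z[0].ravel())
    assert stat.pvalue > 0.01


def test_simulation_determinism_and_dim_error():
    m = br.BridgeModel(d=3, T=1.0, eps=0.3, n_steps=8, seed=0)
    Z0 = np.random.default_rng(1).normal(size=(10, 3))
    p1 = br.simulate(m, Z0, "forward", seed=7)
    p2 = br.simulate(m, Z0, "forward", seed=7)
    assert np.array_equal(p1.Z, p2.Z)
    with pytest.raises(ValueError):
        br.simulate(m, np.zeros((4, 2)), "forward")
    with pytest.raises(ValueError):
        br.simulate(m, Z0, "sideways")


# ----------------------------------------------------------- drift field ----

def test_zero_initialized_drift_is_zero_and_smooth():
    net = br.DriftNet(d=3, seed=0)
    Z = np.random.default_rng(0).normal(size=(6, 3))
    assert np.all(br.drift(net, Z, 0.5) == 0.0)
    net.W2.data = np.random.default_rng(1).normal(0, 0.2,
                                                  size=net.W2.data.shape)
    q0 = net(Z, 0.5)
    assert net(Z, 0.5).shape == (6, 3)
    for delta in [1e-2, 1e-4, 1e-6]:
        dq = np.abs(net(Z + delta, 0.5) - q0).max()
        assert dq < 10 * delta  # Lipschitz smoke test


# ----------------------------------------------------------- divergence -----

@pytest.fixture()
def random_field():
    net = br.DriftNet(d=5, hidden=32, time_dim=8, seed=3)
    net.W2.data = np.random.default_rng(4).normal(0, 0.3,
                                                  size=net.W2.data.shape)
    return net


def test_divergence_linear_field_equals_trace_both_branches():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(4, 4))
    Z = rng.normal(size=(9, 4))

    def field(z):
        return z @ A.T

    exact = br.divergence(field, Z, method="exact")
    hutch = br.divergence(field, Z, method="hutchinson", exhaustive=True)
    assert np.allclose(exact, np.trace(A), atol=1e-8)
    assert np.allclose(hutch, np.trace(A), atol=1e-8)
    # identity in d=3 -> 3
    Z3 = rng.normal(size=(4, 3))
    assert np.allclose(br.divergence(lambda z: z, Z3, method="exact"), 3.0)


def test_divergence_net_exact_vs_finite_differences(random_field):
    Z = np.random.default_rng(5).normal(size=(7, 5))
    t = 0.3
    ana = br.divergence(random_field, Z, t=t, method="exact")
    fd = br.divergence(lambda z: random_field(np.asarray(z), t), Z,
                       method="exact")
    hutch = br.divergence(random_field, Z, t=t, method="hutchinson",
                          exhaustive=True)
    assert np.max(np.abs(ana - fd)) < 1e-4
    assert np.max(np.abs(hutch - fd)) < 1e-4


def test_divergence_hutchinson_random_probes_unbiased(random_field):
    Z = np.random.default_rng(6).normal(size=(3, 5))
    truth = br.divergence(random_field, Z, t=0.0, method="exact")
    ests = [br.divergence(random_field, Z, t=0.0, method="hutchinson",
                          n_probes=16, rng=np.random.default_rng(s))
            for s in range(200)]
    assert np.max(np.abs(np.mean(ests, axis=0) - truth)) < 0.05


# ----------------------------------------------------------- losses ---------

def test_loss_zero_drift_vanishes_and_direction_check():
    m = br.BridgeModel(d=2, T=1.0, eps=0.7, n_steps=10, seed=0)
    pb = br.simulate(m, np.zeros((5, 2)), "backward", seed=1)
    assert br.loss_div_forward(m, pb).item() == 0.0
    pf = br.simulate(m, np.zeros((5, 2)), "forward", seed=1)
    assert br.loss_div_backward(m, pf).item() == 0.0
    with pytest.raises(ValueError):
        br.loss_div_forward(m, pf)
    with pytest.raises(ValueError):
        br.loss_div_backward(m, pb)


def test_loss_constant_drift_hand_summation():
    c = np.array([0.4, -0.3])
    n, S = 13, 10
    m = br.BridgeModel(d=2, T=1.0, eps=0.7, n_steps=S, seed=0)
    m.fwd.b2.data = c.copy()   # Q = c, divergence 0, Q_hat = 0
    path = br.simulate(m, np.random.default_rng(2).normal(size=(n, 2)),
                       "backward", seed=2)
    expected = m.dt * S * n * 0.5 * float(c @ c)
    assert br.loss_div_forward(m, path).item() == pytest.approx(expected)


def test_loss_masking_removes_dead_cell_contribution():
    c = np.array([1.0, 2.0])
    m = br.BridgeModel(d=2, T=1.0, eps=0.7, n_steps=6, seed=0)
    m.fwd.b2.data = c.copy()
    path = br.simulate(m, np.zeros((4, 2)), "backward", seed=3)
    full = br.loss_div_forward(m, path).item()
    path.A[:, 0] = 0.0
    masked = br.loss_div_forward(m, path).item()
    per_cell = m.dt * m.n_steps * 0.5 * float(c @ c)
    assert masked == pytest.approx(full - per_cell)


def test_loss_symmetry_between_directions():
    """Swapping the trained/frozen roles and the path direction reproduces
    the same value on mirrored inputs."""
    c = np.array([0.2, 0.5])
    n = 7
    Z0 = np.random.default_rng(4).normal(size=(n, 2))
    mf = br.BridgeModel(d=2, T=1.0, eps=0.7, n_steps=8, seed=0)
    mf.fwd.b2.data = c.copy()
    pb = br.simulate(mf, Z0, "backward", seed=5)
    lf = br.loss_div_forward(mf, pb).item()
    mb = br.BridgeModel(d=2, T=1.0, eps=0.7, n_steps=8, seed=0)
    mb.bwd.b2.data = c.copy()
    pf = br.simulate(mb, Z0, "forward", seed=5)
    # mirrored path: reuse the same states so only the role swap matters
    pf.Z = pb.Z[::-1].copy()
    lb = br.loss_div_backward(mb, pf).item()
    assert lf == pytest.approx(lb)


# ----------------------------------------------------------- IPF ------------

def test_ipf_zero_rounds_leaves_model_unchanged():
    m = br.BridgeModel(d=1, T=1.0, eps=0.5, n_steps=10, seed=0)
    before = [p.data.copy() for p in m.fwd.params + m.bwd.params]
    # zero rounds == simply not calling ipf_round; the drift stays zero-init
    for p, b in zip(m.fwd.params + m.bwd.params, before):
        assert np.array_equal(p.data, b)
    assert np.all(m.fwd(np.zeros((3, 1)), 0.0) == 0.0)


def test_ipf_two_gaussian_boundary_matching(two_gaussian_bridge):
    fx = two_gaussian_bridge
    final = fx["diagnostics"][-1]["w2_terminal"]
    assert final < 0.2 * fx["w2_round0"]


def test_ipf_diagnostics_mostly_non_increasing(two_gaussian_bridge):
    ws = [d["w2_terminal"] for d in two_gaussian_bridge["diagnostics"]]
    ws = [two_gaussian_bridge["w2_round0"]] + ws
    drops = sum(b <= a for a, b in zip(ws[:-1], ws[1:]))
    assert drops / (len(ws) - 1) >= 0.7
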