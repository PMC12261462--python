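"""Kill rates, birth/death updates and the population-matching loss."""

import numpy as np
import pytest

from cellbridge import bridge as br
from cellbridge import population as pop
from cellbridge._nn import Tensor


# ----------------------------------------------------- prior kill rate ------

def _next_tp(rng, n=50, d=100):
    """Reference ensemble with known mean 0 and sd exactly 1 per feature."""
    Z = rng.normal(size=(n, d))
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    return Z


def test_prior_kill_rate_exact_fractions():
    rng = np.random.default_rng(0)
    Z_next = _next_tp(rng)
    cell_at_mean = np.zeros((1, 100))
    assert pop.prior_kill_rate(cell_at_mean, Z_next)[0] == 0.0
    # 30 of 100 features deviate by 3 sd -> rate exactly 0.30
    cell30 = np.zeros((1, 100))
    cell30[0, :30] = 3.0
    assert pop.prior_kill_rate(cell30, Z_next)[0] == pytest.approx(0.30)
    # 15 of 100 deviate -> below the 20% floor -> 0
    cell15 = np.zeros((1, 100))
    cell15[0, :15] = 3.0
    assert pop.prior_kill_rate(cell15, Z_next)[0] == 0.0
    # exactly at the floor (20/100) is kept
    cell20 = np.zeros((1, 100))
    cell20[0, :20] = 3.0
    assert pop.prior_kill_rate(cell20, Z_next)[0] == pytest.approx(0.20)


def test_prior_kill_rate_needs_two_cells():
    with pytest.raises(ValueError, match=">= 2 cells"):
        pop.prior_kill_rate(np.zeros((1, 4)), np.zeros((1, 4)))


def test_prior_from_stats_uses_next_measured_timepoint():
    stats = {0: (np.zeros(4), np.ones(4)),
             2: (np.full(4, 10.0), np.ones(4)),
             4: (np.zeros(4), np.ones(4))}
    k = pop.make_prior_from_stats(stats, [0, 2, 4])
    cell = np.zeros((1, 4))
    # between 0 and 2 the reference is timepoint 2 (mean 10): all 4 deviate
    assert k(cell, 0.7)[0] == 1.0
    # between 2 and 4 the reference is timepoint 4 (mean 0): none deviate
    assert k(cell, 2.5)[0] == 0.0


# ----------------------------------------------------- transition probs -----

def _field(scale=1.0, birth=0.0, seed=0):
    prior = lambda Z, t: np.full(np.atleast_2d(Z).shape[0], 1.0)
    net = pop.KillNet(time_dim=8, hidden=(8,), seed=seed, scale=scale)
    return pop.KillRateField(prior_k=prior, net=net, birth_rate=birth)


def test_transition_probs_zero_modulation_and_product_form():
    f0 = _field(scale=0.0, birth=2.0)
    p_die, p_born, raw_d, raw_b = pop.transition_probs(
        f0, np.zeros((5, 3)), 0.5, 0.01)
    assert np.all(p_die == 0.0) and np.all(p_born == 0.0)
    f1 = _field(scale=1.0)
    K = f1.net(0.5, None, 1)[0]
    p_die, _, raw_d, _ = pop.transition_probs(f1, np.zeros((2, 3)), 0.5, 0.01)
    assert p_die[0] == pytest.approx(1.0 * K * 0.01)


def test_transition_probs_clamped_with_raw_retained():
    f = _field(scale=1.0)
    # inflate the prior so raw probability exceeds 1
    f.prior_k = lambda Z, t: np.full(np.atleast_2d(Z).shape[0], 1000.0)
    K = f.net(0.2, None, 1)[0]
    p_die, _, raw_d, _ = pop.transition_probs(f, np.zeros((1, 2)), 0.2, 1.0)
    assert raw_d[0] == pytest.approx(1000.0 * K)
    assert p_die[0] == 1.0


def test_posterior_kill_rate_nonnegative():
    f = _field(scale=1.0)
    assert np.all(f.posterior(np.random.default_rng(0).normal(size=(6, 3)),
                              0.3) >= 0)


# ----------------------------------------------------- status updates -------

def test_update_statuses_degenerate_cases():
    rng = np.random.default_rng(0)
    A = np.ones(10)
    A2, ev, _ = pop.update_statuses(A, 0.0, 0.0, rng)
    assert np.array_equal(A2, A) and ev == []
    A3, ev3, _ = pop.update_statuses(A, 1.0, 0.0, rng)
    assert np.all(A3 == 0.0) and len(ev3) == 10
    with pytest.raises(ValueError, match="binary"):
        pop.update_statuses(np.array([0.5, 1.0]), 0.0, 0.0, rng)


def test_update_statuses_binomial_death_fraction():
    rng = np.random.default_rng(1)
    A = np.ones(10_000)
    A2, _, _ = pop.update_statuses(A, 0.5, 0.0, rng)
    dead_frac = 1.0 - A2.mean()
    se = np.sqrt(0.25 / 10_000)
    assert abs(dead_frac - 0.5) < 3 * se


def test_birth_revives_dead_slots_near_live_cells():
    rng = np.random.default_rng(2)
    A = np.array([1.0, 1.0, 0.0, 0.0])
    Z = np.array([[5.0, 5.0], [5.2, 5.1], [0.0, 0.0], [0.0, 0.0]])
    A2, ev, Z2 = pop.update_statuses(A, 0.0, 1.0, rng, Z=Z, jitter_sd=0.05)
    assert np.all(A2 == 1.0)
    assert {kind for _, kind in ev} == {"birth"}
    assert np.all(np.abs(Z2[2:] - 5.0) < 1.0)  # re-entry near the live cluster


def test_event_log_replays_to_status_matrix():
    rng = np.random.default_rng(3)
    field = _field(scale=1.0, birth=0.5)
    field.prior_k = lambda Z, t: np.full(np.atleast_2d(Z).shape[0], 5.0)
    m = br.BridgeModel(d=2, T=1.0, eps=0.3, n_steps=10, seed=0)
    path = br.simulate(m, rng.normal(size=(30, 2)), "forward",
                       killer=pop.make_killer(field), seed=4)
    replay = np.ones(30)
    A_replay = [replay.copy()]
    for k in path.nodes[1:]:
        for node, cell, kind in path.events:
            if node == k:
                replay[cell] = 1.0 if kind == "birth" else 0.0
        A_replay.append(replay.copy())
    assert np.array_equal(np.asarray(A_replay), path.A)
    assert set(np.unique(path.A)) <= {0.0, 1.0}


# ----------------------------------------------------- population loss ------

def test_empirical_mass_change_hand_values():
    tgt = pop.PopulationTarget([0, 1, 2], [100, 150, 50])
    assert pop.empirical_mass_change(tgt, 1) == pytest.approx(50 / 150)
    assert pop.empirical_mass_change(tgt, 2) == pytest.approx(-50 / 150)
    tgt_eq = pop.PopulationTarget([0, 1], [80, 80])
    assert pop.empirical_mass_change(tgt_eq, 1) == 0.0
    with pytest.raises(ValueError, match="not measured"):
        pop.empirical_mass_change(tgt, 7)


def _path(model, n=20, seed=0):
    return br.simulate(model, np.random.default_rng(seed).normal(size=(n, 2)),
                       "forward", seed=seed)


def test_population_loss_zero_for_balanced_counts_and_zero_modulation():
    m = br.BridgeModel(d=2, T=2.0, eps=0.3, n_steps=10, seed=0)
    field = _field(scale=0.0)
    tgt = pop.PopulationTarget([0, 1, 2], [20, 20, 20])
    _, val = pop.population_loss(field, _path(m), tgt, m.node_of)
    assert val == 0.0


def test_population_loss_mismatch_hand_value():
    """Predicted net change 0 but target change 0.5 -> loss exactly 0.5."""
    m = br.BridgeModel(d=2, T=1.0, eps=0.3, n_steps=10, seed=0)
    field = _field(scale=0.0, birth=1.0)
    tgt = pop.PopulationTarget([0, 1], [100, 150])   # (150-100)/150 = 1/3
    _, val = pop.population_loss(field, _path(m), tgt, m.node_of)
    assert val == pytest.approx(1 / 3)


def test_population_loss_penalty_inactive_when_probs_below_one():
    m = br.BridgeModel(d=2, T=1.0, eps=0.3, n_steps=10, seed=0)
    field = _field(scale=1.0)           # k=1, K~O(1), dt=0.1 -> raw < 1
    tgt = pop.PopulationTarget([0, 1], [30, 30])
    path = _path(m)
    loss, val = pop.population_loss(field, path, tgt, m.node_of)
    # loss equals the pure mismatch term: cumulative death mass
    dt = m.dt
    expected = 0.0
    for k in range(m.n_steps + 1):
        K = field.net(k * dt, None, 1)[0]
        expected += 1.0 * K * dt
    assert val == pytest.approx(expected, rel=1e-9)


def test_population_loss_invariant_to_cell_permutation():
    m = br.BridgeModel(d=2, T=1.0, eps=0.3, n_steps=8, seed=0)
    field = _field(scale=1.0, birth=0.3)
    field.prior_k = lambda Z, t: np.abs(np.atleast_2d(Z)[:, 0])
    tgt = pop.PopulationTarget([0, 1], [25, 20])
    path = _path(m, n=25, seed=5)
    path.A[5:, ::3] = 0.0
    _, v1 = pop.population_loss(field, path, tgt, m.node_of)
    perm = np.random.default_rng(0).permutation(25)
    path.Z = path.Z[:, perm]
    path.A = path.A[:, perm]
    _, v2 = pop.population_loss(field, path, tgt, m.node_of)
    assert v1 == pytest.approx(v2)


def test_population_loss_gradients_reach_only_omega():
    m = br.BridgeModel(d=2, T=1.0, eps=0.3, n_steps=8, seed=0)
    field = _field(scale=1.0)
    tgt = pop.PopulationTarget([0, 1], [20, 10])
    loss, _ = pop.population_loss(field, _path(m), tgt, m.node_of)
    loss.backward()
    assert any(p.grad is not None and np.any(p.grad != 0)
               for p in field.net.params)


def test_trained_kill_net_recovers_population_ratios(deathwindow_fit):
    from cellbridge import downstream as ds
    fx = deathwindow_fit
    Xhat, A, path = ds.reconstruct_trajectory(
        fx["vae"], fx["model"], fx["data"].matrix(0), seed=3,
        field=fx["field"])
    nodes = [fx["model"].node_of(float(t)) for t in fx["data"].timepoints]
    pred = ds.population_ratios(A[nodes])
    true = ds.population_ratios(fx["truth"].counts)
    assert np.max(np.abs(pred - true)) < 0.15
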