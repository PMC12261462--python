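"""Shared fixtures: synthetic datasets and trained models.

Training is expensive, so models are fitted once per session at reduced
problem sizes (a few hundred cells per timepoint, 20-40 grid steps) and
reused across unit and acceptance tests.
"""

import numpy as np
import pytest

import cellbridge as cb
from cellbridge import bridge as br
from cellbridge import downstream as ds
from cellbridge import trainer as tr
from cellbridge import vae as vmod
from cellbridge.data_io import zscore_features
from cellbridge._ot import w2_distance


@pytest.fixture(scope="session")
def two_gaussian_bridge():
    """1-d bridge between N(-2, 0.1) and N(2, 0.1), eps=0.5, 20 grid steps."""
    n = 500

    def rho0(r):
        return r.normal(-2.0, np.sqrt(0.1), size=(n, 1))

    def rhoT(r):
        return r.normal(2.0, np.sqrt(0.1), size=(n, 1))

    model = br.BridgeModel(d=1, T=1.0, eps=0.5, n_steps=20, hidden=64, seed=0)
    rng = np.random.default_rng(0)
    path0 = br.simulate(model, rho0(rng), "forward", seed=1)
    w2_round0 = w2_distance(path0.Z[-1], rhoT(rng))
    diagnostics = []
    for r in range(5):
        br.ipf_round(model, rho0, rhoT, inner_steps=100, lr=2e-3,
                     resim_every=10, rng=np.random.default_rng(100 + r),
                     diagnostics=diagnostics)
    return {"model": model, "rho0": rho0, "rhoT": rhoT,
            "w2_round0": w2_round0, "diagnostics": diagnostics}


@pytest.fixture(scope="session")
def branching_data():
    """Branching synthetic system: 5 timepoints, 300 cells each, 50 genes,
    5 planted driver genes on the advancing latent coordinate."""
    data, truth = cb.simulate_timeseries(
        d=2, g=50, T=4, counts=[300] * 5, drift_spec="branching",
        seed=11, eps=0.3, speed=1.0, n_driver=5)
    return data, truth


@pytest.fixture(scope="session")
def branching_fit(branching_data):
    """Model fitted on the branching system with the middle timepoint held out."""
    data, truth = branching_data
    train, store = cb.heldout_split(data, {2})
    cfg = cb.TrainConfig(seed=5, latent_dim=8, vae_hidden=(64, 64),
                         vae_epochs=80, n_steps=40, ipf_rounds=3,
                         inner_steps=60, resim_every=10, drift_lr=2e-3,
                         kill_steps=0, lambda_omega=0.0, eps=0.3,
                         replicates=3)
    vae, model, field, report = tr.fit(train, cfg)
    return {"data": data, "truth": truth, "train": train, "store": store,
            "vae": vae, "model": model, "field": field, "report": report,
            "cfg": cfg}


@pytest.fixture(scope="session")
def zscored_fit(branching_data):
    """Model fitted on the z-scored branching system (all timepoints), as
    used for the perturbation analysis; includes a timepoint classifier."""
    data, truth = branching_data
    dz = zscore_features(data)
    cfg = cb.TrainConfig(seed=5, latent_dim=8, vae_hidden=(64, 64),
                         vae_epochs=80, n_steps=40, ipf_rounds=2,
                         inner_steps=60, resim_every=10, drift_lr=2e-3,
                         kill_steps=0, lambda_omega=0.0, eps=0.3)
    vae, model, field, report = tr.fit(dz, cfg)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = ds.train_timepoint_classifier(vae, dz, seed=0)
    return {"data": dz, "truth": truth, "vae": vae, "model": model,
            "field": field, "clf": clf, "cfg": cfg}


@pytest.fixture(scope="session")
def deathwindow_fit():
    """Model fitted on a declining-population scenario (death window over
    t in [1, 3], counts 300 -> 150)."""
    counts = [300, 300, 200, 150, 150]
    data, truth = cb.simulate_timeseries(
        d=2, g=50, T=4, counts=counts, drift_spec="linear", speed=2.0,
        eps=0.3, death_window=(1.0, 3.0, "auto"), seed=21)
    cfg = cb.TrainConfig(seed=9, latent_dim=4, vae_hidden=(64, 64),
                         vae_epochs=80, n_steps=40, ipf_rounds=3,
                         inner_steps=60, resim_every=10, drift_lr=2e-3,
                         kill_steps=120, kill_lr=2e-2, eps=0.3)
    vae, model, field, report = tr.fit(data, cfg)
    return {"data": data, "truth": truth, "vae": vae, "model": model,
            "field": field, "report": report, "cfg": cfg}
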