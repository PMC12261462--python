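"""Model outputs and analyses: trajectory reconstruction, drift-gene ranking,
population ratios, in-silico perturbation, and live/dead differential
expression.

Drift genes are found by projecting the latent forward drift into gene space
through the decoder: for each cell, the decoded displacement of one drift
step, delta = decode(z + Q(z,t) dt, t) - decode(z, t); the per-gene score is
the mean displacement over cells, with a one-sample Wilcoxon signed-rank test
against 0 and Benjamini-Hochberg adjustment. For a linear decoder this equals
(W q) dt exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import bridge as br
from . import population as pop
from . import vae as vmod

__all__ = ["DriftGeneTable", "PerturbationResult", "reconstruct_trajectory",
           "drift_gene_scores", "population_ratios", "perturb_and_classify",
           "live_dead_de"]


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DriftGeneTable:
    timepoint: float
    table: pd.DataFrame        # gene, score, rank, p_value, p_adj

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.table.head(k)


def reconstruct_trajectory(vae: vmod.VaeModel, model: br.BridgeModel,
                           X0: np.ndarray, seed: int = 0, field=None,
                           start_node: int = 0, t_start: float = 0.0
                           ) -> tuple[np.ndarray, np.ndarray, br.TrajectorySample]:
    """Encode X0, simulate the forward SDE (with birth/death if a kill field
    is given) and decode every grid node.

    Returns (Xhat with one gene-space matrix per grid node, statuses A, the
    latent path). Same seed -> identical trajectory.
    """
    X0 = np.asarray(X0, float)
    if X0.shape[1] != vae.n_genes:
        raise ValueError(f"expected {vae.n_genes} genes, got {X0.shape[1]}")
    rng = np.random.default_rng(seed)
    enc = vmod.encode(vae, X0, t_start)
    z0 = vmod.sample_latent(enc, rng=rng)
    killer = pop.make_killer(field) if field is not None else None
    path = br.simulate(model, z0, "forward", killer=killer,
                       seed=int(rng.integers(0, 2 ** 31 - 1)),
                       start_node=start_node)
    Xhat = np.stack([vmod.decode(vae, path.Z[i], float(path.times[i]))
                     for i in range(len(path.nodes))])
    return Xhat, path.A.copy(), path


def drift_gene_scores(vae: vmod.VaeModel, model: br.BridgeModel,
                      Z_t: np.ndarray, t: float,
                      gene_names: list[str] | None = None) -> DriftGeneTable:
    """Per-gene drift scores at time t from the forward drift Q.

    Positive scores mark genes pushed upward by the deterministic trend
    (drivers); the table is sorted by score, ranks are 1-based.
    """
    Z_t = np.asarray(Z_t, float)
    q = model.fwd(Z_t, float(t))
    base = vmod.decode(vae, Z_t, float(t))
    moved = vmod.decode(vae, Z_t + q * model.dt, float(t))
    delta = moved - base                       # (n_cells, g)
    score = delta.mean(axis=0)
    g = delta.shape[1]
    pvals = np.ones(g)
    for j in range(g):
        col = delta[:, j]
        if np.allclose(col, 0):
            continue
        try:
            pvals[j] = sps.wilcoxon(col, zero_method="wilcox",
                                    alternative="two-sided").pvalue
        except ValueError:
            pvals[j] = 1.0
    padj = _bh(pvals)
    names = gene_names if gene_names is not None else \
        [f"g{j:04d}" for j in range(g)]
    df = pd.DataFrame({"gene": names, "score": score,
                       "p_value": pvals, "p_adj": padj})
    df = df.sort_values("score", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, g + 1)
    return DriftGeneTable(timepoint=float(t), table=df)


def population_ratios(counts_or_A) -> np.ndarray:
    """Consecutive population ratios n_t / n_{t-1}, normalized by their max.

    Accepts a list of counts, or a (timepoints x cells) status matrix whose
    row sums are used as counts.
    """
    arr = np.asarray(counts_or_A, dtype=float)
    counts = arr.sum(axis=1) if arr.ndim == 2 else arr
    if counts.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(counts[:-1] == 0):
        raise ValueError("zero denominator in population ratio")
    ratios = counts[1:] / counts[:-1]
    return ratios / ratios.max()


@dataclass
class PerturbationResult:
    gene: str
    level: float
    counts: pd.DataFrame       # trial, timepoint, group, n_cells
    tests: pd.DataFrame        # timepoint, t_stat, p_value

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.tests[self.tests.p_value < alpha]


def perturb_and_classify(vae: vmod.VaeModel, model: br.BridgeModel,
                         data, gene: str, level: float, t_start: int,
                         n_cells: int = 2000, n_trials: int = 10,
                         seed: int = 0, field=None,
                         classifier=None) -> PerturbationResult:
    """In-silico perturbation of one gene at t_start, scored by a classifier.

    Per trial: sample ``n_cells`` from t_start, add ``level`` to the gene
    (signed: overexpression > 0, underexpression < 0, in units of the scaled
    data), simulate both groups to T with shared noise, classify the latent
    states at every measured grid node with an MLP trained on encoder means
    of the measured data, and count assignments per timepoint. A two-sided
    t-test across trials compares perturbed vs unperturbed counts per
    timepoint; with identical groups (level 0 under shared noise) the test is
    degenerate and p is reported as 1.
    """
    if gene not in data.gene_names:
        raise ValueError(f"gene {gene!r} not on the data gene axis")
    if t_start not in data.timepoints:
        raise ValueError(f"t_start {t_start} is not a measured timepoint")
    gidx = data.gene_names.index(gene)
    rng = np.random.default_rng(seed)

    if classifier is None:
        classifier = train_timepoint_classifier(vae, data, seed=seed)

    killer = pop.make_killer(field) if field is not None else None
    start_node = model.node_of(float(t_start))
    nodes_meas = [model.node_of(float(t)) for t in data.timepoints
                  if model.node_of(float(t)) >= start_node]
    tps = list(data.timepoints)

    records = []
    X_src = data.matrix(t_start)
    for trial in range(n_trials):
        idx = rng.choice(X_src.shape[0], size=min(n_cells, X_src.shape[0]),
                         replace=X_src.shape[0] < n_cells)
        X_un = X_src[idx].copy()
        X_pe = X_un.copy()
        X_pe[:, gidx] += level
        shared_seed = int(rng.integers(0, 2 ** 31 - 1))
        noise = np.random.default_rng(shared_seed).standard_normal(
            (X_un.shape[0], vae.latent_dim))
        for group, X in (("unperturbed", X_un), ("perturbed", X_pe)):
            enc = vmod.encode(vae, X, float(t_start))
            z0 = vmod.sample_latent(enc, noise=noise)
            path = br.simulate(model, z0, "forward", killer=killer,
                               seed=shared_seed + 1, start_node=start_node)
            states, live = [], []
            for node in nodes_meas:
                Zp, Ap = path.state_at_node(node)
                states.append(Zp[Ap > 0])
            states = np.vstack(states)
            labels = classifier.predict(states)
            for ti, t in enumerate(tps):
                records.append({"trial": trial, "timepoint": t,
                                "group": group,
                                "n_cells": int((labels == t).sum())})
    counts = pd.DataFrame(records)

    tests = []
    for t in tps:
        a = counts.query("timepoint == @t and group == 'perturbed'") \
            .sort_values("trial").n_cells.to_numpy(float)
        b = counts.query("timepoint == @t and group == 'unperturbed'") \
            .sort_values("trial").n_cells.to_numpy(float)
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b)
            if not np.isfinite(p):
                p = 1.0
        tests.append({"timepoint": t, "t_stat": float(stat),
                      "p_value": float(p),
                      "mean_perturbed": float(a.mean()),
                      "mean_unperturbed": float(b.mean())})
    return PerturbationResult(gene=gene, level=float(level), counts=counts,
                              tests=pd.DataFrame(tests))


def train_timepoint_classifier(vae: vmod.VaeModel, data, seed: int = 0,
                               hidden: tuple[int, ...] = (128,)):
    """MLP classifier on encoder means of measured cells, labels=timepoints."""
    from sklearn.neural_network import MLPClassifier
    Zs, ys = [], []
    for t in data.timepoints:
        enc = vmod.encode(vae, data.matrix(t), float(t))
        Zs.append(enc.mu)
        ys.append(np.full(enc.mu.shape[0], t))
    clf = MLPClassifier(hidden_layer_sizes=hidden, max_iter=500,
                        random_state=seed)
    clf.fit(np.vstack(Zs), np.concatenate(ys))
    return clf


def live_dead_de(X: np.ndarray, statuses: np.ndarray,
                 gene_names: list[str] | None = None,
                 min_cells: int = 3) -> pd.DataFrame:
    """Rank-sum differential expression between predicted live and dead cells.

    Returns a per-gene table (lfc = mean_live - mean_dead on the provided
    scale, Mann-Whitney p, BH-adjusted p) sorted by p; group sizes are
    attached as DataFrame attrs.
    """
    X = np.asarray(X, float)
    statuses = np.asarray(statuses).astype(bool)
    live, dead = X[statuses], X[~statuses]
    if live.shape[0] < min_cells or dead.shape[0] < min_cells:
        raise ValueError(f"need >= {min_cells} cells per group, got "
                         f"{live.shape[0]} live / {dead.shape[0]} dead")
    g = X.shape[1]
    pvals = np.ones(g)
    for j in range(g):
        if np.ptp(X[:, j]) == 0:
            continue
        pvals[j] = sps.mannwhitneyu(live[:, j], dead[:, j],
                                    alternative="two-sided").pvalue
    names = gene_names if gene_names is not None else \
        [f"g{j:04d}" for j in range(g)]
    df = pd.DataFrame({"gene": names,
                       "lfc": live.mean(axis=0) - dead.mean(axis=0),
                       "p_value": pvals, "p_adj": _bh(pvals)})
    df = df.sort_values("p_value").reset_index(drop=True)
    df.attrs["n_live"] = int(live.shape[0])
    df.attrs["n_dead"] = int(dead.shape[0])
    return df
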