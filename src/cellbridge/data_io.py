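"""Reading, validation and preprocessing of time-series single-cell data.

The preprocessing pipeline mirrors the standard scRNA-seq recipe: per-cell
depth scaling to a common total, log1p, dispersion-based highly-variable-gene
selection on training cells only, an optional anchor-gene correlation filter
(e.g. removing proliferation genes correlated with TOP2A), and per-gene
z-scoring. Timepoint labels are relabeled to consecutive integers starting at
0; the original labels are kept in ``meta``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesExpression",
    "load_timeseries",
    "save_timeseries",
    "preprocess_counts",
    "select_hvgs",
    "filter_gene_correlates",
    "zscore_features",
]


@dataclass
class TimeSeriesExpression:
    """Per-timepoint cell x gene matrices sharing one gene axis.

    ``timepoints`` are integer labels; ``matrices[t]`` is the dense float
    matrix for timepoint ``t``; ``cell_ids[t]`` the matching row names.
    ``meta`` records provenance (label mapping, normalization steps, masks).
    """

    timepoints: list[int]
    matrices: dict[int, np.ndarray]
    gene_names: list[str]
    cell_ids: dict[int, list[str]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def T(self) -> int:
        return max(self.timepoints)

    def n_cells(self, t: int) -> int:
        return self.matrices[t].shape[0]

    @property
    def counts(self) -> list[int]:
        return [self.n_cells(t) for t in self.timepoints]

    def matrix(self, t: int) -> np.ndarray:
        return self.matrices[t]

    def pooled(self) -> np.ndarray:
        return np.vstack([self.matrices[t] for t in self.timepoints])

    def copy(self) -> "TimeSeriesExpression":
        return TimeSeriesExpression(
            list(self.timepoints),
            {t: m.copy() for t, m in self.matrices.items()},
            list(self.gene_names),
            {t: list(c) for t, c in self.cell_ids.items()},
            json.loads(json.dumps(self.meta)),
        )

    def subset_genes(self, mask: np.ndarray) -> "TimeSeriesExpression":
        mask = np.asarray(mask, dtype=bool)
        out = TimeSeriesExpression(
            list(self.timepoints),
            {t: m[:, mask].copy() for t, m in self.matrices.items()},
            [g for g, keep in zip(self.gene_names, mask) if keep],
            {t: list(c) for t, c in self.cell_ids.items()},
            json.loads(json.dumps(self.meta)),
        )
        return out

    def validate(self) -> None:
        if sorted(self.timepoints) != list(self.timepoints):
            raise ValueError("timepoints must be strictly increasing")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("duplicate timepoint labels")
        g = len(self.gene_names)
        for t in self.timepoints:
            m = self.matrices[t]
            if m.ndim != 2 or m.shape[1] != g:
                raise ValueError(f"timepoint {t}: matrix shape {m.shape} "
                                 f"does not match {g} genes")
            if m.shape[0] < 1:
                raise ValueError(f"timepoint {t}: no cells")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"timepoint {t}: non-finite entries")
            if len(self.cell_ids[t]) != m.shape[0]:
                raise ValueError(f"timepoint {t}: cell_ids length mismatch")


# -- timepoint label parsing -----------------------------------------------

_DUR = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(h|hr|hrs|hour|hours|d|day|days|w|wk|week|weeks)\s*$",
                  re.IGNORECASE)
_UNIT_HOURS = {"h": 1, "hr": 1, "hrs": 1, "hour": 1, "hours": 1,
               "d": 24, "day": 24, "days": 24, "w": 168, "wk": 168,
               "week": 168, "weeks": 168}


def _label_sort_key(label: str):
    """Order labels numerically, by duration (8h < 1d < 3d), else lexically."""
    s = str(label).strip()
    try:
        return (0, float(s))
    except ValueError:
        pass
    m = _DUR.match(s)
    if m:
        return (0, float(m.group(1)) * _UNIT_HOURS[m.group(2).lower()])
    return (1, s)


def _relabel(labels: list) -> tuple[dict, list[int]]:
    uniq = sorted(set(str(x) for x in labels), key=_label_sort_key)
    mapping = {lab: i for i, lab in enumerate(uniq)}
    return mapping, [mapping[str(x)] for x in labels]


def _group(X: np.ndarray, times: list, cell_ids: list[str],
           gene_names: list[str], source: str) -> TimeSeriesExpression:
    X = np.asarray(X, dtype=np.float64)
    missing = [cell_ids[i] for i, t in enumerate(times)
               if t is None or (isinstance(t, float) and np.isnan(t))
               or str(t).strip() == ""]
    if missing:
        raise ValueError(f"cells with missing time label: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    if np.any(X < 0):
        raise ValueError("negative counts in input matrix")
    mapping, ints = _relabel(times)
    ints = np.asarray(ints)
    matrices, ids = {}, {}
    for t in sorted(set(ints.tolist())):
        sel = ints == t
        matrices[t] = X[sel]
        ids[t] = [cell_ids[i] for i in np.where(sel)[0]]
    meta = {"source": source, "time_mapping": {k: int(v) for k, v in mapping.items()}}
    return TimeSeriesExpression(sorted(matrices), matrices,
                                list(gene_names), ids, meta)


def load_timeseries(path, format: str, time_key: str = "time") -> TimeSeriesExpression:
    """Load a time-series expression object from disk.

    formats:
      mtx        -- `path` is a directory with matrix.mtx (cells x genes),
                    genes.tsv (one gene per line) and barcodes.tsv
                    (barcode <tab> time label).
      delimited  -- a TSV of cells x genes with a header of gene names and a
                    `time_key` column.
      h5ad       -- AnnData container with obs[time_key].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "mtx":
        from scipy.io import mmread
        M = mmread(path / "matrix.mtx")
        X = np.asarray(M.todense()) if hasattr(M, "todense") else np.asarray(M)
        genes = [ln.split("\t")[0].strip() for ln in
                 (path / "genes.tsv").read_text().splitlines() if ln.strip()]
        rows = [ln.split("\t") for ln in
                (path / "barcodes.tsv").read_text().splitlines() if ln.strip()]
        barcodes = [r[0] for r in rows]
        if any(len(r) < 2 for r in rows):
            bad = [r[0] for r in rows if len(r) < 2]
            raise ValueError(f"cells with missing time label: {bad[:10]}")
        times = [r[1] for r in rows]
        if X.shape != (len(barcodes), len(genes)):
            raise ValueError(f"matrix shape {X.shape} inconsistent with "
                             f"{len(barcodes)} barcodes x {len(genes)} genes")
        return _group(X, times, barcodes, genes, str(path))
    if format == "delimited":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if time_key not in df.columns:
            raise ValueError(f"time column {time_key!r} not found in {path}")
        times = df[time_key].tolist()
        genes = [c for c in df.columns if c != time_key]
        return _group(df[genes].to_numpy(float), times,
                      [str(i) for i in df.index], genes, str(path))
    if format == "h5ad":
        import anndata as ad
        adata = ad.read_h5ad(path)
        if time_key not in adata.obs:
            raise ValueError(f"obs column {time_key!r} not found in {path}")
        X = adata.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        obj = _group(X, adata.obs[time_key].tolist(),
                     [str(i) for i in adata.obs_names],
                     [str(g) for g in adata.var_names], str(path))
        saved_meta = adata.uns.get("cellbridge_meta")
        if saved_meta is not None:
            obj.meta = json.loads(saved_meta) if isinstance(saved_meta, str) else dict(saved_meta)
        return obj
    raise ValueError(f"unknown format {format!r}")


def save_timeseries(data: TimeSeriesExpression, path) -> None:
    """Write as an AnnData h5ad container (obs 'time' holds integer labels)."""
    import anndata as ad
    X = data.pooled()
    times = np.concatenate([[t] * data.n_cells(t) for t in data.timepoints])
    ids = sum((data.cell_ids[t] for t in data.timepoints), [])
    obs = pd.DataFrame({"time": times.astype(int)},
                       index=pd.Index(ids, name="cell"))
    var = pd.DataFrame(index=pd.Index(data.gene_names, name="gene"))
    adata = ad.AnnData(X=X, obs=obs, var=var,
                       uns={"cellbridge_meta": json.dumps(data.meta)})
    adata.write_h5ad(Path(path))


# -- preprocessing ----------------------------------------------------------

def preprocess_counts(data: TimeSeriesExpression,
                      target_depth="median") -> TimeSeriesExpression:
    """Depth-scale each cell to a common total, then log1p.

    ``target_depth`` is a positive number or "median" (median of per-cell
    totals across all cells). Refuses to run twice (meta guard).
    """
    if data.meta.get("log1p"):
        raise ValueError("data already depth-scaled and log1p-transformed")
    out = data.copy()
    totals = np.concatenate([out.matrices[t].sum(axis=1) for t in out.timepoints])
    zero = np.where(totals == 0)[0]
    if zero.size:
        ids = sum((out.cell_ids[t] for t in out.timepoints), [])
        raise ValueError(f"cells with zero total counts cannot be depth-scaled: "
                         f"{[ids[i] for i in zero[:10]]}")
    depth = float(np.median(totals)) if target_depth == "median" else float(target_depth)
    if depth <= 0:
        raise ValueError("target_depth must be positive")
    for t in out.timepoints:
        m = out.matrices[t]
        scale = depth / m.sum(axis=1, keepdims=True)
        out.matrices[t] = np.log1p(m * scale)
    out.meta["depth_scaled_to"] = depth
    out.meta["log1p"] = True
    return out


def select_hvgs(train: TimeSeriesExpression, n_top: int = 2000) -> np.ndarray:
    """Boolean mask of the top-``n_top`` highly variable genes.

    Uses the Seurat-style mean-binned normalized dispersion on the pooled
    training cells (held-out timepoints must already be excluded by the
    caller); the mask is meant to be applied unchanged to held-out data.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    g = train.n_genes
    if n_top >= g:
        return np.ones(g, dtype=bool)
    import anndata as ad
    import scanpy as sc
    adata = ad.AnnData(X=train.pooled())
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    mask = adata.var["highly_variable"].to_numpy()
    if mask.sum() != n_top:  # ties at the threshold: break by dispersion rank
        disp = adata.var["dispersions_norm"].to_numpy()
        order = np.argsort(-np.nan_to_num(disp, nan=-np.inf))
        mask = np.zeros(g, dtype=bool)
        mask[order[:n_top]] = True
    return mask


def filter_gene_correlates(data: TimeSeriesExpression, anchor_gene: str,
                           r_threshold: float = 0.15) -> TimeSeriesExpression:
    """Remove genes whose Pearson r with ``anchor_gene`` exceeds the threshold.

    Correlation is computed on the pooled cells; the anchor itself correlates
    with itself at r=1 and is therefore removed as well.
    """
    if anchor_gene not in data.gene_names:
        raise ValueError(f"anchor gene {anchor_gene!r} not present")
    X = data.pooled()
    a = X[:, data.gene_names.index(anchor_gene)]
    if np.std(a) == 0:
        raise ValueError(f"anchor gene {anchor_gene!r} is constant; "
                         "correlation undefined")
    ac = a - a.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ ac / np.where(denom > 0, denom, 1.0), 0.0)
    keep = r <= r_threshold
    out = data.subset_genes(keep)
    out.meta["anchor_filter"] = {"anchor": anchor_gene, "r_threshold": r_threshold,
                                 "n_removed": int((~keep).sum())}
    return out


def zscore_features(data: TimeSeriesExpression,
                    stats: tuple[np.ndarray, np.ndarray] | None = None
                    ) -> TimeSeriesExpression:
    """Per-gene z-score (unbiased sd, ddof=1); constant genes map to 0.

    Pass ``stats=(mean, sd)`` computed on training data to apply the same
    affine transform to held-out cells. The stats used are stored in meta.
    """
    out = data.copy()
    if stats is None:
        X = out.pooled()
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(out.n_genes)
    else:
        mu, sd = np.asarray(stats[0], float), np.asarray(stats[1], float)
    safe = np.where(sd > 0, sd, 1.0)
    for t in out.timepoints:
        z = (out.matrices[t] - mu) / safe
        z[:, sd <= 0] = 0.0
        out.matrices[t] = z
    out.meta["zscore"] = {"sd_convention": "ddof=1",
                          "mean": mu.tolist(), "sd": sd.tolist()}
    return out
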