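"""Evaluation measures: per-gene similarity (Spearman, vector SSIM,
z-scored RMSE, Jensen-Shannon), clustering agreement (ARI/AMI/NMI/
homogeneity via Leiden on the imputed matrix), and the AS rank aggregate.

Conventions: natural logarithms throughout entropy/JS computations; NMI
uses the geometric-mean normalization and AMI the arithmetic mean; JS is
bounded in [0, ln 2].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import jensenshannon
from sklearn import metrics as skm

from .core_data import ExpressionMatrix


# ----------------------------------------------------------------------
# gene-level similarity


def spcc_gene(pred: np.ndarray, truth: np.ndarray) -> float:
    """Spearman rank correlation of a gene across cells.

    Ties get average ranks (rank-then-Pearson), which reduces to the
    classical 1 - 6*sum(d^2)/(n(n^2-1)) formula on tie-free data.
    Constant vectors have no defined rank correlation: returns NaN with a
    warning.
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and truth must be equal-length vectors, n >= 2")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    rho, _ = scipy.stats.spearmanr(pred, truth)
    return float(rho)


def ssim_gene(pred: np.ndarray, truth: np.ndarray,
              c1: float = 0.01, c2: float = 0.03) -> float:
    """Per-gene vector structural similarity on min-max scaled values.

    SSIM = (2 mu_T mu_P + C1^2)(2 cov(T,P) + C2^2) /
           ((mu_T^2 + mu_P^2 + C1^2)(var_T + var_P + C2^2))

    Both vectors are min-max scaled to [0, 1] independently before
    evaluation (a constant vector maps to zero).
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length vectors")
    if len(pred) < 2:
        raise ValueError("need at least 2 cells")
    p = _minmax(pred)
    t = _minmax(truth)
    mu_p, mu_t = p.mean(), t.mean()
    cov = np.mean((t - mu_t) * (p - mu_p))
    var_p, var_t = p.var(), t.var()
    num = (2 * mu_t * mu_p + c1 ** 2) * (2 * cov + c2 ** 2)
    den = (mu_t ** 2 + mu_p ** 2 + c1 ** 2) * (var_t + var_p + c2 ** 2)
    return float(num / den)


def _minmax(v: np.ndarray) -> np.ndarray:
    rng = np.ptp(v)
    if rng == 0:
        # constant vector: no scale to normalize; keep its level, clipped
        return np.clip(v, 0.0, 1.0)
    return (v - v.min()) / rng


def rmse_gene(pred: np.ndarray, truth: np.ndarray, zscore: bool = True) -> float:
    """Root-mean-square error between per-gene z-scored vectors.

    With a zero-variance vector z-scores are undefined: falls back to
    raw-scale RMSE with a warning.  ``zscore=False`` requests raw scale
    directly.
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length vectors")
    if zscore:
        if pred.std() == 0 or truth.std() == 0:
            warnings.warn("zero-variance vector: falling back to raw-scale RMSE")
        else:
            pred = (pred - pred.mean()) / pred.std()
            truth = (truth - truth.mean()) / truth.std()
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def js_gene(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) between the two vectors
    normalized to distributions over cells; bounded in [0, ln 2]."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length vectors")
    if np.any(pred < 0) or np.any(truth < 0):
        raise ValueError("JS requires nonnegative vectors")
    sp, st_ = pred.sum(), truth.sum()
    if sp == 0 or st_ == 0:
        raise ValueError("JS requires vectors with positive sums")
    # scipy returns the JS *distance* = sqrt(divergence)
    return float(jensenshannon(pred / sp, truth / st_, base=np.e) ** 2)


def js_histogram(a: np.ndarray, b: np.ndarray, n_bins: int = 20) -> float:
    """JS divergence between two value distributions of possibly different
    lengths, via histograms on shared bins over the pooled range.

    Used for cross-cohort comparisons (e.g. reference cells vs ST cells)
    where the per-cell-aligned form does not apply.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(jensenshannon(pa / pa.sum(), pb / pb.sum(), base=np.e) ** 2)


def evaluate_genes(
    pred: np.ndarray, truth: np.ndarray, gene_names: list[str]
) -> pd.DataFrame:
    """Tidy per-gene table of all four similarity metrics (cells × genes in)."""
    pred = np.atleast_2d(np.asarray(pred, float))
    truth = np.atleast_2d(np.asarray(truth, float))
    if pred.shape != truth.shape or pred.shape[1] != len(gene_names):
        raise ValueError("pred/truth shapes and gene_names must agree")
    rows = []
    for j, g in enumerate(gene_names):
        p, t = pred[:, j], truth[:, j]
        rows.append({
            "gene": g,
            "spcc": spcc_gene(p, t),
            "ssim": ssim_gene(p, t),
            "rmse": rmse_gene(p, t),
            "js": js_gene(np.maximum(p, 0), np.maximum(t, 0)),
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# clustering harness and agreement


def cluster_cells(
    x: ExpressionMatrix,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 15,
) -> np.ndarray:
    """PCA -> kNN graph -> Leiden community detection; deterministic given seed."""
    import scanpy as sc
    import anndata as adm

    if x.n_cells < 2:
        raise ValueError("clustering needs at least 2 cells")
    if x.n_cells <= n_neighbors:
        n_neighbors = max(2, x.n_cells - 1)
        warnings.warn(f"fewer cells than neighbors; reduced to k={n_neighbors}")
    adata = adm.AnnData(X=x.values.astype(np.float32).copy())
    n_comps = int(min(n_pcs, x.n_cells - 1, x.n_genes - 1))
    n_comps = max(n_comps, 1)
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata, resolution=resolution, random_state=seed,
            flavor="leidenalg", n_iterations=-1,
        )
    return adata.obs["leiden"].astype(int).to_numpy()


def ari(pred_labels, true_labels) -> float:
    """Adjusted Rand index via the contingency table (pair counting)."""
    pred_labels, true_labels = _check_labels(pred_labels, true_labels)
    return float(skm.adjusted_rand_score(true_labels, pred_labels))


def nmi(pred_labels, true_labels) -> float:
    """Normalized mutual information, geometric-mean normalization."""
    pred_labels, true_labels = _check_labels(pred_labels, true_labels)
    return float(skm.normalized_mutual_info_score(
        true_labels, pred_labels, average_method="geometric"))


def ami(pred_labels, true_labels) -> float:
    """Adjusted mutual information, arithmetic-mean normalization, with the
    expected MI under the permutation model."""
    pred_labels, true_labels = _check_labels(pred_labels, true_labels)
    return float(skm.adjusted_mutual_info_score(
        true_labels, pred_labels, average_method="arithmetic"))


def homo(pred_labels, true_labels) -> float:
    """Homogeneity 1 - H(T|P)/H(T); single-cluster truth returns 1 by
    convention with a warning (conditional entropy undefined)."""
    pred_labels, true_labels = _check_labels(pred_labels, true_labels)
    if len(np.unique(true_labels)) < 2:
        warnings.warn("single-cluster truth: homogeneity undefined, returning 1")
        return 1.0
    return float(skm.homogeneity_score(true_labels, pred_labels))


def _check_labels(pred_labels, true_labels):
    p = np.asarray(pred_labels)
    t = np.asarray(true_labels)
    if p.shape != t.shape:
        raise ValueError("label vectors must have equal length")
    return p, t


def clustering_agreement(
    imputed: ExpressionMatrix,
    st_truth: ExpressionMatrix,
    resolution: float = 1.0,
    seed: int = 0,
) -> dict:
    """Leiden-cluster both matrices and score the agreement of the imputed
    clustering against the truth-derived clustering."""
    truth_labels = cluster_cells(st_truth, resolution=resolution, seed=seed)
    pred_labels = cluster_cells(imputed, resolution=resolution, seed=seed)
    return {
        "ari": ari(pred_labels, truth_labels),
        "ami": ami(pred_labels, truth_labels),
        "nmi": nmi(pred_labels, truth_labels),
        "homo": homo(pred_labels, truth_labels),
    }


# ----------------------------------------------------------------------
# AS rank aggregate

LOWER_IS_BETTER = {"rmse", "js"}


def as_score(
    results: pd.DataFrame,
    orientation: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Mean rank of each method over all (dataset, metric) cells.

    `results` is tidy with columns ``method``, ``dataset``, ``metric``,
    ``value``.  Within each (dataset, metric) cell methods are ranked so
    better performance gets the higher rank (lower-is-better metrics are
    reversed; ties get average ranks).  Returns a frame indexed by method
    with the ``as_score`` column, higher is better.
    """
    required = {"method", "dataset", "metric", "value"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    orientation = orientation or {}
    ranks: dict[str, list[float]] = {m: [] for m in results["method"].unique()}
    for (_, metric), cell in results.groupby(["dataset", "metric"], sort=False):
        if cell["method"].duplicated().any():
            raise ValueError("duplicate method within a (dataset, metric) cell")
        lower_better = orientation.get(metric, metric in LOWER_IS_BETTER)
        v = cell["value"].to_numpy(float)
        r = scipy.stats.rankdata(-v if lower_better else v)  # higher rank = better
        for meth, rank in zip(cell["method"], r):
            ranks[meth].append(float(rank))
    out = pd.DataFrame({
        "method": list(ranks),
        "as_score": [float(np.mean(v)) for v in ranks.values()],
    }).set_index("method")
    return out.sort_values("as_score", ascending=False)
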