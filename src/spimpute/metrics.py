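"""Imputation evaluation panel.

Per-gene statistical metrics comparing a predicted expression vector to
ground truth across cells: Spearman correlation (SCC), a single-window
structural similarity on max-scaled vectors (SSIM), RMSE of z-scored
vectors, and the Jensen-Shannon divergence of the cell-normalized spatial
distributions.  Biological metrics: Louvain-clustering agreement with
known cell types (NMI/ARI and normalized silhouette), Moran's I
spatial-autocorrelation z-test, and a Gaussian-process likelihood-ratio
test for spatially variable (SV) genes with a squared-exponential kernel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial.distance import pdist

from .graph import NeighborGraph, build_knn

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport", "SVGeneReport",
    "scc", "ssim", "rmse_z", "js_divergence",
    "metric_report", "clustering_metrics",
    "moran_sv", "gp_sv", "sv_ratio", "sv_gene_report",
]

SSIM_C1 = 0.01
SSIM_C2 = 0.03


@dataclass
class MetricReport:
    per_gene: pd.DataFrame        # index gene; columns scc, ssim, rmse, js
    c1: float = SSIM_C1
    c2: float = SSIM_C2

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)

    def aggregate(self, how: str = "median") -> pd.Series:
        return getattr(self.per_gene, how)()


@dataclass
class SVGeneReport:
    table: pd.DataFrame           # index gene; moran_i, moran_z, moran_p, gp_llr, gp_p
    threshold: float = 0.05

    @property
    def moran_sv_ratio(self) -> float:
        return sv_ratio(self.table["moran_p"].to_numpy(), self.threshold)

    @property
    def gp_sv_ratio(self) -> float:
        return sv_ratio(self.table["gp_p"].to_numpy(), self.threshold)


# ---------------------------------------------------------------------------
# per-gene statistical metrics
# ---------------------------------------------------------------------------

def _as_float(v) -> np.ndarray:
    return np.asarray(v, dtype=np.float64).ravel()


def scc(truth, pred) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks (average
    ranks for ties).  Constant input yields 0 with a warning."""
    truth, pred = _as_float(truth), _as_float(pred)
    if len(truth) < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(truth) == 0 or np.ptp(pred) == 0:
        warnings.warn("constant vector in scc; returning 0", stacklevel=2)
        return 0.0
    rt = stats.rankdata(truth)
    rp = stats.rankdata(pred)
    rt = rt - rt.mean()
    rp = rp - rp.mean()
    return float((rt @ rp) / np.sqrt((rt @ rt) * (rp @ rp)))


def ssim(truth, pred, c1: float = SSIM_C1, c2: float = SSIM_C2) -> float:
    """Single-window SSIM on vectors scaled by their own maximum.

    Stabilizers default to the literal values C1 = 0.01, C2 = 0.03 (not
    squared); moments are population moments across cells.
    """
    truth, pred = _as_float(truth), _as_float(pred)
    if truth.max() <= 0 or pred.max() <= 0:
        raise ValueError("ssim requires a positive maximum in each vector")
    x = truth / truth.max()
    y = pred / pred.max()
    ux, uy = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - ux) * (y - uy)).mean()
    return float(((2 * ux * uy + c1) * (2 * cov + c2))
                 / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))


def rmse_z(truth, pred) -> float:
    """RMSE between the z-scored (population SD) vectors.

    Raises on zero variance — the z-score is undefined there; callers skip
    such genes with a warning.
    """
    truth, pred = _as_float(truth), _as_float(pred)
    if len(truth) < 2:
        raise ValueError("need at least 2 cells")
    st, sp_ = truth.std(), pred.std()
    if st == 0 or sp_ == 0:
        raise ValueError("zero-variance vector; z-score undefined")
    zt = (truth - truth.mean()) / st
    zp = (pred - pred.mean()) / sp_
    return float(np.sqrt(np.mean((zp - zt) ** 2)))


def js_divergence(truth, pred) -> float:
    """Jensen-Shannon divergence (natural log) of the two distributions
    obtained by normalizing each nonnegative vector to sum 1."""
    truth, pred = _as_float(truth), _as_float(pred)
    if np.any(truth < 0) or np.any(pred < 0):
        raise ValueError("js_divergence requires nonnegative vectors")
    if truth.sum() <= 0 or pred.sum() <= 0:
        raise ValueError("js_divergence requires positive totals")
    p = truth / truth.sum()
    q = pred / pred.sum()
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return 0.5 * _kl(q, m) + 0.5 * _kl(p, m)


def metric_report(truth: np.ndarray, pred: np.ndarray,
                  gene_names: Sequence[str],
                  c1: float = SSIM_C1, c2: float = SSIM_C2) -> MetricReport:
    """All four metrics per gene (columns of cells x genes matrices).

    Genes where a metric is undefined (zero variance, all-zero) get NaN
    there and a logged warning.
    """
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    rows = {}
    for j, g in enumerate(gene_names):
        t, p = truth[:, j], pred[:, j]
        row = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["scc"] = scc(t, p)
        for name, fn in (("ssim", lambda: ssim(t, p, c1, c2)),
                         ("rmse", lambda: rmse_z(t, p)),
                         ("js", lambda: js_divergence(t, p))):
            try:
                row[name] = fn()
            except ValueError:
                row[name] = np.nan
        rows[g] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    n_bad = int(table.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("%d genes had undefined metrics (skipped as NaN)", n_bad)
    return MetricReport(per_gene=table, c1=c1, c2=c2)


# ---------------------------------------------------------------------------
# clustering metrics
# ---------------------------------------------------------------------------

def clustering_metrics(expr: np.ndarray, labels: Sequence,
                       resolution: float = 1.0,
                       seed: int = 0) -> Tuple[float, float, float]:
    """Louvain-cluster the expression matrix and compare to known labels.

    Pipeline: total-count normalize, log1p, top-2000 highly variable genes
    (when more are present), 50-component PCA, 15-NN graph, Louvain
    communities (igraph multilevel).  Returns (NMI, ARI, normalized ASW),
    the silhouette computed on the PCA embedding with the *given* labels
    and mapped to [0, 1] via (ASW + 1) / 2.
    """
    import anndata as adn
    import igraph
    import scanpy as sc_api
    from sklearn import metrics as skm

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 label classes")
    adata = adn.AnnData(X=np.asarray(expr, dtype=np.float32))
    sc_api.pp.normalize_total(adata, target_sum=1e4)
    sc_api.pp.log1p(adata)
    if adata.n_vars > 2000:
        sc_api.pp.highly_variable_genes(adata, n_top_genes=2000, subset=True)
    n_comps = min(50, adata.n_vars - 1, adata.n_obs - 1)
    sc_api.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc_api.pp.neighbors(adata, n_neighbors=15, random_state=seed)
    conn = adata.obsp["connectivities"].tocoo()
    mask = conn.row < conn.col
    g = igraph.Graph(
        n=adata.n_obs,
        edges=list(zip(conn.row[mask], conn.col[mask])),
        edge_attrs={"weight": conn.data[mask].tolist()},
    )
    communities = g.community_multilevel(weights="weight",
                                         resolution=resolution)
    clusters = np.asarray(communities.membership)
    if len(np.unique(clusters)) < 2:
        warnings.warn("Louvain returned a single cluster", stacklevel=2)
    nmi = float(skm.normalized_mutual_info_score(labels, clusters))
    ari = float(skm.adjusted_rand_score(labels, clusters))
    asw_raw = float(skm.silhouette_score(adata.obsm["X_pca"], labels))
    return nmi, ari, (asw_raw + 1.0) / 2.0


# ---------------------------------------------------------------------------
# spatially variable genes
# ---------------------------------------------------------------------------

def _row_standardized_weights(graph: NeighborGraph) -> sparse.csr_matrix:
    mask = graph.edges[:, 0] != graph.edges[:, 1]
    e = graph.edges[mask]
    W = sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])),
        shape=(graph.n_nodes, graph.n_nodes)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sparse.diags(1.0 / deg) @ W


def moran_sv(expr_gene, graph: NeighborGraph,
             n_permutations: int = 0, seed: int = 0) -> Tuple[float, float, float]:
    """Moran's I with row-standardized binary k-NN weights and its
    one-sided z-test.

    Under the null, E[I] = -1/(n-1); the variance uses the standard
    normality-assumption closed form.  ``n_permutations > 0`` replaces the
    analytic p with a permutation p (the z-score is still analytic).
    Constant genes return (nan, nan, 1) with a warning.
    """
    x = _as_float(expr_gene)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 cells for Moran's I")
    if np.ptp(x) == 0:
        warnings.warn("constant gene; Moran's I undefined, p = 1",
                      stacklevel=2)
        return float("nan"), float("nan"), 1.0
    W = _row_standardized_weights(graph)
    xd = x - x.mean()
    s0 = W.sum()
    num = float(xd @ (W @ xd))
    I = (n / s0) * num / float(xd @ xd)

    EI = -1.0 / (n - 1)
    Wd = W.toarray()
    s1 = 0.5 * ((Wd + Wd.T) ** 2).sum()
    s2 = ((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2).sum()
    EI2 = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0)
    VI = EI2 - EI ** 2
    z = (I - EI) / np.sqrt(VI)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perm_I = np.empty(n_permutations)
        for b in range(n_permutations):
            xp = xd[rng.permutation(n)]
            perm_I[b] = (n / s0) * float(xp @ (W @ xp)) / float(xp @ xp)
        p = (1 + np.sum(perm_I >= I)) / (n_permutations + 1)
    else:
        p = float(stats.norm.sf(z))
    return float(I), float(z), float(p)


def _sq_exp_kernel(coords: np.ndarray, lengthscale: float) -> np.ndarray:
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return np.exp(-0.5 * d2 / lengthscale ** 2)


def default_lengthscales(coords: np.ndarray, n: int = 5) -> np.ndarray:
    d = pdist(np.asarray(coords, dtype=np.float64))
    qs = np.quantile(d[d > 0], np.linspace(0.1, 0.9, n))
    return np.unique(qs)


def gp_sv(expr_gene, coords, lengthscales: Optional[Sequence[float]] = None,
          delta_grid: Optional[Sequence[float]] = None) -> Tuple[float, float]:
    """Gaussian-process likelihood-ratio SV test, SpatialDE-style.

    Alternative: y ~ N(mu·1, sigma^2 (Sigma + delta·I)) with a squared-
    exponential Sigma; mu and sigma^2 are profiled in closed form per
    (lengthscale, delta) grid point.  Null: y ~ N(mu, sigma^2 I).  Returns
    the maximal log-likelihood ratio and its chi-square(1) upper-tail p —
    anti-conservative at the boundary, by the field's convention.
    """
    y = _as_float(expr_gene)
    coords = np.asarray(coords, dtype=np.float64)
    n = len(y)
    if n > 2000:
        raise ValueError("dense GP solve limited to 2000 cells")
    if lengthscales is None:
        lengthscales = default_lengthscales(coords)
    if delta_grid is None:
        delta_grid = np.logspace(-2, 2, 10)
    if len(lengthscales) == 0 or len(delta_grid) == 0:
        raise ValueError("grids must be nonempty")

    var0 = y.var()
    if var0 == 0:
        return 0.0, 1.0
    ll_null = -0.5 * n * (np.log(2 * np.pi * var0) + 1.0)

    ones = np.ones(n)
    best = -np.inf
    for ls in lengthscales:
        Sigma = _sq_exp_kernel(coords, ls)
        for delta in delta_grid:
            C = Sigma + delta * np.eye(n)
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                logger.info("singular kernel at ls=%.3g delta=%.3g; "
                            "jitter added", ls, delta)
                L = np.linalg.cholesky(C + 1e-6 * np.eye(n))
            alpha_1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
            mu = float(ones @ np.linalg.solve(L.T, np.linalg.solve(L, y))) \
                / float(ones @ alpha_1)
            r = y - mu
            alpha_r = np.linalg.solve(L.T, np.linalg.solve(L, r))
            sigma2 = float(r @ alpha_r) / n
            sigma2 = max(sigma2, 1e-12)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
            best = max(best, ll)
    llr = max(best - ll_null, 0.0)
    p = float(stats.chi2.sf(2.0 * llr, df=1))
    return float(llr), p


def sv_ratio(pvals, threshold: float = 0.05) -> float:
    """Fraction of genes with p below the threshold."""
    pvals = _as_float(pvals)
    if len(pvals) == 0:
        raise ValueError("empty p-value list")
    return float(np.mean(pvals < threshold))


def sv_gene_report(expr: np.ndarray, coords: np.ndarray,
                   gene_names: Sequence[str], k: int = 10,
                   threshold: float = 0.05,
                   run_gp: bool = True) -> SVGeneReport:
    """Per-gene Moran and (optionally) GP SV tests over a matrix."""
    expr = np.asarray(expr, dtype=np.float64)
    graph = build_knn(np.asarray(coords, dtype=np.float64), k=k)
    rows = {}
    for j, g in enumerate(gene_names):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            I, z, p = moran_sv(expr[:, j], graph)
        row = {"moran_i": I, "moran_z": z, "moran_p": p}
        if run_gp:
            llr, gp_p = gp_sv(expr[:, j], coords)
            row.update(gp_llr=llr, gp_p=gp_p)
        else:
            row.update(gp_llr=np.nan, gp_p=np.nan)
        rows[g] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return SVGeneReport(table=table, threshold=threshold)
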