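"""Sampling-based uncertainty scores for imputed expression.

Both scores resample counts from the fitted NB output distribution around
the predicted mean rates v̄ and measure how far samples stray from the
mean in direction: ``delta = 1 - median_j cos(v_j, v̄)``.  Gene-level
scores sample whole across-cell vectors per gene; cell-level scores sample
whole across-gene vectors per cell.  Counts are nonnegative, so delta lies
in [0, 1]; low delta marks genes (or cells) whose imputation can be
trusted, and the conventional filter keeps items strictly below the median
score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .likelihoods import sample_nb

logger = logging.getLogger(__name__)

__all__ = [
    "UncertaintyReport", "default_num_samples",
    "gene_uncertainty", "cell_uncertainty", "filter_by_median",
    "uncertainty_report",
]


@dataclass
class UncertaintyReport:
    delta_gene: np.ndarray
    delta_cell: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    L: int
    seed: int

    def to_dataframe(self):
        import pandas as pd

        gene_df = pd.DataFrame({"kind": "gene", "name": self.gene_names,
                                "delta": self.delta_gene})
        cell_df = pd.DataFrame({"kind": "cell", "name": self.cell_ids,
                                "delta": self.delta_cell})
        return pd.concat([gene_df, cell_df], ignore_index=True)


def default_num_samples(n_spatial_cells: int) -> int:
    """L = min(floor(N'/10), 100), never below 1."""
    return max(1, min(n_spatial_cells // 10, 100))


def _median_cosine(samples: np.ndarray, mean_vec: np.ndarray) -> float:
    """Median over rows of cos(sample, mean); an all-zero sample counts as
    cosine 0 (maximal uncertainty contribution)."""
    mean_norm = np.linalg.norm(mean_vec)
    if mean_norm == 0:
        return 0.0
    norms = np.linalg.norm(samples, axis=1)
    dots = samples @ mean_vec
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(norms > 0, dots / (norms * mean_norm), 0.0)
    return float(np.median(cos))


def gene_uncertainty(means: np.ndarray, thetas: np.ndarray, L: int,
                     seed: int = 0) -> np.ndarray:
    """delta_g per gene: resample each gene's across-cell NB count vector
    L times and take one minus the median cosine to the mean vector."""
    means = np.asarray(means, dtype=np.float64)
    thetas = np.asarray(thetas, dtype=np.float64)
    if L < 1:
        raise ValueError("L must be >= 1")
    n_cells, n_genes = means.shape
    rng = np.random.default_rng(seed)
    delta = np.empty(n_genes)
    for g in range(n_genes):
        col = means[:, g]
        if np.all(col == 0):
            warnings.warn(f"gene column {g} has all-zero mean; delta set to 1",
                          stacklevel=2)
            delta[g] = 1.0
            continue
        samples = sample_nb(rng, col, thetas[g], size=(L, n_cells))
        delta[g] = 1.0 - _median_cosine(samples.astype(np.float64), col)
    return delta


def cell_uncertainty(means: np.ndarray, thetas: np.ndarray, L: int,
                     seed: int = 0) -> np.ndarray:
    """delta_c per cell: resample each cell's across-gene NB count vector
    L times; symmetric to :func:`gene_uncertainty`."""
    means = np.asarray(means, dtype=np.float64)
    thetas = np.asarray(thetas, dtype=np.float64)
    if L < 1:
        raise ValueError("L must be >= 1")
    n_cells, n_genes = means.shape
    rng = np.random.default_rng(seed)
    delta = np.empty(n_cells)
    for c in range(n_cells):
        row = means[c]
        if np.all(row == 0):
            warnings.warn(f"cell row {c} has all-zero mean; delta set to 1",
                          stacklevel=2)
            delta[c] = 1.0
            continue
        samples = sample_nb(rng, row, thetas, size=(L, n_genes))
        delta[c] = 1.0 - _median_cosine(samples.astype(np.float64), row)
    return delta


def filter_by_median(scores: np.ndarray, items: Sequence) -> list:
    """Keep items whose score is strictly below the median; ties at the
    median are excluded (conservative, reproducible)."""
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) == 0:
        raise ValueError("no items to filter")
    med = np.median(scores)
    kept = [item for s, item in zip(scores, items) if s < med]
    if not kept:
        warnings.warn("all scores tie at the median; kept set is empty",
                      stacklevel=2)
    return kept


def uncertainty_report(sp, params, targets, L: Optional[int] = None,
                       n_samples: int = 25, seed: int = 0) -> UncertaintyReport:
    """Impute ``targets`` and score both axes of the predicted rate matrix.

    Dispersions: genes in the spatial training panel use the fitted spatial
    NB head theta'; other (imputed) genes fall back to the scRNA-seq
    per-gene theta.
    """
    from .impute import impute, index_genes_full

    result = impute(sp, params, targets, n_samples=n_samples, seed=seed)
    if L is None:
        L = default_num_samples(sp.n_cells)
    theta_sc = np.exp(params.weights["log_theta"].value)
    theta_sp = np.exp(params.weights["log_theta_sp"].value)
    sp_pos = {g: i for i, g in enumerate(params.sp_gene_names)}
    tidx = index_genes_full(params, result.target_genes)
    thetas = np.asarray([
        theta_sp[sp_pos[g]] if g in sp_pos else theta_sc[i]
        for g, i in zip(result.target_genes, tidx)
    ])
    delta_g = gene_uncertainty(result.imputed, thetas, L, seed=seed + 1)
    delta_c = cell_uncertainty(result.imputed, thetas, L, seed=seed + 2)
    return UncertaintyReport(
        delta_gene=delta_g, delta_cell=delta_c,
        gene_names=result.target_genes, cell_ids=result.cell_ids,
        L=L, seed=seed)
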