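"""Imputation of unmeasured genes for spatial cells from the fitted model.

For each spatial cell, latents are drawn from the fused posterior
q(z_s | x', s=1) built on the full-data neighborhood graph, decoded to the
gene simplex, and averaged; the reported value is the NB mean rate
``l' * rho_g`` (the observed cell total times the decoded frequency), not a
sampled count.  ``transfer_decode`` instead routes spatial latents through
the scRNA-seq decoder head — useful when the reference carries a perturbed
or diseased condition the spatial data lacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .data import CountDataset, index_genes
from .graph import build_knn
from .model import JointModelParams, decode, encode_sp

logger = logging.getLogger(__name__)

__all__ = ["ImputationResult", "impute", "transfer_decode", "split_genes"]


@dataclass
class ImputationResult:
    imputed: np.ndarray          # spatial cells x target genes, NB rates
    target_genes: np.ndarray
    cell_ids: np.ndarray
    n_posterior_samples: int
    mode: str = "standard"       # or "transfer"

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.imputed, index=self.cell_ids,
                            columns=self.target_genes)

    def to_anndata(self):
        import anndata as adn
        import pandas as pd

        adata = adn.AnnData(
            X=self.imputed.astype(np.float32),
            obs=pd.DataFrame(index=self.cell_ids.astype(str)),
            var=pd.DataFrame(index=self.target_genes.astype(str)),
        )
        adata.layers["imputed"] = adata.X.copy()
        return adata


def _posterior_and_library(sp: CountDataset, params: JointModelParams):
    x_panel = sp.counts[:, index_genes(sp, params.sp_gene_names)]
    lib = np.exp(sp.log_library)       # observed transcript totals
    graph = build_knn(sp.coordinates, k=params.config.k_neighbors)
    post = encode_sp(x_panel.astype(np.float64), graph, params)
    return post, lib


def _check_targets(params: JointModelParams, targets) -> np.ndarray:
    targets = np.asarray(list(targets), dtype=object)
    known = set(params.gene_names)
    unknown = [g for g in targets if g not in known]
    if unknown:
        raise ValueError(f"unknown target genes: {unknown}")
    return targets


def impute(sp: CountDataset, params: JointModelParams,
           targets: Sequence[str], n_samples: int = 25,
           seed: int = 0) -> ImputationResult:
    """Posterior-mean NB rates for ``targets`` in every spatial cell.

    ``n_samples = 0`` decodes the posterior mean of z (deterministic);
    otherwise ``n_samples`` reparameterized draws are decoded and averaged.
    """
    targets = _check_targets(params, targets)
    tidx = index_genes_full(params, targets)
    post, lib = _posterior_and_library(sp, params)
    rng = np.random.default_rng(seed)
    sd = np.sqrt(post.z_var)
    if n_samples == 0:
        rho, _ = decode(post.z_mean, 1, params)
        rho_t = rho[:, tidx]
    else:
        acc = np.zeros((sp.n_cells, len(tidx)))
        for _ in range(n_samples):
            z = post.z_mean + sd * rng.standard_normal(sd.shape)
            rho, _ = decode(z, 1, params)
            acc += rho[:, tidx]
        rho_t = acc / n_samples
    return ImputationResult(
        imputed=lib[:, None] * rho_t,
        target_genes=targets,
        cell_ids=sp.cell_ids.copy(),
        n_posterior_samples=n_samples,
        mode="standard",
    )


def transfer_decode(sp: CountDataset, params_ref: JointModelParams,
                    targets: Sequence[str]) -> ImputationResult:
    """Decode spatial latents with the scRNA-seq decoder head (s = 0).

    The rates are scaled by the reference encoder's library posterior mean
    for each spatial cell (its panel counts zero-padded into the reference
    gene space), so the output lives on the reference expression scale with
    per-cell depth — the mechanism for transferring a perturbed/diseased
    condition onto the spatial cells.
    """
    from .model import _shared_encoder

    targets = _check_targets(params_ref, targets)
    tidx = index_genes_full(params_ref, targets)
    post, _ = _posterior_and_library(sp, params_ref)
    rho, _ = decode(post.z_mean, 0, params_ref)
    x_panel = sp.counts[:, index_genes(sp, params_ref.sp_gene_names)]
    padded = np.zeros((sp.n_cells, params_ref.n_genes))
    padded[:, params_ref.sp_gene_idx] = x_panel
    _, _, l_mu, _ = _shared_encoder(padded, 0, params_ref)
    scale = np.exp(l_mu.value[:, 0])
    return ImputationResult(
        imputed=scale[:, None] * rho[:, tidx],
        target_genes=targets,
        cell_ids=sp.cell_ids.copy(),
        n_posterior_samples=0,
        mode="transfer",
    )


def index_genes_full(params: JointModelParams, genes) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(params.gene_names)}
    return np.asarray([lookup[g] for g in genes], dtype=np.int64)


def split_genes(shared_genes: Sequence[str], train_frac: float = 0.7,
                seed: int = 0) -> Tuple[list, list]:
    """Reproducible disjoint train/test split of the shared gene list.

    Train size is ``round(train_frac * n)``; the remainder is the test set.
    """
    genes = list(shared_genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    n_train = int(round(train_frac * len(genes)))
    train = [genes[i] for i in sorted(order[:n_train])]
    test = [genes[i] for i in sorted(order[n_train:])]
    return train, test
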