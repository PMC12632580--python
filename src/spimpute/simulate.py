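"""Synthetic paired scRNA-seq / spatial data from the model's own generative
assumptions, with ground truth retained.

Cells live in a shared low-dimensional latent space drawn from a Gaussian
mixture (one component per cell type).  A fixed random linear map followed
by a row softmax turns latents into per-cell gene frequency simplices.
scRNA-seq counts are ZINB with lognormal library sizes; spatial counts are
NB over a random gene panel, with spatial autocorrelation injected by
smoothing latents over a coordinate k-NN graph.  Everything is reproducible
from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
from scipy import special
from sklearn.neighbors import NearestNeighbors

from .data import CountDataset, PairedDataset, pair_datasets, SC_MODALITY, SPATIAL_MODALITY
from .likelihoods import sample_nb

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_paired"]


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the package's reference study
    conditions (a 400-gene transcriptome with a 250-gene in-situ panel at
    a few thousand cells per modality)."""

    n_sc: int = 2000
    n_sp: int = 1500
    n_genes: int = 400
    panel_size: int = 250
    latent_dim: int = 10
    n_cell_types: int = 5
    spatial_smoothness: float = 0.3     # in [0, 1]; 0 = no autocorrelation
    zinb_dropout_logit: float = -2.0    # sigmoid(-2) ~ 12% excess zeros
    dispersion_range: Tuple[float, float] = (2.0, 20.0)
    library_log_mean: float = 7.6       # e^7.6 ~ 2000 transcripts per cell
    library_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.panel_size >= self.n_genes:
            raise ValueError("panel_size must be smaller than n_genes")
        for name in ("n_sc", "n_sp", "n_genes", "panel_size",
                     "latent_dim", "n_cell_types"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise ValueError("dispersion_range must be positive and ordered")
        if not 0.0 <= self.spatial_smoothness <= 1.0:
            raise ValueError("spatial_smoothness must be in [0, 1]")
        if self.library_log_sd <= 0:
            raise ValueError("library_log_sd must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth retained by the generator.

    Rows of ``latent`` / ``rho`` / ``type_assignments`` are ordered
    scRNA-seq cells first (``n_sc`` of them after zero-cell filtering),
    then spatial cells.  ``held_out_expression`` holds the NB mean rates of
    the non-panel genes for the spatial cells — the quantity imputation is
    judged against.
    """

    latent: np.ndarray
    rho: np.ndarray
    held_out_expression: np.ndarray
    type_assignments: np.ndarray
    n_sc: int
    panel_genes: np.ndarray
    held_out_genes: np.ndarray
    theta_sc: np.ndarray
    theta_sp: np.ndarray          # over the full gene set
    sc_library: np.ndarray        # generative linear-scale library of sc cells
    spatial_library: np.ndarray   # generative linear-scale library of spatial cells


def _smooth_latents(z: np.ndarray, coords: np.ndarray, weight: float,
                    k: int = 10) -> np.ndarray:
    if weight == 0.0 or len(z) <= 1:
        return z
    k = min(k, len(z) - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(coords)
    return (1.0 - weight) * z + weight * z[idx].mean(axis=1)


def simulate_paired(config: SimulationConfig) -> Tuple[PairedDataset, SyntheticTruth]:
    """Generate a paired dataset plus its :class:`SyntheticTruth`."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_sc + cfg.n_sp
    d = cfg.latent_dim

    # latent mixture over cell types
    centers = rng.normal(0.0, 1.5, size=(cfg.n_cell_types, d))
    types = rng.integers(cfg.n_cell_types, size=n_total)
    z = centers[types] + rng.normal(0.0, 0.8, size=(n_total, d))

    # spatial layout and latent smoothing for the spatial cells
    coords = rng.uniform(0.0, 1.0, size=(cfg.n_sp, 2))
    z_sp = _smooth_latents(z[cfg.n_sc:], coords, cfg.spatial_smoothness)
    z = np.vstack([z[: cfg.n_sc], z_sp])

    # simplex-decoded gene frequencies from a fixed random linear map
    W = rng.normal(0.0, 1.0 / np.sqrt(d), size=(cfg.n_genes, d))
    b = rng.normal(0.0, 1.0, size=cfg.n_genes)
    logits = z @ W.T + b
    logits -= logits.max(axis=1, keepdims=True)
    rho = np.exp(logits)
    rho /= rho.sum(axis=1, keepdims=True)

    lo, hi = cfg.dispersion_range
    theta_sc = rng.uniform(lo, hi, size=cfg.n_genes)
    theta_sp = rng.uniform(lo, hi, size=cfg.n_genes)

    # scRNA-seq: ZINB counts with lognormal libraries
    lib_sc = rng.lognormal(cfg.library_log_mean, cfg.library_log_sd, cfg.n_sc)
    mean_sc = lib_sc[:, None] * rho[: cfg.n_sc]
    x_sc = sample_nb(rng, mean_sc, theta_sc[None, :])
    dropout_p = special.expit(cfg.zinb_dropout_logit)
    if dropout_p > 0:
        x_sc = np.where(rng.random(x_sc.shape) < dropout_p, 0, x_sc)

    # spatial: NB counts over a random panel, frequencies renormalized to it
    panel = np.sort(rng.choice(cfg.n_genes, size=cfg.panel_size, replace=False))
    held_out = np.setdiff1d(np.arange(cfg.n_genes), panel)
    rho_sp = rho[cfg.n_sc:]
    rho_panel = rho_sp[:, panel]
    rho_panel = rho_panel / rho_panel.sum(axis=1, keepdims=True)
    lib_sp = rng.lognormal(cfg.library_log_mean, cfg.library_log_sd, cfg.n_sp)
    mean_sp = lib_sp[:, None] * rho_panel
    x_sp = sample_nb(rng, mean_sp, theta_sp[panel][None, :])

    gene_names = np.asarray(
        [f"g{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    type_labels = np.asarray(
        [f"type_{t}" for t in types], dtype=object)

    keep_sc = x_sc.sum(axis=1) > 0
    keep_sp = x_sp.sum(axis=1) > 0

    sc_ds = CountDataset(
        counts=x_sc[keep_sc],
        gene_names=gene_names,
        cell_ids=np.asarray([f"sc_{i:05d}" for i in range(cfg.n_sc)],
                            dtype=object)[keep_sc],
        modality=SC_MODALITY,
        cell_types=type_labels[: cfg.n_sc][keep_sc],
    )
    sp_ds = CountDataset(
        counts=x_sp[keep_sp],
        gene_names=gene_names[panel],
        cell_ids=np.asarray([f"sp_{i:05d}" for i in range(cfg.n_sp)],
                            dtype=object)[keep_sp],
        modality=SPATIAL_MODALITY,
        coordinates=coords[keep_sp],
        cell_types=type_labels[cfg.n_sc:][keep_sp],
    )
    paired = pair_datasets(sc_ds, sp_ds)

    keep_all = np.concatenate([keep_sc, keep_sp])
    truth = SyntheticTruth(
        latent=z[keep_all],
        rho=rho[keep_all],
        held_out_expression=(lib_sp[:, None] * rho_sp[:, held_out])[keep_sp],
        type_assignments=types[keep_all],
        n_sc=int(keep_sc.sum()),
        panel_genes=gene_names[panel],
        held_out_genes=gene_names[held_out],
        theta_sc=theta_sc,
        theta_sp=theta_sp,
        sc_library=lib_sc[keep_sc],
        spatial_library=lib_sp[keep_sp],
    )
    return paired, truth


def save_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground truth to an HDF5 companion file."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("latent", "rho", "held_out_expression",
                     "type_assignments", "theta_sc", "theta_sp",
                     "sc_library", "spatial_library"):
            fh.create_dataset(name, data=getattr(truth, name))
        fh.create_dataset(
            "panel_genes",
            data=np.asarray(truth.panel_genes, dtype="S"))
        fh.create_dataset(
            "held_out_genes",
            data=np.asarray(truth.held_out_genes, dtype="S"))
        fh.attrs["n_sc"] = truth.n_sc
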