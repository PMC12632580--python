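"""The two-modality count VAE and its training loop.

Generative model
----------------
Each cell carries a latent ``z ~ N(0, I_d)`` shared between modalities.  A
decoder maps ``(z, s)`` — ``s`` the modality flag — to a probability
simplex ``rho`` over the full reference gene set G.  scRNA-seq counts are
ZINB with mean ``l * rho_g`` where the log-library ``l`` is latent with a
lognormal prior matched to the data; spatial counts are NB with mean
``l' * rho'_g`` where ``l'`` is the observed cell total and ``rho'`` is
``rho`` renormalized to the measured panel.

Inference
---------
Amortized diagonal-Gaussian posteriors.  scRNA-seq cells use a shared MLP
encoder; spatial cells add a graph-attention branch over their coordinate
k-NN neighborhood and fuse residually, ``z_s = z + z'``.  An adversarial
modality classifier with gradient reversal pulls the two latent clouds
together.  Training maximizes the two-modality ELBO by Adam on
mini-batches, with per-batch node-sampled subgraphs for the spatial side.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .anchors import AnchorReport
from .data import CountDataset, PairedDataset, index_genes
from .graph import NeighborGraph, sample_batch_graph
from .likelihoods import nb_log_likelihood_ad, zinb_log_likelihood_ad

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "JointModelParams", "LatentPosterior",
    "encode_sc", "encode_sp", "gat_layer", "decode", "renormalize_rho",
    "elbo", "adversarial_loss", "fit",
    "SpatialImputationModel", "SpatialImputationResults",
]

_EPS = 1e-8


@dataclass
class ModelConfig:
    latent_dim: int = 10
    encoder_hidden: Tuple[int, ...] = (128, 128)
    decoder_hidden: Tuple[int, ...] = (128, 128)
    gat_heads: int = 1
    gat_hidden: Tuple[int, ...] = (64,)
    gat_feature_dim: int = 32
    k_neighbors: int = 10
    likelihood_sc: str = "zinb"           # or "nb"
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 256
    kl_warmup_epochs: int = 20
    adv_weight: float = 1.0
    adv_lr_scale: float = 20.0
    grad_clip_norm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.likelihood_sc not in ("zinb", "nb"):
            raise ValueError("likelihood_sc must be 'zinb' or 'nb'")
        for name in ("latent_dim", "gat_heads", "k_neighbors", "epochs",
                     "batch_size", "kl_warmup_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.adv_weight < 0 or self.lr <= 0 or self.grad_clip_norm <= 0:
            raise ValueError("invalid lr/adv_weight/grad_clip_norm")
        self.encoder_hidden = tuple(self.encoder_hidden)
        self.decoder_hidden = tuple(self.decoder_hidden)
        self.gat_hidden = tuple(self.gat_hidden)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LatentPosterior:
    z_mean: np.ndarray
    z_var: np.ndarray
    l_mean: Optional[np.ndarray] = None
    l_var: Optional[np.ndarray] = None


class JointModelParams:
    """All learnable arrays plus the static metadata needed to use them."""

    def __init__(self, weights: dict, gene_names: np.ndarray,
                 sp_gene_names: np.ndarray, config: ModelConfig,
                 library_prior: Tuple[float, float],
                 ref_log_library_mean: float = 0.0):
        self.weights = weights                      # name -> ad.Var
        self.gene_names = np.asarray(gene_names, dtype=object)
        self.sp_gene_names = np.asarray(sp_gene_names, dtype=object)
        self.config = config
        self.library_prior = library_prior          # (mu, var) of log totals
        self.ref_log_library_mean = ref_log_library_mean
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        self.sp_gene_idx = np.asarray(
            [lookup[g] for g in self.sp_gene_names], dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def copy_values(self) -> dict:
        return {k: v.value.copy() for k, v in self.weights.items()}

    def restore_values(self, snapshot: dict) -> None:
        for k, v in snapshot.items():
            self.weights[k].value[...] = v

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "weights.npz",
                 **{k: v.value for k, v in self.weights.items()})
        meta = {
            "gene_names": list(map(str, self.gene_names)),
            "sp_gene_names": list(map(str, self.sp_gene_names)),
            "config": self.config.to_dict(),
            "library_prior": list(self.library_prior),
            "ref_log_library_mean": float(self.ref_log_library_mean),
        }
        (out_dir / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, model_dir) -> "JointModelParams":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        npz = np.load(model_dir / "weights.npz")
        weights = {k: ad.Var(npz[k]) for k in npz.files}
        return cls(
            weights=weights,
            gene_names=np.asarray(meta["gene_names"], dtype=object),
            sp_gene_names=np.asarray(meta["sp_gene_names"], dtype=object),
            config=ModelConfig(**meta["config"]),
            library_prior=tuple(meta["library_prior"]),
            ref_log_library_mean=meta["ref_log_library_mean"],
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _dense_init(rng, fan_in, fan_out, scale=None):
    scale = np.sqrt(2.0 / fan_in) if scale is None else scale
    return (ad.Var(rng.standard_normal((fan_in, fan_out)) * scale),
            ad.Var(np.zeros(fan_out)))


def init_params(config: ModelConfig, gene_names, sp_gene_names,
                library_prior) -> JointModelParams:
    rng = np.random.default_rng(config.seed)
    G = len(gene_names)
    P = len(sp_gene_names)
    d = config.latent_dim
    w: dict = {}

    def mlp(prefix, sizes):
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            w[f"{prefix}.l{i}.W"], w[f"{prefix}.l{i}.b"] = _dense_init(rng, a, b)

    enc_sizes = (G + 2,) + config.encoder_hidden
    mlp("enc", enc_sizes)
    h = enc_sizes[-1]
    for head, dim in (("z_mu", d), ("z_logvar", d), ("l_mu", 1), ("l_logvar", 1)):
        w[f"enc.{head}.W"], w[f"enc.{head}.b"] = _dense_init(
            rng, h, dim, scale=1e-2)

    fs_sizes = (P,) + config.gat_hidden + (config.gat_feature_dim,)
    mlp("fs", fs_sizes)
    for hd in range(config.gat_heads):
        w[f"gat.h{hd}.W"] = ad.Var(
            rng.standard_normal((config.gat_feature_dim, d))
            * np.sqrt(2.0 / config.gat_feature_dim))
        w[f"gat.h{hd}.a"] = ad.Var(rng.standard_normal(2 * d) * 0.1)

    dec_sizes = (d + 2,) + config.decoder_hidden
    mlp("dec", dec_sizes)
    w["dec.out.W"], w["dec.out.b"] = _dense_init(
        rng, dec_sizes[-1], G, scale=1e-2)
    mlp("drop", (d + 2,) + config.decoder_hidden[:1])
    w["drop.out.W"], w["drop.out.b"] = _dense_init(
        rng, config.decoder_hidden[0], G, scale=1e-2)

    w["log_theta"] = ad.Var(np.zeros(G))
    w["log_theta_sp"] = ad.Var(np.zeros(P))

    w["adv.l0.W"], w["adv.l0.b"] = _dense_init(rng, d, 32)
    w["adv.out.W"], w["adv.out.b"] = _dense_init(rng, 32, 2)

    return JointModelParams(w, gene_names, sp_gene_names, config, library_prior)


# ---------------------------------------------------------------------------
# forward pieces
# ---------------------------------------------------------------------------

def _mlp_forward(x, weights, prefix, n_layers):
    h = x
    for i in range(n_layers):
        h = ad.relu(h @ weights[f"{prefix}.l{i}.W"] + weights[f"{prefix}.l{i}.b"])
    return h


def _bounded_logvar(raw: ad.Var, bound: float = 4.0) -> ad.Var:
    return bound * ad.tanh(raw * (1.0 / bound))


def _one_hot_s(n: int, s: int) -> np.ndarray:
    oh = np.zeros((n, 2))
    oh[:, s] = 1.0
    return oh


def _shared_encoder(x_full: np.ndarray, s: int, params: JointModelParams):
    """Shared MLP path on log1p counts over the full gene space G."""
    cfg = params.config
    inp = ad.Var(np.concatenate(
        [np.log1p(x_full), _one_hot_s(x_full.shape[0], s)], axis=1))
    h = _mlp_forward(inp, params.weights, "enc", len(cfg.encoder_hidden))
    w = params.weights
    z_mu = h @ w["enc.z_mu.W"] + w["enc.z_mu.b"]
    z_logvar = _bounded_logvar(h @ w["enc.z_logvar.W"] + w["enc.z_logvar.b"])
    l_mu = h @ w["enc.l_mu.W"] + w["enc.l_mu.b"] + params.library_prior[0]
    l_logvar = _bounded_logvar(h @ w["enc.l_logvar.W"] + w["enc.l_logvar.b"])
    return z_mu, z_logvar, l_mu, l_logvar


def encode_sc(x_rows: np.ndarray, params: JointModelParams) -> LatentPosterior:
    """Posterior for scRNA-seq cells: q(z|x, s=0) and q(l|x, s=0)."""
    x_rows = np.atleast_2d(np.asarray(x_rows, dtype=np.float64))
    if x_rows.shape[1] != params.n_genes:
        raise ValueError(
            f"expected {params.n_genes} genes, got {x_rows.shape[1]}")
    z_mu, z_logvar, l_mu, l_logvar = _shared_encoder(x_rows, 0, params)
    return LatentPosterior(
        z_mean=z_mu.value, z_var=np.exp(z_logvar.value),
        l_mean=l_mu.value[:, 0], l_var=np.exp(l_logvar.value)[:, 0])


def gat_layer(h_init: ad.Var, graph: NeighborGraph, W: ad.Var,
              a: ad.Var) -> ad.Var:
    """Single-head graph attention over N(i) ∪ {i}.

    ``e_ij = LeakyReLU(a^T [W h_i || W h_j])``, attention is the softmax of
    e over each node's neighborhood including itself, and the output is
    ``ReLU(sum_j alpha_ij W h_j)``.
    """
    if graph.n_nodes != h_init.shape[0]:
        raise ValueError("graph node count != feature rows")
    if not graph.includes_self:
        raise ValueError("gat_layer requires self-loops in the graph")
    d = W.shape[1]
    nbr = graph.neighbor_matrix()             # (n, k+1), col 0 = self
    Hh = h_init @ W                           # (n, d)
    a1, a2 = a[:d], a[d:]
    e_i = ad.vsum(Hh * a1, axis=1, keepdims=True)        # (n, 1)
    Hj = Hh[nbr]                                          # (n, k+1, d)
    e_j = ad.vsum(Hj * a2, axis=2)                        # (n, k+1)
    e = ad.leaky_relu(e_i + e_j, slope=0.2)
    alpha = ad.softmax(e, axis=1)
    out = ad.vsum(ad.reshape(alpha, alpha.shape + (1,)) * Hj, axis=1)
    return ad.relu(out)


def _spatial_residual(x_panel: np.ndarray, graph: NeighborGraph,
                      params: JointModelParams) -> ad.Var:
    cfg = params.config
    h = _mlp_forward(ad.Var(np.log1p(x_panel)), params.weights, "fs",
                     len(cfg.gat_hidden) + 1)
    heads = [
        gat_layer(h, graph, params.weights[f"gat.h{i}.W"],
                  params.weights[f"gat.h{i}.a"])
        for i in range(cfg.gat_heads)
    ]
    out = heads[0]
    for extra in heads[1:]:
        out = out + extra
    if cfg.gat_heads > 1:
        out = out * (1.0 / cfg.gat_heads)
    return out


def _encode_sp_ad(x_panel: np.ndarray, graph: NeighborGraph,
                  params: JointModelParams):
    """Fused spatial posterior as autodiff nodes (used in training)."""
    G = params.n_genes
    padded = np.zeros((x_panel.shape[0], G))
    padded[:, params.sp_gene_idx] = x_panel
    z_mu, z_logvar, _, _ = _shared_encoder(padded, 1, params)
    z_res = _spatial_residual(x_panel, graph, params)
    return z_mu + z_res, z_logvar


def encode_sp(x_rows: np.ndarray, graph: NeighborGraph,
              params: JointModelParams) -> LatentPosterior:
    """Posterior for spatial cells: residual fusion z_s = z + z'."""
    x_rows = np.atleast_2d(np.asarray(x_rows, dtype=np.float64))
    if x_rows.shape[1] != len(params.sp_gene_names):
        raise ValueError(
            f"expected {len(params.sp_gene_names)} panel genes, "
            f"got {x_rows.shape[1]}")
    if graph.n_nodes != x_rows.shape[0]:
        raise ValueError("graph/batch size mismatch")
    mu, logvar = _encode_sp_ad(x_rows, graph, params)
    return LatentPosterior(z_mean=mu.value, z_var=np.exp(logvar.value))


def decode(z, s: int, params: JointModelParams, return_ad: bool = False):
    """Map latents to the gene-frequency simplex; for s = 0 also return
    per-gene ZINB dropout logits."""
    zv = z if isinstance(z, ad.Var) else ad.Var(np.atleast_2d(z))
    cfg = params.config
    n = zv.shape[0]
    inp = ad.concat([zv, ad.Var(_one_hot_s(n, s))], axis=1)
    h = _mlp_forward(inp, params.weights, "dec", len(cfg.decoder_hidden))
    logits = h @ params.weights["dec.out.W"] + params.weights["dec.out.b"]
    rho = ad.softmax(logits, axis=1)
    dropout = None
    if s == 0:
        hd = _mlp_forward(inp, params.weights, "drop", 1)
        dropout = hd @ params.weights["drop.out.W"] + params.weights["drop.out.b"]
    if return_ad:
        return rho, dropout
    return rho.value, None if dropout is None else dropout.value


def renormalize_rho(rho, panel_index, over_panel: bool = True):
    """Restrict a gene-frequency simplex to a panel and renormalize.

    With ``over_panel=False`` the denominator is the total mass over the
    full gene set (exactly 1 for a simplex), i.e. a plain subset.
    """
    is_var = isinstance(rho, ad.Var)
    sub = rho[:, panel_index] if is_var else np.asarray(rho)[..., panel_index]
    if not over_panel:
        return sub
    if is_var:
        denom = ad.vsum(sub, axis=-1, keepdims=True)
        if np.any(denom.value <= 0):
            raise ValueError("panel has zero total frequency mass")
        return sub / denom
    denom = sub.sum(axis=-1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("panel has zero total frequency mass")
    return sub / denom


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _kl_std_normal(mu: ad.Var, logvar: ad.Var) -> ad.Var:
    """KL(N(mu, diag e^logvar) || N(0, I)) summed over dims, per row."""
    return 0.5 * ad.vsum(
        ad.square(mu) + ad.exp(logvar) - logvar - 1.0, axis=1)


def _kl_normal(mu: ad.Var, logvar: ad.Var, mu0: float, var0: float) -> ad.Var:
    return 0.5 * ad.vsum(
        np.log(var0) - logvar
        + (ad.exp(logvar) + ad.square(mu - mu0)) * (1.0 / var0)
        - 1.0, axis=1)


def _reparam(rng, mu: ad.Var, logvar: ad.Var) -> ad.Var:
    eps = rng.standard_normal(mu.shape)
    return mu + ad.exp(0.5 * logvar) * eps


def elbo(batch_sc, batch_sp, graph: NeighborGraph,
         params: JointModelParams, kl_scale: float = 1.0,
         rng: Optional[np.random.Generator] = None):
    """Per-cell-averaged two-modality ELBO (single reparameterized sample).

    ``batch_sc`` is a dict with ``counts`` (cells x G); ``batch_sp`` a dict
    with ``counts`` (cells x panel) and ``log_library``; either may be
    ``None``.  Returns ``(total, parts)`` where ``total`` is an autodiff
    scalar and ``parts`` maps term names to floats.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    w = params.weights
    parts: dict = {}
    total = ad.Var(0.0)
    mu0, var0 = params.library_prior

    if batch_sc is not None:
        x = np.asarray(batch_sc["counts"], dtype=np.float64)
        z_mu, z_logvar, l_mu, l_logvar = _shared_encoder(x, 0, params)
        z = _reparam(rng, z_mu, z_logvar)
        l_log = _reparam(rng, l_mu, l_logvar)
        lib = ad.exp(l_log)
        rho, dropout = decode(z, 0, params, return_ad=True)
        mean = lib * rho
        theta = ad.exp(w["log_theta"])
        if params.config.likelihood_sc == "zinb":
            ll = zinb_log_likelihood_ad(x, mean, theta, dropout)
        else:
            ll = nb_log_likelihood_ad(x, mean, theta)
        recon = ad.vmean(ad.vsum(ll, axis=1))
        kl_z = ad.vmean(_kl_std_normal(z_mu, z_logvar))
        kl_l = ad.vmean(_kl_normal(l_mu, l_logvar, mu0, var0))
        term = recon - kl_scale * (kl_z + kl_l)
        total = total + term
        parts.update(recon_sc=float(recon.value), kl_z_sc=float(kl_z.value),
                     kl_l=float(kl_l.value), elbo_sc=float(term.value))
        parts["_z_sc"] = z

    if batch_sp is not None:
        xp = np.asarray(batch_sp["counts"], dtype=np.float64)
        lib_sp = np.exp(np.asarray(batch_sp["log_library"]))[:, None]
        zs_mu, zs_logvar = _encode_sp_ad(xp, graph, params)
        zs = _reparam(rng, zs_mu, zs_logvar)
        rho, _ = decode(zs, 1, params, return_ad=True)
        rho_panel = renormalize_rho(rho, params.sp_gene_idx)
        mean = lib_sp * rho_panel
        theta_sp = ad.exp(w["log_theta_sp"])
        ll = nb_log_likelihood_ad(xp, mean, theta_sp)
        recon = ad.vmean(ad.vsum(ll, axis=1))
        kl_z = ad.vmean(_kl_std_normal(zs_mu, zs_logvar))
        term = recon - kl_scale * kl_z
        total = total + term
        parts.update(recon_sp=float(recon.value), kl_z_sp=float(kl_z.value),
                     elbo_sp=float(term.value))
        parts["_z_sp"] = zs

    for name in ("elbo_sc", "elbo_sp"):
        if name in parts and not np.isfinite(parts[name]):
            raise FloatingPointError(f"non-finite ELBO term: {name}")
    return total, parts


def adversarial_loss(z_batch: ad.Var, s_labels: np.ndarray,
                     params: JointModelParams,
                     reverse_weight: float = 1.0) -> ad.Var:
    """Cross-entropy of the modality classifier on latents.

    The latents pass through a gradient-reversal op scaled by
    ``reverse_weight``, so minimizing this loss trains the classifier while
    pushing the encoders toward modality-indistinguishable latents.
    """
    s_labels = np.asarray(s_labels, dtype=np.int64)
    if len(np.unique(s_labels)) < 2:
        warnings.warn("adversarial batch contains a single modality; "
                      "no alignment signal", stacklevel=2)
    w = params.weights
    z_rev = ad.grad_reverse(z_batch, reverse_weight)
    h = ad.relu(z_rev @ w["adv.l0.W"] + w["adv.l0.b"])
    logits = h @ w["adv.out.W"] + w["adv.out.b"]
    logp = logits - ad.logsumexp(logits, axis=1, keepdims=True)
    picked = logp[(np.arange(len(s_labels)), s_labels)]
    return ad.neg(ad.vmean(picked))


def classify_modality(z: np.ndarray, params: JointModelParams) -> np.ndarray:
    """Classifier probability of modality 1 for given latents (no autodiff)."""
    w = params.weights
    h = np.maximum(z @ w["adv.l0.W"].value + w["adv.l0.b"].value, 0.0)
    logits = h @ w["adv.out.W"].value + w["adv.out.b"].value
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p[:, 1]


# ---------------------------------------------------------------------------
# optimizer + training loop
# ---------------------------------------------------------------------------

class _Adam:
    """Adam with global-norm clipping and an optional per-group learning
    rate for the adversarial classifier.

    The classifier must track the drifting encoders closely, otherwise the
    gradient-reversed encoders "win" the minimax game by relabeling rather
    than mixing the modalities (the classifier CE climbs above ln 2 and the
    latent clouds stay separable).  A faster classifier keeps its CE near
    the ln 2 equilibrium, where maximizing it approximates minimizing the
    modality divergence.
    """

    def __init__(self, weights: dict, lr: float,
                 betas=(0.9, 0.999), eps=1e-8,
                 group_lr_scale: Optional[dict] = None):
        self.weights = weights
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.value) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v.value) for k, v in weights.items()}
        group_lr_scale = group_lr_scale or {}
        self.lr_by_key = {
            k: lr * next((s for pre, s in group_lr_scale.items()
                          if k.startswith(pre)), 1.0)
            for k in weights
        }

    def step(self, clip_norm: float) -> None:
        grads = {k: w.grad for k, w in self.weights.items()
                 if w.grad is not None}
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = 1.0 if norm <= clip_norm else clip_norm / (norm + 1e-12)
        self.t += 1
        corr1 = 1.0 - self.b1 ** self.t
        corr2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = g * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.weights[k].value -= (
                self.lr_by_key[k] * (self.m[k] / corr1)
                / (np.sqrt(self.v[k] / corr2) + self.eps))


def fit(paired: PairedDataset, anchors: Optional[AnchorReport],
        config: ModelConfig) -> Tuple[JointModelParams, pd.DataFrame]:
    """Train the joint model; returns fitted params and the loss trajectory.

    The spatial head is restricted to the anchor-kept shared genes (all
    shared genes if ``anchors`` is None).  Mini-batches alternate within
    each step: one scRNA-seq chunk and one node-sampled spatial batch whose
    k-NN subgraph is recomputed among the sampled cells.
    """
    sc, sp = paired.sc, paired.sp
    if anchors is not None:
        train_genes = [g for g in anchors.kept_genes
                       if g in set(paired.shared_gene_names)]
    else:
        train_genes = list(paired.shared_gene_names)
    if not train_genes:
        raise ValueError("no training genes left after anchor filtering")

    sp_counts = sp.counts[:, index_genes(sp, train_genes)].astype(np.float64)
    sp_log_lib = sp.log_library
    sc_counts = sc.counts.astype(np.float64)

    lib_logs = sc.log_library
    library_prior = (float(lib_logs.mean()),
                     float(max(lib_logs.var(), 1e-4)))
    params = init_params(config, sc.gene_names, np.asarray(train_genes,
                                                           dtype=object),
                         library_prior)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(params.weights, config.lr,
                group_lr_scale={"adv.": config.adv_lr_scale})

    n_sc, n_sp = sc.n_cells, sp.n_cells
    bs = config.batch_size
    steps = max(int(np.ceil(n_sc / bs)), int(np.ceil(n_sp / bs)))
    history = []
    snapshot = params.copy_values()

    for epoch in range(config.epochs):
        kl_scale = min(1.0, (epoch + 1) / config.kl_warmup_epochs)
        perm = rng.permutation(n_sc)
        ep = {"elbo_sc": 0.0, "elbo_sp": 0.0, "kl": 0.0, "adv": 0.0}
        try:
            for step in range(steps):
                lo = (step * bs) % n_sc
                sc_ids = perm[lo: lo + bs]
                if len(sc_ids) < min(bs, n_sc):
                    sc_ids = np.concatenate(
                        [sc_ids, perm[: min(bs, n_sc) - len(sc_ids)]])
                sp_ids = rng.choice(n_sp, size=min(bs, n_sp), replace=False)
                graph = sample_batch_graph(sp.coordinates, sp_ids,
                                           k=config.k_neighbors)
                total, parts = elbo(
                    {"counts": sc_counts[sc_ids]},
                    {"counts": sp_counts[sp_ids],
                     "log_library": sp_log_lib[sp_ids]},
                    graph, params, kl_scale=kl_scale, rng=rng)
                loss = ad.neg(total)
                if config.adv_weight > 0:
                    z_all = ad.concat([parts["_z_sc"], parts["_z_sp"]], axis=0)
                    s_lab = np.concatenate(
                        [np.zeros(len(sc_ids), dtype=np.int64),
                         np.ones(len(sp_ids), dtype=np.int64)])
                    adv = adversarial_loss(z_all, s_lab, params,
                                           reverse_weight=config.adv_weight)
                    loss = loss + config.adv_weight * adv
                    ep["adv"] += float(adv.value)
                if not np.isfinite(loss.value):
                    raise FloatingPointError("non-finite loss")
                loss.backward()
                opt.step(config.grad_clip_norm)
                ep["elbo_sc"] += parts["elbo_sc"]
                ep["elbo_sp"] += parts["elbo_sp"]
                ep["kl"] += parts["kl_z_sc"] + parts["kl_l"] + parts["kl_z_sp"]
        except FloatingPointError as exc:
            logger.warning("training diverged at epoch %d (%s); "
                           "restoring last checkpoint", epoch, exc)
            params.restore_values(snapshot)
            break
        for k in ep:
            ep[k] /= steps
        ep["epoch"] = epoch
        ep["loss"] = -(ep["elbo_sc"] + ep["elbo_sp"])
        history.append(ep)
        snapshot = params.copy_values()
        if epoch % 10 == 0 or epoch == config.epochs - 1:
            logger.info("epoch %d  elbo_sc=%.2f  elbo_sp=%.2f  adv=%.3f",
                        epoch, ep["elbo_sc"], ep["elbo_sp"], ep["adv"])

    post = encode_sc(sc_counts, params)
    params.ref_log_library_mean = float(post.l_mean.mean())
    log = pd.DataFrame(history,
                       columns=["epoch", "loss", "elbo_sc", "elbo_sp",
                                "kl", "adv"])
    return params, log


# ---------------------------------------------------------------------------
# model / results frontend
# ---------------------------------------------------------------------------

class SpatialImputationModel:
    """Joint scRNA-seq / spatial count model, statsmodels-style.

    Parameters
    ----------
    paired
        The paired reference + spatial dataset.
    anchors
        Optional anchor-gene report restricting the spatial training genes.
    config
        Hyper-parameters; defaults follow scVI-family conventions.
    """

    def __init__(self, paired: PairedDataset,
                 anchors: Optional[AnchorReport] = None,
                 config: Optional[ModelConfig] = None):
        self.paired = paired
        self.anchors = anchors
        self.config = config or ModelConfig()

    @classmethod
    def from_datasets(cls, sc: CountDataset, sp: CountDataset,
                      anchors: Optional[AnchorReport] = None,
                      config: Optional[ModelConfig] = None):
        from .data import pair_datasets

        return cls(pair_datasets(sc, sp), anchors=anchors, config=config)

    def fit(self) -> "SpatialImputationResults":
        params, log = fit(self.paired, self.anchors, self.config)
        return SpatialImputationResults(self, params, log)


class SpatialImputationResults:
    """Fitted-model results: parameters, training history, and the
    imputation / uncertainty entry points."""

    def __init__(self, model: Optional[SpatialImputationModel],
                 params: JointModelParams, history: pd.DataFrame):
        self.model = model
        self.params = params
        self.history = history

    # -- downstream --------------------------------------------------------
    def impute(self, sp: Optional[CountDataset] = None, targets="missing",
               n_samples: int = 25, seed: int = 0):
        from .impute import impute as _impute

        sp = sp if sp is not None else self.model.paired.sp
        targets = self._resolve_targets(targets)
        return _impute(sp, self.params, targets, n_samples=n_samples,
                       seed=seed)

    def transfer_decode(self, sp: Optional[CountDataset] = None,
                        targets="missing"):
        from .impute import transfer_decode as _transfer

        sp = sp if sp is not None else self.model.paired.sp
        return _transfer(sp, self.params, self._resolve_targets(targets))

    def uncertainty(self, sp: Optional[CountDataset] = None,
                    targets="missing", L: Optional[int] = None,
                    n_samples: int = 25, seed: int = 0):
        from .uncertainty import uncertainty_report

        sp = sp if sp is not None else self.model.paired.sp
        return uncertainty_report(sp, self.params,
                                  self._resolve_targets(targets),
                                  L=L, n_samples=n_samples, seed=seed)

    def _resolve_targets(self, targets):
        if isinstance(targets, str):
            if targets == "missing":
                shared = set(self.params.sp_gene_names)
                if self.model is not None:
                    shared = set(self.model.paired.shared_gene_names)
                return np.asarray(
                    [g for g in self.params.gene_names if g not in shared],
                    dtype=object)
            if targets == "all":
                return self.params.gene_names.copy()
            raise ValueError("targets must be 'missing', 'all', or a list")
        return np.asarray(list(targets), dtype=object)

    # -- bookkeeping -------------------------------------------------------
    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        self.params.save(out_dir)
        self.history.to_csv(out_dir / "training_log.csv", index=False)
        if self.model is not None and self.model.anchors is not None:
            self.model.anchors.to_csv(out_dir / "anchors.csv")

    @classmethod
    def load(cls, model_dir,
             model: Optional[SpatialImputationModel] = None):
        model_dir = Path(model_dir)
        params = JointModelParams.load(model_dir)
        log_path = model_dir / "training_log.csv"
        history = pd.read_csv(log_path) if log_path.exists() else pd.DataFrame()
        return cls(model, params, history)

    def summary(self) -> str:
        cfg = self.params.config
        lines = [
            "Joint spatial imputation model",
            "=" * 46,
            f"reference genes (G):        {self.params.n_genes}",
            f"spatial training genes:     {len(self.params.sp_gene_names)}",
            f"latent dimension:           {cfg.latent_dim}",
            f"scRNA-seq likelihood:       {cfg.likelihood_sc.upper()}",
            f"epochs trained:             {len(self.history)}",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines += [
                f"final ELBO (scRNA-seq):     {last['elbo_sc']:.2f}",
                f"final ELBO (spatial):       {last['elbo_sp']:.2f}",
                f"final adversarial CE:       {last['adv']:.3f}",
            ]
        return "\n".join(lines)
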