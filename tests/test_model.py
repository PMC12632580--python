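"""Joint-model contracts: attention normalization against a dense oracle,
encoder determinism and sensitivity, simplex decoding, closed-form KL vs
Monte Carlo, the ELBO's lower-bound property against importance sampling,
adversarial gradient direction, and training-loop sanity."""

import numpy as np
import pytest

from spimpute import _autodiff as ad
from spimpute.graph import build_knn
from spimpute.likelihoods import nb_log_likelihood
from spimpute.model import (
    ModelConfig,
    _Adam,
    _kl_normal,
    _kl_std_normal,
    adversarial_loss,
    decode,
    encode_sc,
    encode_sp,
    fit,
    gat_layer,
    init_params,
    renormalize_rho,
)


def _tiny_params(n_genes=6, n_panel=4, seed=0, **cfg_kwargs):
    cfg = ModelConfig(latent_dim=3, encoder_hidden=(16,),
                      decoder_hidden=(16,), gat_hidden=(8,),
                      gat_feature_dim=4, seed=seed, **cfg_kwargs)
    genes = [f"g{i}" for i in range(n_genes)]
    return init_params(cfg, np.asarray(genes, dtype=object),
                       np.asarray(genes[:n_panel], dtype=object),
                       library_prior=(3.0, 0.25))


# ---------------------------------------------------------------------------
# graph attention
# ---------------------------------------------------------------------------

def _dense_attention_oracle(h, nbr, W, a, slope=0.2):
    """Literal transcription: e_ij = LeakyReLU(a^T[Wh_i || Wh_j]), softmax
    over the neighborhood including self, ReLU-aggregated output."""
    Hh = h @ W
    d = W.shape[1]
    n, kk = nbr.shape
    out = np.zeros((n, d))
    alpha_all = np.zeros((n, kk))
    for i in range(n):
        e = np.empty(kk)
        for c, j in enumerate(nbr[i]):
            pre = a[:d] @ Hh[i] + a[d:] @ Hh[j]
            e[c] = pre if pre > 0 else slope * pre
        e -= e.max()
        alpha = np.exp(e) / np.exp(e).sum()
        alpha_all[i] = alpha
        out[i] = np.maximum((alpha[:, None] * Hh[nbr[i]]).sum(0), 0.0)
    return alpha_all, out


def test_gat_matches_dense_oracle_and_rows_normalize(rng):
    coords = rng.uniform(size=(6, 2))
    graph = build_knn(coords, k=2)
    h = rng.normal(size=(6, 5))
    W = ad.Var(rng.normal(size=(5, 3)))
    a = ad.Var(rng.normal(size=6))
    out = gat_layer(ad.Var(h), graph, W, a)
    alpha_ref, out_ref = _dense_attention_oracle(
        h, graph.neighbor_matrix(), W.value, a.value)
    assert np.allclose(out.value, out_ref, atol=1e-10)
    assert np.allclose(alpha_ref.sum(axis=1), 1.0, atol=1e-6)


def test_gat_isolated_node_returns_relu_of_self():
    graph = build_knn(np.zeros((1, 2)), k=1)   # clamps to self-loop only
    h = np.array([[1.0, -2.0]])
    W = ad.Var(np.eye(2))
    a = ad.Var(np.zeros(4))
    out = gat_layer(ad.Var(h), graph, W, a)
    assert np.allclose(out.value, [[1.0, 0.0]])


def test_gat_identical_neighbors_give_uniform_attention(rng):
    coords = rng.uniform(size=(5, 2))
    graph = build_knn(coords, k=3)
    h = np.ones((5, 4))
    W = ad.Var(rng.normal(size=(4, 3)))
    a = ad.Var(rng.normal(size=6))
    alpha_ref, _ = _dense_attention_oracle(
        h, graph.neighbor_matrix(), W.value, a.value)
    assert np.allclose(alpha_ref, 0.25, atol=1e-12)
    out = gat_layer(ad.Var(h), graph, W, a)
    expected = np.maximum(h @ W.value, 0.0)
    assert np.allclose(out.value, expected, atol=1e-10)


def test_gat_requires_self_loops(rng):
    coords = rng.uniform(size=(4, 2))
    graph = build_knn(coords, k=2, include_self=False)
    with pytest.raises(ValueError, match="self-loop"):
        gat_layer(ad.Var(np.zeros((4, 4))), graph,
                  ad.Var(np.zeros((4, 3))), ad.Var(np.zeros(6)))


# ---------------------------------------------------------------------------
# encoders / decoder
# ---------------------------------------------------------------------------

def test_encode_sc_deterministic_and_positive_variance(rng):
    params = _tiny_params()
    x = rng.integers(0, 20, size=(1, 6)).astype(float)
    p1 = encode_sc(np.vstack([x, x]), params)
    assert np.allclose(p1.z_mean[0], p1.z_mean[1])
    assert np.all(p1.z_var > 0)
    assert np.all(p1.l_var > 0)


def test_encode_sc_sensitive_to_input(rng):
    params = _tiny_params()
    x = rng.integers(0, 20, size=(6,)).astype(float)
    x2 = x.copy()
    x2[0] += 15
    p = encode_sc(np.vstack([x, x2]), params)
    assert not np.allclose(p.z_mean[0], p.z_mean[1])


def test_encode_sc_rejects_wrong_gene_count():
    params = _tiny_params()
    with pytest.raises(ValueError, match="genes"):
        encode_sc(np.zeros((2, 5)), params)


def test_encode_sp_zero_gat_weights_reduce_to_shared_path(rng):
    params = _tiny_params()
    for i in range(params.config.gat_heads):
        params.weights[f"gat.h{i}.W"].value[...] = 0.0
        params.weights[f"gat.h{i}.a"].value[...] = 0.0
    coords = rng.uniform(size=(5, 2))
    graph = build_knn(coords, k=2)
    x = rng.integers(0, 10, size=(5, 4)).astype(float)
    post = encode_sp(x, graph, params)
    # shared-path mean: zero-pad the panel into G and run the sc encoder
    padded = np.zeros((5, 6))
    padded[:, params.sp_gene_idx] = x
    from spimpute.model import _shared_encoder

    z_mu, _, _, _ = _shared_encoder(padded, 1, params)
    assert np.allclose(post.z_mean, z_mu.value, atol=1e-12)


def test_encode_sp_permutation_equivariant(rng):
    params = _tiny_params()
    coords = rng.uniform(size=(8, 2))
    x = rng.integers(0, 10, size=(8, 4)).astype(float)
    graph = build_knn(coords, k=3)
    base = encode_sp(x, graph, params)
    perm = rng.permutation(8)
    graph_p = build_knn(coords[perm], k=3)
    permuted = encode_sp(x[perm], graph_p, params)
    assert np.allclose(permuted.z_mean, base.z_mean[perm], atol=1e-9)


def test_encode_sp_uses_spatial_context(rng):
    """Two cells with identical expression but different neighborhoods get
    different fused latents."""
    params = _tiny_params()
    coords = np.array([[0.0, 0], [0.1, 0], [5.0, 5], [5.1, 5]])
    x = rng.integers(1, 10, size=(4, 4)).astype(float)
    x[3] = x[0]            # same expression, far-away neighborhood
    graph = build_knn(coords, k=1)
    post = encode_sp(x, graph, params)
    assert not np.allclose(post.z_mean[0], post.z_mean[3])


def test_decode_outputs_simplex_and_conditions_on_modality(rng):
    params = _tiny_params()
    z = rng.normal(size=(7, 3))
    rho0, dropout = decode(z, 0, params)
    rho1, none = decode(z, 1, params)
    assert np.allclose(rho0.sum(axis=1), 1.0, atol=1e-6)
    assert np.allclose(rho1.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(rho0 >= 0)
    assert dropout is not None and none is None
    assert not np.allclose(rho0, rho1)


def test_renormalize_rho_identity_uniform_and_oracle(rng):
    rho = np.full((3, 10), 0.1)
    sub = renormalize_rho(rho, np.arange(10))
    assert np.allclose(sub, rho)
    quarter = renormalize_rho(rho, np.arange(4))
    assert np.allclose(quarter, 0.25)
    r = rng.dirichlet(np.ones(10), size=5)
    panel = np.array([1, 4, 7])
    got = renormalize_rho(r, panel)
    oracle = r[:, panel] / r[:, panel].sum(axis=1, keepdims=True)
    assert np.allclose(got, oracle, atol=1e-12)
    assert np.allclose(got.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def test_kl_of_prior_is_zero():
    mu = ad.Var(np.zeros((4, 3)))
    logvar = ad.Var(np.zeros((4, 3)))
    assert np.allclose(_kl_std_normal(mu, logvar).value, 0.0)


def test_kl_closed_form_matches_monte_carlo(rng):
    mu = rng.normal(size=(1, 4))
    logvar = rng.normal(scale=0.5, size=(1, 4))
    closed = float(_kl_std_normal(ad.Var(mu), ad.Var(logvar)).value[0])
    sd = np.exp(0.5 * logvar)
    zs = mu + sd * rng.standard_normal((100_000, 4))
    log_q = (-0.5 * ((zs - mu) / sd) ** 2 - 0.5 * np.log(2 * np.pi)
             - 0.5 * logvar).sum(axis=1)
    log_p = (-0.5 * zs ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
    diffs = log_q - log_p
    mc = diffs.mean()
    se = diffs.std() / np.sqrt(len(diffs))
    assert abs(closed - mc) < 3 * se


def test_kl_general_normal_matches_monte_carlo(rng):
    mu = rng.normal(size=(1, 1))
    logvar = rng.normal(scale=0.3, size=(1, 1))
    mu0, var0 = 1.5, 2.0
    closed = float(_kl_normal(ad.Var(mu), ad.Var(logvar), mu0, var0).value[0])
    sd = np.exp(0.5 * logvar)
    zs = mu + sd * rng.standard_normal((100_000, 1))
    log_q = (-0.5 * ((zs - mu) / sd) ** 2 - 0.5 * np.log(2 * np.pi)
             - 0.5 * logvar).sum(axis=1)
    log_p = (-0.5 * (zs - mu0) ** 2 / var0 - 0.5 * np.log(2 * np.pi * var0)
             ).sum(axis=1)
    diffs = log_q - log_p
    assert abs(closed - diffs.mean()) < 3 * diffs.std() / np.sqrt(len(diffs))


def _numpy_decoder_rho(params, z, s):
    """Independent numpy transcription of the decoder forward pass."""
    w = {k: v.value for k, v in params.weights.items()}
    oh = np.zeros((len(z), 2))
    oh[:, s] = 1.0
    h = np.concatenate([z, oh], axis=1)
    i = 0
    while f"dec.l{i}.W" in w:
        h = np.maximum(h @ w[f"dec.l{i}.W"] + w[f"dec.l{i}.b"], 0.0)
        i += 1
    logits = h @ w["dec.out.W"] + w["dec.out.b"]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def test_elbo_is_lower_bound_on_toy_evidence(rng):
    """One cell, three genes, NB likelihood: the analytic-KL ELBO must not
    exceed the importance-sampled log evidence."""
    params = _tiny_params(n_genes=3, n_panel=2, likelihood_sc="nb")
    mu0, var0 = params.library_prior
    theta = np.exp(params.weights["log_theta"].value)
    x = np.array([[3.0, 0.0, 5.0]])

    post = encode_sc(x, params)
    n_mc = 5000
    z = post.z_mean + np.sqrt(post.z_var) * rng.standard_normal((n_mc, 3))
    l_log = post.l_mean + np.sqrt(post.l_var) * rng.standard_normal(n_mc)
    rho = _numpy_decoder_rho(params, z, 0)
    mean = np.exp(l_log)[:, None] * rho
    ll = nb_log_likelihood(x, mean, theta).sum(axis=1)
    kl_z = float(_kl_std_normal(
        ad.Var(post.z_mean), ad.Var(np.log(post.z_var))).value[0])
    kl_l = float(_kl_normal(
        ad.Var(post.l_mean[:, None]), ad.Var(np.log(post.l_var[:, None])),
        mu0, var0).value[0])
    elbo_val = ll.mean() - kl_z - kl_l
    elbo_se = ll.std() / np.sqrt(n_mc)

    n_is = 200_000
    z_p = rng.standard_normal((n_is, 3))
    l_p = mu0 + np.sqrt(var0) * rng.standard_normal(n_is)
    rho_p = _numpy_decoder_rho(params, z_p, 0)
    ll_p = nb_log_likelihood(x, np.exp(l_p)[:, None] * rho_p, theta).sum(axis=1)
    m = ll_p.max()
    log_z = m + np.log(np.mean(np.exp(ll_p - m)))
    w_norm = np.exp(ll_p - log_z)
    log_z_se = w_norm.std() / np.sqrt(n_is)   # relative SE of the evidence
    assert elbo_val <= log_z + 3 * (log_z_se + elbo_se)


def test_adversarial_uniform_classifier_gives_log2(rng):
    params = _tiny_params()
    for k in ("adv.l0.W", "adv.l0.b", "adv.out.W", "adv.out.b"):
        params.weights[k].value[...] = 0.0
    z = ad.Var(rng.normal(size=(10, 3)))
    s = np.array([0, 1] * 5)
    loss = adversarial_loss(z, s, params, reverse_weight=1.0)
    assert np.isclose(float(loss.value), np.log(2.0), atol=1e-12)


def test_adversarial_gradient_pushes_modalities_together(rng):
    """With a classifier trained on well-separated 1-D latents, the
    reversed gradient on the latents points toward the other modality."""
    params = _tiny_params()
    z0 = np.concatenate([rng.normal(-3, 0.3, size=(30, 1)),
                         rng.normal(3, 0.3, size=(30, 1))])
    z0 = np.hstack([z0, np.zeros((60, 2))])
    s = np.array([0] * 30 + [1] * 30)
    adv_weights = {k: v for k, v in params.weights.items()
                   if k.startswith("adv.")}
    opt = _Adam(adv_weights, lr=0.05)
    for _ in range(200):
        loss = adversarial_loss(ad.Var(z0), s, params, reverse_weight=1.0)
        loss.backward()
        opt.step(clip_norm=100.0)
    zv = ad.Var(z0)
    loss = adversarial_loss(zv, s, params, reverse_weight=1.0)
    assert float(loss.value) < 0.3          # classifier separates well
    loss.backward()
    # gradient descent moves z along -grad: modality 0 should move right
    # (toward +3), modality 1 left
    assert (-zv.grad[:30, 0]).mean() > 0
    assert (-zv.grad[30:, 0]).mean() < 0


def test_single_modality_adversarial_batch_warns(rng):
    params = _tiny_params()
    with pytest.warns(UserWarning, match="single modality"):
        adversarial_loss(ad.Var(rng.normal(size=(4, 3))),
                         np.zeros(4, dtype=int), params)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _quick_fit(paired, seed, epochs=10, adv_weight=1.0):
    cfg = ModelConfig(latent_dim=5, encoder_hidden=(32,),
                      decoder_hidden=(32,), gat_hidden=(16,),
                      gat_feature_dim=8, epochs=epochs, batch_size=128,
                      kl_warmup_epochs=5, seed=seed, adv_weight=adv_weight)
    return fit(paired, None, cfg)


def test_fit_loss_decreases(small_paired):
    paired, _ = small_paired
    drops = []
    for seed in range(3):
        _, log = _quick_fit(paired, seed)
        drops.append(log["loss"].iloc[0] - log["loss"].iloc[-1])
    assert np.median(drops) > 0


def test_fit_reproducible_with_fixed_seed(small_paired):
    paired, _ = small_paired
    p1, log1 = _quick_fit(paired, 0, epochs=4)
    p2, log2 = _quick_fit(paired, 0, epochs=4)
    assert abs(log1["loss"].iloc[-1] - log2["loss"].iloc[-1]) < 1e-6
    for k in p1.weights:
        assert np.array_equal(p1.weights[k].value, p2.weights[k].value)


def test_fit_without_adversary_logs_zero_adv(small_paired):
    paired, _ = small_paired
    _, log = _quick_fit(paired, 0, epochs=2, adv_weight=0.0)
    assert np.allclose(log["adv"], 0.0)


def test_results_summary_and_roundtrip(tmp_path, trained_small):
    res = trained_small["results"]
    text = res.summary()
    assert "latent dimension" in text
    res.save(tmp_path / "model")
    from spimpute.model import SpatialImputationResults

    back = SpatialImputationResults.load(tmp_path / "model")
    for k, v in res.params.weights.items():
        assert np.array_equal(v.value, back.params.weights[k].value)
    assert back.params.config.latent_dim == res.params.config.latent_dim
    assert np.array_equal(back.params.sp_gene_names,
                          res.params.sp_gene_names)
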