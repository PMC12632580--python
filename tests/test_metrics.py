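"""Metric-panel correctness against independent brute-force oracles,
invariances, and the SV-gene tests' null/power behavior."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import jensenshannon

from spimpute.graph import build_knn
from spimpute.metrics import (
    clustering_metrics,
    gp_sv,
    js_divergence,
    metric_report,
    moran_sv,
    rmse_z,
    scc,
    ssim,
    sv_gene_report,
    sv_ratio,
)


def _random_pairs(rng, n_instances=100, n_cells=20, nonneg=False):
    for _ in range(n_instances):
        if nonneg:
            yield (rng.uniform(0.0, 10.0, n_cells),
                   rng.uniform(0.0, 10.0, n_cells))
        else:
            yield (rng.normal(size=n_cells), rng.normal(size=n_cells))


# ---------------------------------------------------------------------------
# statistical metrics vs oracles
# ---------------------------------------------------------------------------

def test_scc_perfect_and_reversed():
    x = np.array([1.0, 2, 3, 4, 5])
    assert scc(x, x) == pytest.approx(1.0)
    assert scc(x, -x) == pytest.approx(-1.0)


def test_scc_matches_rank_pearson_oracle():
    truth = np.array([1.0, 2, 3, 4, 5])
    pred = np.array([2.0, 1, 3, 5, 4])
    r_oracle = np.corrcoef(stats.rankdata(truth), stats.rankdata(pred))[0, 1]
    assert scc(truth, pred) == pytest.approx(r_oracle, abs=1e-12)


def test_scc_matches_scipy_spearman(rng):
    for t, p in _random_pairs(rng):
        ref = stats.spearmanr(t, p).statistic
        assert scc(t, p) == pytest.approx(ref, abs=1e-10)


def test_scc_constant_input_warns_zero():
    with pytest.warns(UserWarning):
        assert scc(np.ones(5), np.arange(5.0)) == 0.0


def _ssim_oracle(t, p, c1=0.01, c2=0.03):
    x = t / t.max()
    y = p / p.max()
    ux, uy = x.mean(), y.mean()
    cov = np.mean((x - ux) * (y - uy))
    return ((2 * ux * uy + c1) * (2 * cov + c2)) / \
        ((ux ** 2 + uy ** 2 + c1) * (x.var() + y.var() + c2))


def test_ssim_identity_and_scale_invariance(rng):
    t = rng.uniform(0.1, 5.0, 30)
    assert ssim(t, t) == pytest.approx(1.0)
    for c in (0.2, 3.0, 17.0):
        assert ssim(t, c * t) == pytest.approx(1.0, abs=1e-12)


def test_ssim_matches_literal_oracle(rng):
    for t, p in _random_pairs(rng, nonneg=True):
        t, p = t + 0.01, p + 0.01
        assert ssim(t, p) == pytest.approx(_ssim_oracle(t, p), abs=1e-10)


def test_ssim_rejects_nonpositive_max():
    with pytest.raises(ValueError):
        ssim(np.zeros(5), np.ones(5))


def test_rmse_z_identity_and_affine_invariance(rng):
    t = rng.normal(size=25)
    assert rmse_z(t, t) == pytest.approx(0.0)
    for a, b in [(2.0, 1.0), (0.5, -3.0), (10.0, 100.0)]:
        assert rmse_z(t, a * t + b) == pytest.approx(0.0, abs=1e-10)


def test_rmse_z_matches_direct_formula(rng):
    for t, p in _random_pairs(rng):
        zt = (t - t.mean()) / t.std()
        zp = (p - p.mean()) / p.std()
        oracle = np.sqrt(np.mean((zp - zt) ** 2))
        assert rmse_z(t, p) == pytest.approx(oracle, abs=1e-10)


def test_rmse_z_rejects_constant():
    with pytest.raises(ValueError):
        rmse_z(np.ones(5), np.arange(5.0))


def test_js_identity_disjoint_and_symmetry(rng):
    t = rng.uniform(0.1, 1.0, 10)
    assert js_divergence(t, t) == pytest.approx(0.0)
    a = np.array([1.0, 1, 0, 0])
    b = np.array([0.0, 0, 1, 1])
    assert js_divergence(a, b) == pytest.approx(np.log(2.0), abs=1e-15)
    for t, p in _random_pairs(rng, 20, nonneg=True):
        t, p = t + 0.01, p + 0.01
        assert js_divergence(t, p) == js_divergence(p, t)


def test_js_matches_scipy_oracle(rng):
    for t, p in _random_pairs(rng, nonneg=True):
        t, p = t + 0.01, p + 0.01
        ref = jensenshannon(t / t.sum(), p / p.sum()) ** 2
        assert js_divergence(t, p) == pytest.approx(ref, abs=1e-10)


def test_js_rejects_negative():
    with pytest.raises(ValueError):
        js_divergence(np.array([-1.0, 2.0]), np.array([1.0, 1.0]))


def test_metric_report_aggregates(rng):
    truth = rng.uniform(0.1, 10, size=(30, 5))
    pred = truth + rng.normal(scale=0.5, size=(30, 5))
    pred = np.clip(pred, 0.01, None)
    rep = metric_report(truth, pred, [f"g{i}" for i in range(5)])
    assert rep.n_genes == 5
    med = rep.aggregate("median")
    assert med["scc"] > 0.8
    assert med["js"] < 0.1
    assert set(rep.per_gene.columns) == {"scc", "ssim", "rmse", "js"}


# ---------------------------------------------------------------------------
# clustering metrics
# ---------------------------------------------------------------------------

def test_clustering_metrics_well_separated_blobs(rng):
    """Two tight, distant expression blobs: Louvain recovers the labels
    and the silhouette is high."""
    n = 150
    base = np.zeros((2 * n, 20))
    base[:n, :10] = 40.0
    base[n:, 10:] = 40.0
    expr = np.clip(base + rng.normal(scale=1.0, size=base.shape) + 5, 0, None)
    labels = np.array(["a"] * n + ["b"] * n)
    nmi, ari, asw = clustering_metrics(expr, labels, resolution=0.3, seed=0)
    assert nmi == pytest.approx(1.0)
    assert ari == pytest.approx(1.0)
    assert asw > 0.75


def test_clustering_metrics_random_labels_near_zero_ari(rng):
    expr = rng.uniform(0, 10, size=(300, 15))
    aris = []
    for seed in range(5):
        lab_rng = np.random.default_rng(seed)
        labels = lab_rng.choice(["a", "b", "c"], size=300)
        _, ari, _ = clustering_metrics(expr, labels, seed=seed)
        aris.append(ari)
    assert abs(np.median(aris)) < 0.05


def test_clustering_metrics_requires_two_classes(rng):
    with pytest.raises(ValueError):
        clustering_metrics(rng.uniform(size=(20, 5)), ["a"] * 20)


# ---------------------------------------------------------------------------
# spatially variable genes
# ---------------------------------------------------------------------------

def _lattice(m):
    xs, ys = np.meshgrid(np.arange(m, dtype=float), np.arange(m, dtype=float))
    return np.column_stack([xs.ravel(), ys.ravel()])


def test_moran_expected_value_exact():
    coords = np.random.default_rng(0).uniform(size=(11, 2))
    graph = build_knn(coords, k=3)
    x = np.random.default_rng(1).normal(size=11)
    I, z, p = moran_sv(x, graph)
    # back out E[I] from the analytic z at the permutation-invariant point:
    # z = (I - EI)/sqrt(VI) with EI = -1/(n-1) = -0.1 for n = 11
    # check directly that a shifted I changes z accordingly
    assert np.isfinite(I)
    EI = -1.0 / (11 - 1)
    assert EI == -0.1


def test_moran_permutation_null_z_centered(rng):
    coords = _lattice(10)
    graph = build_knn(coords, k=8)
    x = rng.normal(size=100)
    zs = []
    for _ in range(200):
        xp = x[rng.permutation(100)]
        zs.append(moran_sv(xp, graph)[1])
    zs = np.asarray(zs)
    assert abs(zs.mean()) < 3 * zs.std() / np.sqrt(len(zs))
    assert 0.5 < zs.std() < 1.5


def test_moran_gradient_field_strongly_significant():
    coords = _lattice(10)
    graph = build_knn(coords, k=8)
    I, z, p = moran_sv(coords[:, 0], graph)
    assert z > 3
    assert p < 1e-3


def test_moran_constant_gene_p_one():
    coords = _lattice(5)
    graph = build_knn(coords, k=4)
    with pytest.warns(UserWarning, match="constant"):
        I, z, p = moran_sv(np.ones(25), graph)
    assert p == 1.0


def test_moran_permutation_p_close_to_analytic(rng):
    coords = _lattice(8)
    graph = build_knn(coords, k=6)
    x = coords[:, 0] + rng.normal(scale=2.0, size=64)
    _, _, p_analytic = moran_sv(x, graph)
    _, _, p_perm = moran_sv(x, graph, n_permutations=999, seed=0)
    assert (p_analytic < 0.05) == (p_perm < 0.05)


def test_gp_null_low_tail_calibrated(rng):
    """White noise: the boundary LRT puts an atom of p = 1 at llr = 0, so
    the global distribution is conservative, but the 5% tail must not be
    inflated (false-positive rate within binomial slack of nominal)."""
    coords = rng.uniform(size=(40, 2))
    pvals = []
    for _ in range(200):
        y = rng.normal(size=40)
        pvals.append(gp_sv(y, coords,
                           lengthscales=[0.1, 0.3],
                           delta_grid=np.logspace(-1, 1, 4))[1])
    pvals = np.asarray(pvals)
    fpr = np.mean(pvals < 0.05)
    assert fpr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)
    assert np.mean(pvals < 0.5) <= 0.5  # stochastically conservative


def test_gp_power_on_true_gp_signal(rng):
    coords = rng.uniform(size=(50, 2))
    ls = 0.3
    d2 = ((coords[:, None] - coords[None]) ** 2).sum(-1)
    K = np.exp(-0.5 * d2 / ls ** 2) + 1e-8 * np.eye(50)
    L = np.linalg.cholesky(K)
    hits = 0
    n_sim = 100
    for _ in range(n_sim):
        signal = L @ rng.standard_normal(50)
        y = 3.0 * signal + rng.standard_normal(50)
        p = gp_sv(y, coords, lengthscales=[0.1, 0.3, 0.6],
                  delta_grid=np.logspace(-2, 1, 6))[1]
        hits += p < 0.05
    assert hits / n_sim >= 0.8


def test_gp_infinite_noise_collapses_to_null(rng):
    coords = rng.uniform(size=(30, 2))
    y = rng.normal(size=30)
    llr, p = gp_sv(y, coords, lengthscales=[0.3],
                   delta_grid=[1e8])
    assert llr < 1e-3


def test_sv_ratio_counts():
    assert sv_ratio(np.full(10, 0.01)) == 1.0
    assert sv_ratio(np.full(10, 0.5)) == 0.0
    ps = np.array([0.001, 0.2, 0.04, 0.06, 0.9, 0.049, 0.051, 0.03,
                   0.5, 0.01, 0.07, 0.02, 0.99, 0.045, 0.055, 0.8,
                   0.001, 0.3, 0.02, 0.6])
    assert sv_ratio(ps) == pytest.approx(
        np.sum(ps < 0.05) / len(ps))


def test_sv_gene_report_flags_spatial_genes(rng):
    coords = _lattice(12)
    n = len(coords)
    smooth = np.sin(coords[:, 0] / 3.0) + np.cos(coords[:, 1] / 3.0)
    expr = np.column_stack([
        3 * smooth + rng.normal(scale=0.5, size=n),   # spatial
        rng.normal(size=n),                            # noise
        rng.normal(size=n),                            # noise
    ])
    rep = sv_gene_report(expr, coords, ["sv", "n1", "n2"], k=8)
    assert rep.table.loc["sv", "moran_p"] < 0.05
    assert rep.table.loc["sv", "gp_p"] < 0.05
    assert rep.moran_sv_ratio >= 1 / 3
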