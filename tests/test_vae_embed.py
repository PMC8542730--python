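"""Tests of the mixed-likelihood VAE and the PCA baseline."""

import numpy as np
import pandas as pd
import pytest

from hfphenomap import prep
from hfphenomap.embed import (
    EmbeddingPipeline,
    VaeConfig,
    encode_mean,
    fit_pca,
    fit_vae,
)
from hfphenomap.prep import FeatureMatrix
from hfphenomap.vae import MixedVae, _LOG2PI, _MIN_LOGVAR, _sigmoid, _softplus


def make_matrix(values, kinds=None):
    n, p = values.shape
    kinds = kinds or ["continuous"] * p
    schema = tuple((f"v{i}", kinds[i]) for i in range(p))
    return FeatureMatrix(np.asarray(values, float), schema, {},
                         pd.RangeIndex(n))


def mixed_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    cont = rng.normal(0, 1, (n, 4))
    binv = (rng.random((n, 3)) < 0.4).astype(float)
    X = np.column_stack([cont, binv])
    return make_matrix(X, ["continuous"] * 4 + ["binary"] * 3)


def test_training_objective_decreases_and_is_deterministic():
    X = mixed_data()
    cfg = VaeConfig(latent_dim=2, hidden_widths=(16, 16), epochs=25, seed=1)
    m1 = fit_vae(X, cfg)
    m2 = fit_vae(X, cfg)
    log1 = m1.training_log
    assert log1[-1]["objective"] <= log1[0]["objective"]
    assert log1[-1]["objective"] == m2.training_log[-1]["objective"]
    emb1 = encode_mean(m1, X)
    emb2 = encode_mean(m2, X)
    np.testing.assert_array_equal(emb1.coords, emb2.coords)


def test_elbo_decomposition_identity():
    X = mixed_data(seed=2)
    cfg = VaeConfig(latent_dim=2, hidden_widths=(8, 8), epochs=10, seed=0)
    m = fit_vae(X, cfg)
    for rec in m.training_log:
        assert rec["objective"] == pytest.approx(
            rec["recon_nll"] + rec["kl_weight"] * rec["kl"], abs=1e-6
        )
        assert rec["elbo"] == pytest.approx(
            -(rec["recon_nll"] + rec["kl"]), abs=1e-6
        )


def test_latent_dim_must_be_smaller_than_feature_count():
    with pytest.raises(ValueError):
        MixedVae(["continuous"] * 3, VaeConfig(latent_dim=3))


def test_encode_mean_is_deterministic_and_rowwise():
    X = mixed_data(n=60, seed=3)
    m = fit_vae(X, VaeConfig(latent_dim=2, hidden_widths=(8, 8), epochs=5,
                             seed=0))
    emb = encode_mean(m, X)
    emb_again = encode_mean(m, X)
    np.testing.assert_array_equal(emb.coords, emb_again.coords)
    # duplicate rows map to identical coordinates
    dup = make_matrix(np.vstack([X.values[0], X.values[0]]),
                      ["continuous"] * 4 + ["binary"] * 3)
    coords = m.encode_mean(dup.values)
    np.testing.assert_array_equal(coords[0], coords[1])
    single = m.encode_mean(X.values[0])
    assert single.shape == (1, 2)


def test_permuting_rows_permutes_embedding():
    X = mixed_data(n=50, seed=4)
    m = fit_vae(X, VaeConfig(latent_dim=2, hidden_widths=(8, 8), epochs=5,
                             seed=0))
    perm = np.random.default_rng(0).permutation(50)
    coords = m.encode_mean(X.values)
    coords_perm = m.encode_mean(X.values[perm])
    np.testing.assert_allclose(coords_perm, coords[perm])


def test_schema_mismatch_rejected():
    X = mixed_data(n=30)
    m = fit_vae(X, VaeConfig(latent_dim=2, hidden_widths=(8, 8), epochs=3,
                             seed=0))
    wrong = make_matrix(np.zeros((5, 5)))
    with pytest.raises(ValueError):
        encode_mean(m, wrong)


def test_gradients_match_finite_differences():
    """Analytic backprop equals central finite differences of the batch loss
    (fixed reparameterisation noise)."""
    rng = np.random.default_rng(0)
    kinds = ["continuous"] * 3 + ["binary"] * 2
    cfg = VaeConfig(latent_dim=2, hidden_widths=(5, 4), seed=0, epochs=1)
    m = MixedVae(kinds, cfg)
    m._init_params(np.random.default_rng(1))
    X = np.column_stack(
        [rng.normal(size=(7, 3)), rng.integers(0, 2, size=(7, 2))]
    ).astype(float)
    eps = rng.standard_normal((7, 2))
    klw = 0.7
    B = len(X)

    def loss() -> float:
        h1, h2, mu, lv = m._encode(X)
        z = mu + np.exp(0.5 * lv) * eps
        _, _, out = m._decode(z)
        P = m.params
        loglam = np.maximum(P["loglam"], _MIN_LOGVAR)
        lam = np.exp(loglam)
        diff = out[:, m.cont_idx] - X[:, m.cont_idx]
        recon = 0.5 * np.sum(loglam + diff**2 / lam + _LOG2PI) / B
        t = out[:, m.bin_idx]
        xb = X[:, m.bin_idx]
        recon += np.sum(_softplus(t) - xb * t) / B
        kl = 0.5 * np.sum(mu**2 + np.exp(lv) - 1 - lv) / B
        return float(recon + klw * kl)

    # analytic gradients via one replicated training step
    P = m.params
    h1, h2, mu, lv = m._encode(X)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    g1, g2, out = m._decode(z)
    grads = {k: np.zeros_like(v) for k, v in P.items()}
    dout = np.zeros_like(out)
    loglam = np.maximum(P["loglam"], _MIN_LOGVAR)
    lam = np.exp(loglam)
    diff = out[:, m.cont_idx] - X[:, m.cont_idx]
    dout[:, m.cont_idx] = diff / lam / B
    grads["loglam"] = 0.5 * np.sum(1.0 - diff**2 / lam, axis=0) / B
    t = out[:, m.bin_idx]
    xb = X[:, m.bin_idx]
    dout[:, m.bin_idx] = (_sigmoid(t) - xb) / B
    grads["Wout"] = g2.T @ dout
    grads["cout"] = dout.sum(0)
    dg2 = dout @ P["Wout"].T
    dpre2 = dg2 * (1 - g2**2)
    grads["Wd2"] = g1.T @ dpre2
    grads["cd2"] = dpre2.sum(0)
    dg1 = dpre2 @ P["Wd2"].T
    dpre1 = dg1 * (1 - g1**2)
    grads["Wd1"] = z.T @ dpre1
    grads["cd1"] = dpre1.sum(0)
    dz = dpre1 @ P["Wd1"].T
    dmu = dz + klw * mu / B
    dlv = dz * eps * 0.5 * std + klw * 0.5 * (np.exp(lv) - 1) / B
    grads["Wmu"] = h2.T @ dmu
    grads["bmu"] = dmu.sum(0)
    grads["Wlv"] = h2.T @ dlv
    grads["blv"] = dlv.sum(0)
    dh2 = dmu @ P["Wmu"].T + dlv @ P["Wlv"].T
    dpre_e2 = dh2 * (1 - h2**2)
    grads["We2"] = h1.T @ dpre_e2
    grads["be2"] = dpre_e2.sum(0)
    dh1 = dpre_e2 @ P["We2"].T
    dpre_e1 = dh1 * (1 - h1**2)
    grads["We1"] = X.T @ dpre_e1
    grads["be1"] = dpre_e1.sum(0)

    h = 1e-6
    for k, v in P.items():
        it = np.nditer(v, flags=["multi_index"])
        num = np.zeros_like(v)
        for _ in it:
            idx = it.multi_index
            orig = v[idx]
            v[idx] = orig + h
            up = loss()
            v[idx] = orig - h
            down = loss()
            v[idx] = orig
            num[idx] = (up - down) / (2 * h)
        np.testing.assert_allclose(num, grads[k], rtol=1e-4, atol=1e-7)


def test_vae_matches_pca_on_linear_gaussian_factor_model():
    """Data from a 2-factor linear gaussian model: the VAE's held-out
    reconstruction error should come within 10% of PCA(2), which is optimal
    in this limit."""
    rng = np.random.default_rng(7)
    n, p, d = 1200, 6, 2
    W = rng.normal(0, 1, (d, p))
    z = rng.normal(0, 1, (n, d))
    X = z @ W + rng.normal(0, 0.3, (n, p))
    X = (X - X.mean(0)) / X.std(0)
    train, test = X[:800], X[800:]
    Xtr = make_matrix(train)
    Xte = make_matrix(test)
    m = fit_vae(Xtr, VaeConfig(latent_dim=2, hidden_widths=(32, 32),
                               epochs=400, learning_rate=2e-3, seed=0))
    vae_err = m.reconstruction_mse(Xte.values)

    from sklearn.decomposition import PCA

    pca = PCA(n_components=2).fit(train)
    rec = pca.inverse_transform(pca.transform(test))
    pca_err = float(np.mean((test - rec) ** 2))
    assert vae_err <= 1.1 * pca_err


def test_pca_embedding_matches_hand_eigendecomposition():
    pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
    X = make_matrix(pts)
    emb = fit_pca(X, 1)
    expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(2.0)
    np.testing.assert_allclose(emb.coords[:, 0], expected, atol=1e-12)


def test_pca_preserves_variance_at_full_rank_and_zero_error_on_line():
    rng = np.random.default_rng(1)
    vals = rng.normal(0, 1, (40, 3))
    X = make_matrix(vals)
    emb = fit_pca(X, 3)
    assert np.var(emb.coords, axis=0).sum() == pytest.approx(
        np.var(vals - vals.mean(0), axis=0).sum()
    )
    t = rng.normal(0, 1, 30)
    line = np.column_stack([t, 2 * t])
    emb1 = fit_pca(make_matrix(line), 1)
    # 1 component captures all variance exactly
    assert np.var(emb1.coords[:, 0]) == pytest.approx(np.var(t) * 5)
    with pytest.raises(ValueError):
        fit_pca(make_matrix(line), 3)


def test_pipeline_clone_and_transform_round_trip():
    X = mixed_data(n=80, seed=9)
    pipe = EmbeddingPipeline("vae", 2,
                             VaeConfig(epochs=5, hidden_widths=(8, 8)))
    emb = pipe.fit(X, seed=4)
    np.testing.assert_array_equal(pipe.transform(X), emb.coords)
    clone = pipe.clone(d=3)
    assert clone.d == 3 and clone.config.latent_dim == 3
    with pytest.raises(RuntimeError):
        clone.transform(X)
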