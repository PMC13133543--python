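"""NIPALS PLS1: fitting, prediction, VIP, leverage and component selection."""

import numpy as np
import pytest

from miaqsar import pls_engine as pe


def make_problem(rng, n=10, p=6, noise=0.1):
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = X @ w + noise * rng.normal(size=n)
    return X, y


def test_single_informative_column_equals_ols(rng):
    x = rng.normal(size=12)
    y = 2.5 * x - 1.0
    X = np.column_stack([x, np.zeros(12), np.zeros(12)])
    model = pe.fit(X, y, 1)
    slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
    assert model.b[0] == pytest.approx(slope)
    assert np.allclose(model.fitted, y)


def test_response_shift_invariance(rng):
    X, y = make_problem(rng)
    m1 = pe.fit(X, y, 3)
    m2 = pe.fit(X, y + 7.0, 3)
    assert np.allclose(m1.b, m2.b)
    assert np.allclose(pe.predict(m2, X), pe.predict(m1, X) + 7.0)


def test_noiseless_low_rank_signal_fits_exactly(rng):
    # X of rank 2, y in its row space: 2 components suffice
    basis = rng.normal(size=(2, 8))
    scores = rng.normal(size=(15, 2))
    X = scores @ basis
    y = X @ rng.normal(size=8)
    model = pe.fit(X, y, 2)
    assert np.abs(model.fitted - y).max() < 1e-8


def test_prediction_is_affine(rng):
    X, y = make_problem(rng)
    model = pe.fit(X, y, 2)
    x1, x2 = rng.normal(size=(2, X.shape[1]))
    alpha = 0.3
    mix = pe.predict(model, (alpha * x1 + (1 - alpha) * x2)[None, :])[0]
    parts = pe.predict(model, np.vstack([x1, x2]))
    assert mix == pytest.approx(alpha * parts[0] + (1 - alpha) * parts[1])


def test_mean_row_predicts_mean_response(rng):
    X, y = make_problem(rng)
    model = pe.fit(X, y, 3)
    assert pe.predict(model, X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean())


def test_score_orthogonality_and_unit_weights(rng):
    X, y = make_problem(rng, n=14, p=9)
    model = pe.fit(X, y, 4)
    TtT = model.T.T @ model.T
    off = TtT - np.diag(np.diag(TtT))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(TtT)).max()
    assert np.allclose((model.W**2).sum(axis=0), 1.0)


def test_full_rank_pls_matches_least_squares(rng):
    """With A = rank(X), PLS reproduces the least-squares predictions."""
    for trial in range(5):
        n, p = 12, 5
        X, y = make_problem(rng, n=n, p=p, noise=0.3)
        model = pe.fit(X, y, p)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        assert np.allclose(model.fitted, y.mean() + Xc @ beta, atol=1e-6)


def test_matches_sklearn_nipals(rng):
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    X, y = make_problem(rng, n=20, p=12, noise=0.5)
    X_new = rng.normal(size=(5, 12))
    for A in (1, 3, 5):
        ours = pe.fit(X, y, A)
        ref = sklearn.PLSRegression(n_components=A, scale=False).fit(X, y)
        assert np.allclose(
            pe.predict(ours, X_new), ref.predict(X_new).ravel(), atol=1e-8
        )


def test_deflation_conserves_variance(rng):
    X, y = make_problem(rng, n=10, p=4)
    Xc = X - X.mean(axis=0)
    total = (Xc**2).sum()
    model = pe.fit(X, y, 4)
    explained = sum(
        (np.outer(model.T[:, a], model.P[:, a]) ** 2).sum() for a in range(4)
    )
    assert explained <= total * (1 + 1e-10)
    assert explained == pytest.approx(total, rel=1e-8)  # full rank


def test_column_permutation_equivariance(rng):
    X, y = make_problem(rng)
    perm = rng.permutation(X.shape[1])
    m1 = pe.fit(X, y, 3)
    m2 = pe.fit(X[:, perm], y, 3)
    assert np.allclose(m2.b, m1.b[perm])
    assert np.allclose(pe.vip(m2), pe.vip(m1)[perm])


def test_fit_input_validation(rng):
    X, y = make_problem(rng)
    with pytest.raises(ValueError, match="range"):
        pe.fit(X, y, 0)
    with pytest.raises(ValueError, match="range"):
        pe.fit(X, y, X.shape[0])
    with pytest.raises(ValueError, match="zero-variance"):
        pe.fit(X, np.ones(X.shape[0]), 1)


def test_vip_normalization_and_formula(rng):
    X, y = make_problem(rng, p=7)
    model = pe.fit(X, y, 3)
    v = pe.vip(model)
    assert (v >= 0).all()
    assert (v**2).sum() == pytest.approx(7, rel=1e-6)
    one = pe.fit(X, y, 1)
    assert np.allclose(pe.vip(one), np.sqrt(7) * np.abs(one.W[:, 0]))


def test_vip_uniform_when_columns_identical(rng):
    col = rng.normal(size=10)
    X = np.tile(col[:, None], (1, 5))
    y = 2 * col
    model = pe.fit(X, y, 1)
    assert np.allclose(pe.vip(model), 1.0)


def test_leverage_identities(rng):
    X, y = make_problem(rng, n=12, p=6)
    A = 3
    model = pe.fit(X, y, A)
    h = pe.leverage(model, X)
    assert h.sum() == pytest.approx(A + 1, rel=1e-8)  # hat-trace identity
    assert (h >= 1 / 12 - 1e-12).all()
    assert pe.leverage(model, X.mean(axis=0)[None, :])[0] == pytest.approx(1 / 12)
    # a far-extrapolated point exceeds all training leverages
    far = X.mean(axis=0) + 10 * (X[0] - X.mean(axis=0))
    assert pe.leverage(model, far[None, :])[0] > h.max()


def test_select_components_recovers_rank(rng):
    basis = rng.normal(size=(2, 6))
    X = rng.normal(size=(16, 2)) @ basis
    y = X @ rng.normal(size=6)
    assert pe.select_components(X, y, 5) == 2
    assert pe.select_components(X, y, 1) == 1


def test_loo_predictions_match_explicit_refits(rng):
    X, y = make_problem(rng, n=8, p=3)
    preds = pe.loo_predictions(X, y, 2)
    for i in range(8):
        keep = np.arange(8) != i
        m = pe.fit(X[keep], y[keep], 2)
        assert preds[i, 1] == pytest.approx(pe.predict(m, X[i : i + 1])[0])


def test_model_save_load_roundtrip(tmp_path, rng):
    X, y = make_problem(rng)
    model = pe.fit(X, y, 2, column_mask=np.ones(X.shape[1], dtype=bool))
    pe.save_model(model, tmp_path / "m")
    back = pe.load_model(tmp_path / "m")
    assert back.A == model.A
    assert np.array_equal(back.b, model.b)
    assert np.allclose(pe.predict(back, X), pe.predict(model, X))
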