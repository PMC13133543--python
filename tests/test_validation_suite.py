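"""Calibration / CV / external statistics and the Williams domain."""

import numpy as np
import pytest

from miaqsar import pls_engine as pe
from miaqsar import validation_suite as vs


def test_calibration_perfect_fit():
    y = np.array([5.0, 6.0, 7.0])
    assert vs.calibration_metrics(y, y) == (0.0, pytest.approx(1.0))


def test_calibration_hand_example():
    rmsec, r2 = vs.calibration_metrics([1, 2, 3], [1.1, 1.9, 3.2])
    assert rmsec == pytest.approx(np.sqrt(0.06 / 3))
    assert r2 == pytest.approx(0.9814540059347179)


def test_calibration_degenerate_prediction():
    with pytest.raises(ValueError, match="variance"):
        vs.calibration_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


def test_cross_validation_noiseless_line(rng):
    x = rng.normal(size=10)
    X = x[:, None]
    y = 3 * x + 1
    rmsecv, q2 = vs.cross_validation(X, y, 1)
    assert rmsecv == pytest.approx(0.0, abs=1e-8)
    assert q2 == pytest.approx(1.0)


def test_cross_validation_matches_brute_force_oracle(rng):
    """n=4 single-column LOO: compare against explicit per-fold least squares."""
    x = np.array([0.0, 1.0, 2.0, 4.0])
    y = np.array([1.0, 2.2, 2.8, 5.1])
    X = x[:, None]
    preds = []
    for i in range(4):
        keep = np.arange(4) != i
        slope, icept = np.polyfit(x[keep], y[keep], 1)
        preds.append(slope * x[i] + icept)
    press = ((y - np.asarray(preds)) ** 2).sum()
    rmsecv, q2 = vs.cross_validation(X, y, 1)
    assert rmsecv == pytest.approx(np.sqrt(press / 4))
    assert q2 == pytest.approx(1 - press / ((y - y.mean()) ** 2).sum())


def test_cross_validation_permuted_response_fails(rng):
    X = rng.normal(size=(15, 4))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.05 * rng.normal(size=15)
    _, q2_real = vs.cross_validation(X, y, 2)
    _, q2_perm = vs.cross_validation(X, rng.permutation(y), 2)
    assert q2_real > 0.9
    assert q2_perm <= 0.0


def test_external_metrics_perfect():
    y = np.array([5.0, 6.0, 7.0])
    m = vs.external_metrics(y, y, y_train_mean=6.2)
    for key in ("r2_pred", "ccc", "q2_f1", "q2_f2", "r2m_test", "avg_r2m"):
        assert m[key] == pytest.approx(1.0)
    assert m["rmsep"] == 0.0 and m["mae"] == 0.0 and m["delta_r2m"] == 0.0


def test_external_metrics_constant_bias():
    rngl = np.random.default_rng(3)
    y = rngl.normal(size=8)
    c = 0.5
    m = vs.external_metrics(y, y + c, y_train_mean=float(y.mean()))
    assert m["r2_pred"] == pytest.approx(1.0)
    # closed-form CCC under pure bias: 2 s^2 / (2 s^2 + c^2)
    s2 = y.var()
    assert m["ccc"] == pytest.approx(2 * s2 / (2 * s2 + c**2))
    assert m["ccc"] < 1.0


def test_external_metrics_three_point_oracle():
    """Hand-computed values for y=(5,6,7), yhat=(5.2,5.9,7.1), train mean 6."""
    m = vs.external_metrics([5.0, 6.0, 7.0], [5.2, 5.9, 7.1], 6.0)
    expected = {
        "rmsep": 0.14142135623730942,
        "r2_pred": 0.9774368231046933,
        "r2m_test": 0.940299457303278,
        "avg_r2m": 0.9280706618524501,
        "delta_r2m": 0.02445759090165589,
        "ccc": 0.9844559585492227,
        "q2_f1": 0.97,
        "q2_f2": 0.97,
        "mae": 0.13333333333333316,
    }
    for key, val in expected.items():
        assert m[key] == pytest.approx(val), key


def test_q2f1_equals_q2f2_when_means_match(rng):
    y = rng.normal(size=6)
    yhat = y + 0.1 * rng.normal(size=6)
    m = vs.external_metrics(y, yhat, y_train_mean=float(y.mean()))
    assert m["q2_f1"] == pytest.approx(m["q2_f2"])


def test_ccc_bounded_by_pearson(rng):
    for _ in range(10):
        y = rng.normal(size=12)
        yhat = rng.normal(size=12)
        r = abs(np.corrcoef(y, yhat)[0, 1])
        assert vs.concordance_correlation(y, yhat) <= r + 1e-12


def test_metrics_invariant_to_common_reordering(rng):
    y = rng.normal(size=9)
    yhat = y + 0.2 * rng.normal(size=9)
    perm = rng.permutation(9)
    a = vs.external_metrics(y, yhat, 0.3)
    b = vs.external_metrics(y[perm], yhat[perm], 0.3)
    for key in a:
        assert a[key] == pytest.approx(b[key]), key


@pytest.mark.parametrize(
    "r2, r2_yrand, expected",
    [
        (0.9861, 0.3609, 0.7852),  # vdW-radius model, printed cell
        (0.9936, 0.3388, 0.8066),  # electronegativity model, printed cell
    ],
)
def test_c_r2p_reproduces_reported_cells(r2, r2_yrand, expected):
    _, _, c_r2p = vs.y_randomization_summary(r2, [r2_yrand], [0.5])
    assert round(c_r2p, 4) == expected


def test_c_r2p_degenerate_cases():
    _, _, zero = vs.y_randomization_summary(0.8, [0.8], [0.5])
    assert zero == pytest.approx(0.0)
    with pytest.warns(UserWarning, match="chance"):
        _, _, worse = vs.y_randomization_summary(0.3, [0.6], [0.5])
    assert worse == 0.0


def _assessment(rng, n=20, p=5):
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
    model = pe.fit(X, y, 3)
    return X, y, model


def test_williams_domain_flags(rng):
    X, y, model = _assessment(rng)
    ad = vs.williams_domain(model, X, y)
    assert ad.h_star == pytest.approx(3 * (model.A + 1) / len(y))
    # duplicated centroid row: leverage 1/n, zero residual -> unflagged
    centroid = X.mean(axis=0)[None, :]
    h_c = pe.leverage(model, centroid)[0]
    assert h_c == pytest.approx(1 / len(y))
    # a response shifted by 10 RMSE must be flagged on the residual
    rmse = float(np.sqrt(((y - pe.predict(model, X)) ** 2).mean()))
    y_bad = y.copy()
    y_bad[0] += 10 * rmse
    ad_bad = vs.williams_domain(model, X, y_bad)
    assert "0" in ad_bad.outliers
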