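"""Ridge fit, λ selection, mirroring, prediction, and the output smoother."""

from __future__ import annotations

import numpy as np
import pytest

from mirrormyo.core_data import KinematicRecording, MirrorSpec, ValidationError
from mirrormyo.decoder import (
    RidgeDecoder,
    add_intercept,
    fit_ridge,
    mirror_transform,
    predict_stream,
    select_lambda_nested_cv,
    smooth_predictions,
    smoother_weights,
)
from mirrormyo.schemes_eval import compute_cc

RNG = np.random.default_rng(2024)


def _linear_problem(n=80, p=5, d=3, rng=RNG):
    X = rng.standard_normal((n, p))
    W = rng.standard_normal((p, d))
    b = rng.standard_normal(d)
    return X, W, b, X @ W + b


# ---------------------------------------------------------------------------
# ridge fit
# ---------------------------------------------------------------------------

def test_interpolation_recovers_true_weights():
    """Noise-free full-rank data at λ=0 returns the generating weights."""
    X, W, b, Y = _linear_problem()
    dec = fit_ridge(add_intercept(X), Y, 0.0)
    np.testing.assert_allclose(dec.weights[:-1], W, atol=1e-8)
    np.testing.assert_allclose(dec.weights[-1], b, atol=1e-8)


def test_huge_lambda_shrinks_weights_to_zero():
    X, W, b, Y = _linear_problem()
    w0 = fit_ridge(add_intercept(X), Y, 0.0).weights[:-1]
    w_inf = fit_ridge(add_intercept(X), Y, 1e12).weights[:-1]
    assert np.linalg.norm(w_inf) < 1e-6 * np.linalg.norm(w0)
    # intercept absorbs the mean instead
    dec = fit_ridge(add_intercept(X), Y, 1e12)
    np.testing.assert_allclose(dec.weights[-1], Y.mean(axis=0), atol=1e-5)


def test_matches_normal_equation_oracle():
    """Independent oracle: solve (XᵀX + λD)w = Xᵀy directly."""
    rng = np.random.default_rng(7)
    X1 = add_intercept(rng.standard_normal((5, 2)))
    y = rng.standard_normal((5, 1))
    lam = 1.0
    D = np.eye(3)
    D[-1, -1] = 0.0
    w_oracle = np.linalg.solve(X1.T @ X1 + lam * D, X1.T @ y)
    dec = fit_ridge(X1, y, lam)
    np.testing.assert_allclose(dec.weights, w_oracle, atol=1e-10)


def test_matches_sklearn_ridge():
    """Cross-check against scikit-learn's independent implementation."""
    sklearn = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(8)
    X = rng.standard_normal((60, 7))
    Y = rng.standard_normal((60, 2))
    lam = 3.5
    dec = fit_ridge(add_intercept(X), Y, lam)
    ref = sklearn.Ridge(alpha=lam, fit_intercept=True).fit(X, Y)
    np.testing.assert_allclose(dec.weights[:-1], ref.coef_.T, atol=1e-8)
    np.testing.assert_allclose(dec.weights[-1], ref.intercept_, atol=1e-8)


def test_negative_lambda_rejected():
    X, _, _, Y = _linear_problem()
    with pytest.raises(ValidationError, match="λ|>= 0"):
        fit_ridge(add_intercept(X), Y, -1.0)


def test_rank_deficient_with_zero_lambda_rejected():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((30, 4))
    X = np.hstack([X, X[:, :1]])  # duplicated column
    with pytest.raises(ValidationError, match="rank-deficient"):
        fit_ridge(add_intercept(X), rng.standard_normal(30), 0.0)


def test_monotone_shrinkage():
    X, _, _, Y = _linear_problem()
    X1 = add_intercept(X)
    norms = [
        np.linalg.norm(fit_ridge(X1, Y, lam).weights[:-1])
        for lam in (0.0, 1.0, 10.0, 1e3, 1e6)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


def test_collinear_columns_share_weight():
    """Two identical antagonist columns split the load evenly — the ridge
    mechanism that penalizes co-activating one muscle arbitrarily."""
    rng = np.random.default_rng(10)
    base = rng.standard_normal((100, 1))
    X = np.hstack([base, base, rng.standard_normal((100, 2))])
    y = X @ np.array([1.0, 1.0, 0.3, -0.2]) + 0.1
    dec = fit_ridge(add_intercept(X), y, 1.0)
    assert abs(dec.weights[0, 0] - dec.weights[1, 0]) < 1e-6


def test_fit_is_local_optimum():
    """Objective at the fit beats 100 random perturbations."""
    X, _, _, Y = _linear_problem(d=1)
    X1 = add_intercept(X)
    lam = 2.0
    dec = fit_ridge(X1, Y, lam)
    w = dec.weights[:, 0]

    def obj(wv):
        resid = X1 @ wv - Y[:, 0]
        return resid @ resid + lam * (wv[:-1] @ wv[:-1])

    base = obj(w)
    rng = np.random.default_rng(11)
    for _ in range(100):
        assert obj(w + 1e-3 * rng.standard_normal(len(w))) >= base - 1e-9


# ---------------------------------------------------------------------------
# λ selection
# ---------------------------------------------------------------------------

def exhaustive_grid_oracle(X1, Y, grid, folds=5):
    """Independent re-evaluation of every λ by explicit fold loops."""
    n = X1.shape[0]
    bounds = np.linspace(0, n, folds + 1).round().astype(int)
    scores = np.zeros((len(grid), Y.shape[1]))
    D = np.eye(X1.shape[1])
    D[-1, -1] = 0.0
    for f in range(folds):
        va = np.zeros(n, dtype=bool)
        va[bounds[f]:bounds[f + 1]] = True
        A = X1[~va].T @ X1[~va] + 1e-300 * np.eye(X1.shape[1])
        for gi, lam in enumerate(grid):
            W = np.linalg.lstsq(A + lam * D, X1[~va].T @ Y[~va], rcond=None)[0]
            P = X1[va] @ W
            for d in range(Y.shape[1]):
                c = compute_cc(Y[va][:, d], P[:, d])
                scores[gi, d] += 0.0 if np.isnan(c) else c
    scores /= folds
    out = []
    for d in range(Y.shape[1]):
        best = scores[:, d].max()
        out.append(max(g for gi, g in enumerate(grid) if scores[gi, d] >= best - 1e-9))
    return np.array(out)


def test_noise_free_linear_selects_small_lambda():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 6))
    Y = X @ rng.standard_normal((6, 3))
    lams = select_lambda_nested_cv(add_intercept(X), Y)
    assert np.all(lams <= 1e-3)
    dec = fit_ridge(add_intercept(X), Y, lams)
    Xt = rng.standard_normal((100, 6))
    P = predict_stream(dec, Xt)
    Yt = Xt @ np.linalg.lstsq(X, Y, rcond=None)[0]
    for d in range(3):
        assert compute_cc(Yt[:, d], P[:, d]) > 0.99


def test_pure_noise_selects_large_lambda():
    """With nothing to fit, validation CC favors the shrunk end of the grid."""
    rng = np.random.default_rng(1)
    X = rng.standard_normal((300, 10))
    Y = rng.standard_normal((300, 2))
    lams = select_lambda_nested_cv(add_intercept(X), Y)
    assert np.all(lams >= 1e3)


def test_selection_agrees_with_exhaustive_oracle():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((150, 4))
    Y = X @ rng.standard_normal((4, 2)) + 0.5 * rng.standard_normal((150, 2))
    grid = tuple(10.0 ** k for k in range(-4, 5))
    got = select_lambda_nested_cv(add_intercept(X), Y, grid)
    want = exhaustive_grid_oracle(add_intercept(X), Y, sorted(grid))
    np.testing.assert_allclose(got, want)


def test_single_value_grid():
    X, _, _, Y = _linear_problem()
    lams = select_lambda_nested_cv(add_intercept(X), Y, grid=(7.0,))
    assert np.all(lams == 7.0)


def test_empty_grid_rejected():
    X, _, _, Y = _linear_problem()
    with pytest.raises(ValidationError, match="empty"):
        select_lambda_nested_cv(add_intercept(X), Y, grid=())


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------

def test_mirror_is_involution():
    rng = np.random.default_rng(12)
    kin = KinematicRecording(samples=rng.standard_normal((50, 7)), arm_side="right")
    # zero neutral (the default): bit-exact involution
    twice = mirror_transform(mirror_transform(kin, MirrorSpec()), MirrorSpec())
    np.testing.assert_array_equal(twice.samples, kin.samples)
    assert twice.arm_side == "right"
    # non-zero neutral: involution up to one rounding step
    spec = MirrorSpec(neutral=(1.0, 0.0, -2.0, 0.0, 0.0, 0.0, 0.0))
    twice = mirror_transform(mirror_transform(kin, spec), spec)
    np.testing.assert_allclose(twice.samples, kin.samples, atol=1e-12)


def test_mirror_all_false_is_identity_with_toggled_arm():
    kin = KinematicRecording(samples=np.ones((10, 7)), arm_side="left")
    out = mirror_transform(kin, MirrorSpec.identity())
    np.testing.assert_array_equal(out.samples, kin.samples)
    assert out.arm_side == "right"


def test_mirror_flips_exactly_the_masked_columns():
    ramp = np.tile(np.arange(20, dtype=float)[:, None], (1, 7))
    kin = KinematicRecording(samples=ramp, arm_side="right")
    spec = MirrorSpec(flip_mask=(False, True, True, True, False, False, False))
    out = mirror_transform(kin, spec)
    for d in range(7):
        expected = -ramp[:, d] if d in (1, 2, 3) else ramp[:, d]
        np.testing.assert_array_equal(out.samples[:, d], expected)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_zero_features_predict_intercept():
    X, W, b, Y = _linear_problem()
    dec = fit_ridge(add_intercept(X), Y, 1e-8)
    P = predict_stream(dec, np.zeros((5, X.shape[1])))
    np.testing.assert_allclose(P, np.tile(dec.weights[-1], (5, 1)))


def test_feature_name_binding_enforced():
    X, _, _, Y = _linear_problem()
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    dec = fit_ridge(add_intercept(X), Y, 1.0, feature_names=names)
    with pytest.raises(ValidationError, match="binding"):
        predict_stream(dec, X, feature_names=names[::-1])


def test_prediction_invariant_under_consistent_permutation():
    """Permuting columns together with their names leaves predictions alone."""
    X, _, _, Y = _linear_problem()
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    dec = fit_ridge(add_intercept(X), Y, 1.0, feature_names=names)
    perm = np.random.default_rng(13).permutation(X.shape[1])
    W2 = np.vstack([dec.weights[:-1][perm], dec.weights[-1:]])
    dec2 = RidgeDecoder(
        weights=W2,
        lambda_per_dof=dec.lambda_per_dof,
        feature_names=tuple(names[i] for i in perm),
        dof_names=dec.dof_names,
    )
    np.testing.assert_allclose(
        predict_stream(dec, X), predict_stream(dec2, X[:, perm]), atol=1e-12
    )


def test_decoder_json_round_trip(tmp_path):
    X, _, _, Y = _linear_problem()
    dec = fit_ridge(
        add_intercept(X), Y, (1.0, 2.0, 3.0), mirror=MirrorSpec(),
        provenance={"session": "S1"},
    )
    dec.to_json(tmp_path / "dec.json")
    back = RidgeDecoder.from_json(tmp_path / "dec.json")
    np.testing.assert_array_equal(back.weights, dec.weights)
    np.testing.assert_array_equal(back.lambda_per_dof, dec.lambda_per_dof)
    assert back.feature_names == dec.feature_names
    assert back.mirror == dec.mirror
    assert back.provenance == {"session": "S1"}


# ---------------------------------------------------------------------------
# smoother
# ---------------------------------------------------------------------------

def loop_smoother(x, w):
    """Naive per-frame weighted sum with truncated-window renormalization."""
    out = np.zeros_like(x)
    for t in range(len(x)):
        k = min(t + 1, len(w))
        ws = w[:k] / w[:k].sum()
        out[t] = sum(ws[j] * x[t - j] for j in range(k))
    return out


def test_smoother_weights_are_550ms_linear():
    w = smoother_weights()
    assert len(w) == 10  # round(0.550 * 18)
    np.testing.assert_allclose(w, np.arange(10, 0, -1) / 55.0)


def test_constant_trajectory_unchanged():
    x = np.full((40, 7), 2.5)
    np.testing.assert_allclose(smooth_predictions(x), x, atol=1e-12)


def test_impulse_response_is_weight_sequence():
    x = np.zeros(40)
    j = 15
    x[j] = 1.0
    out = smooth_predictions(x)
    np.testing.assert_allclose(out[j:j + 10], np.arange(10, 0, -1) / 55.0, atol=1e-12)
    assert np.all(out[:j] == 0) and np.all(out[j + 10:] == 0)


def test_ramp_matches_loop_oracle():
    x = np.arange(60, dtype=float)
    np.testing.assert_allclose(
        smooth_predictions(x), loop_smoother(x, smoother_weights()), atol=1e-12
    )


def test_smoother_matches_oracle_on_random_streams():
    rng = np.random.default_rng(14)
    for _ in range(100):
        x = rng.standard_normal(int(rng.integers(3, 50)))
        np.testing.assert_allclose(
            smooth_predictions(x), loop_smoother(x, smoother_weights()), atol=1e-12
        )


def test_smoother_is_causal():
    rng = np.random.default_rng(15)
    x = rng.standard_normal(50)
    a = smooth_predictions(x)
    x2 = x.copy()
    x2[30] += 10.0
    b = smooth_predictions(x2)
    np.testing.assert_array_equal(a[:30], b[:30])
    assert not np.allclose(a[30:40], b[30:40])
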