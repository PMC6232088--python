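"""Metrics, pseudo-online evaluation, and the five decoding schemes."""

from __future__ import annotations

import numpy as np
import pytest

from mirrormyo.core_data import MirrorSpec, PipelineConfig, ValidationError
from mirrormyo.decoder import add_intercept, fit_ridge
from mirrormyo.features import AlignedFeatureSet
from mirrormyo.schemes_eval import (
    PerformanceReport,
    _fold_masks,
    compute_cc,
    compute_nrmse,
    evaluate_pseudo_online,
    prepare_session,
    run_mirror,
    run_recalibrated,
    run_session_to_session,
    run_within_session,
)
from mirrormyo.study import build_study_sessions
from mirrormyo.synthetic import SynthConfig, generate_session


# ---------------------------------------------------------------------------
# metric definitions
# ---------------------------------------------------------------------------

def test_cc_and_nrmse_identity():
    y = np.array([0.0, 1.0, 2.0, 1.0])
    assert compute_cc(y, y) == pytest.approx(1.0)
    assert compute_nrmse(y, y) == 0.0


def test_cc_anticorrelation():
    y = np.array([0.0, 1.0, 2.0, 3.0])
    assert compute_cc(y, -y) == pytest.approx(-1.0)


def test_nrmse_hand_example():
    """Constant offset 1 against range 3: NRMSE = 1/3."""
    y = np.array([0.0, 1.0, 2.0, 3.0])
    yhat = y + 1.0
    assert compute_cc(y, yhat) == pytest.approx(1.0)
    assert compute_nrmse(y, yhat) == pytest.approx(1.0 / 3.0)


def test_constant_prediction_formula():
    """ŷ = mean(y): NRMSE = population std / range; CC missing."""
    rng = np.random.default_rng(0)
    y = rng.standard_normal(50) * 3 + 1
    yhat = np.full_like(y, y.mean())
    n = len(y)
    expected = np.std(y, ddof=1) * np.sqrt((n - 1) / n) / np.ptp(y)
    assert compute_nrmse(y, yhat) == pytest.approx(expected)
    assert np.isnan(compute_cc(np.full(10, 2.0), rng.standard_normal(10)))


def test_metrics_on_toy_20_frame_stream():
    """Frozen toy stream: direct evaluation of the metric formulas."""
    rng = np.random.default_rng(99)
    y = np.cumsum(rng.standard_normal(20))
    yhat = y + 0.3 * rng.standard_normal(20)
    ys, hs = y - y.mean(), yhat - yhat.mean()
    cc_oracle = (ys * hs).sum() / np.sqrt((ys**2).sum() * (hs**2).sum())
    nrmse_oracle = np.sqrt(np.mean((y - yhat) ** 2)) / (y.max() - y.min())
    assert compute_cc(y, yhat) == pytest.approx(cc_oracle, abs=1e-12)
    assert compute_nrmse(y, yhat) == pytest.approx(nrmse_oracle, abs=1e-12)


def test_metric_input_validation():
    with pytest.raises(ValidationError):
        compute_cc(np.zeros(3), np.zeros(4))
    with pytest.raises(ValidationError):
        compute_nrmse(np.zeros((2, 2)), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# pseudo-online evaluation
# ---------------------------------------------------------------------------

def _aligned_linear(n=200, p=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    W = rng.standard_normal((p, 7))
    Y = X @ W
    names = tuple(f"f{i}" for i in range(p))
    return (
        AlignedFeatureSet(
            X=X,
            Y=Y,
            frame_times_s=(np.arange(n) + 1) / 18,
            feature_names=names,
            dof_names=tuple(f"d{i}" for i in range(7)),
        ),
        W,
        names,
    )


def test_perfect_decoder_scores_perfectly():
    aligned, W, names = _aligned_linear()
    dec = fit_ridge(add_intercept(aligned.X), aligned.Y, 0.0, feature_names=names)
    rep = evaluate_pseudo_online(dec, aligned, scheme="t")
    assert rep.mean_cc() == pytest.approx(1.0, abs=1e-9)
    assert rep.mean_nrmse() == pytest.approx(0.0, abs=1e-9)


def test_sign_flipped_decoder_anticorrelates():
    aligned, W, names = _aligned_linear()
    dec = fit_ridge(add_intercept(aligned.X), -aligned.Y, 0.0, feature_names=names)
    rep = evaluate_pseudo_online(dec, aligned, scheme="t")
    assert rep.mean_cc() == pytest.approx(-1.0, abs=1e-9)


def test_report_aggregation_consistency():
    """Grand mean equals the mean of per-DoF means for equal group sizes."""
    aligned, _, names = _aligned_linear(seed=3)
    dec = fit_ridge(add_intercept(aligned.X), aligned.Y, 1.0, feature_names=names)
    rep = evaluate_pseudo_online(dec, aligned, scheme="t")
    assert rep.mean_cc() == pytest.approx(rep.per_dof()["cc"].mean())


def test_report_csv_and_json(tmp_path):
    aligned, _, names = _aligned_linear(seed=4)
    dec = fit_ridge(add_intercept(aligned.X), aligned.Y, 1.0, feature_names=names)
    rep = evaluate_pseudo_online(dec, aligned, scheme="t")
    rep.to_csv(tmp_path / "r.csv")
    rep.to_json(tmp_path / "r.json")
    assert (tmp_path / "r.csv").read_text().startswith("scheme,")
    import json

    summary = json.loads((tmp_path / "r.json").read_text())
    assert {"mean_cc", "mean_nrmse"} <= set(summary)


# ---------------------------------------------------------------------------
# scheme runners
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ws_session():
    return generate_session(
        SynthConfig(n_trials_per_task=2, tasks=("T1", "T2", "T3", "T4"), seed=21)
    )


def test_within_session_runs_and_scores(ws_session):
    rep = run_within_session(ws_session)
    assert 0.3 < rep.mean_cc() <= 1.0
    assert set(rep.rows["fold"].unique()) <= set(range(5))


def test_fold_boundaries_never_split_trials(ws_session):
    cfg = PipelineConfig()
    aligned = prepare_session(ws_session, cfg)
    kin_idx = np.round(aligned.frame_times_s * 18).astype(int) - 1
    masks, _ = _fold_masks(ws_session, aligned, 5)
    stacked = np.zeros(aligned.n_frames, dtype=int)
    for f, m in enumerate(masks):
        stacked[m] = f
    for t in ws_session.trials:
        inside = (kin_idx >= t.start) & (kin_idx < t.end)
        if inside.any():
            assert len(np.unique(stacked[inside])) == 1, t


def test_too_few_trials_rejected():
    s = generate_session(SynthConfig(n_trials_per_task=1, tasks=("T1", "T2"), seed=5))
    with pytest.raises(ValidationError, match="trials"):
        run_within_session(s, folds=5)


def test_ss_arm_mismatch_rejected():
    a = generate_session(SynthConfig(n_trials_per_task=1, tasks=("T1",), seed=6))
    b = generate_session(
        SynthConfig(n_trials_per_task=1, tasks=("T1",), seed=6, arm_side="left")
    )
    with pytest.raises(ValidationError, match="arm"):
        run_session_to_session(a, b)


def test_rss_zero_minutes_equals_ss(ws_session):
    other = generate_session(
        SynthConfig(n_trials_per_task=2, tasks=("T1", "T2", "T3", "T4"), seed=22)
    )
    ss = run_session_to_session(ws_session, other)
    rss = run_recalibrated(ws_session, other, minutes=0.0)
    assert rss.mean_cc() == pytest.approx(ss.mean_cc(), abs=1e-12)


def test_rss_recalibration_frames_never_tested(ws_session):
    other = generate_session(
        SynthConfig(n_trials_per_task=2, tasks=("T1", "T2", "T3", "T4"), seed=23)
    )
    rep = run_recalibrated(ws_session, other, minutes=1.0)
    cut = rep.metadata["cut_kin_index"]
    assert cut > 0
    # metadata carries the snapped boundary; every evaluated frame is after it
    assert rep.metadata["scheme"] == "RSS"


def test_rss_session_too_short_rejected(ws_session):
    with pytest.raises(ValidationError, match="shorter"):
        run_recalibrated(ws_session, ws_session, minutes=60.0)


def test_mirror_same_arm_rejected(ws_session):
    with pytest.raises(ValidationError, match="arms must differ"):
        run_mirror(ws_session, ws_session, task_specific=False)


def test_mirror_degenerate_flipmask_matches_ipsilateral_fit():
    """All-false flip mask on non-mirrored identical arms reduces the
    arm-to-arm scheme to a plain same-data fit: same decoder, same scores."""
    from dataclasses import replace

    from mirrormyo.schemes_eval import _fit

    cfg_a = SynthConfig(
        n_trials_per_task=2, tasks=("T1", "T2", "T3", "T4"), seed=31,
        trial_order="interleaved",
    )
    a = generate_session(cfg_a)
    # same generator, labelled left but with identity mirror: identical data
    b = generate_session(
        replace(cfg_a, arm_side="left", mirror=MirrorSpec.identity(), session_id="b")
    )
    np.testing.assert_array_equal(a.kin.samples, b.kin.samples)
    np.testing.assert_array_equal(a.emg.samples, b.emg.samples)

    cfg = PipelineConfig()
    rep = run_mirror(a, b, task_specific=False, mirror=MirrorSpec.identity(), config=cfg)
    # ipsilateral reference: fit on the same pooled task frames of session a
    # and score each task stream through the public evaluator
    from mirrormyo.schemes_eval import _owned_task_mask

    tasks = ("T1", "T2", "T3", "T4")
    aligned = prepare_session(a, cfg)
    pool = _owned_task_mask(a, aligned, tasks)
    dec = _fit(aligned.subset(pool), cfg, "fixed")
    ref = PerformanceReport()
    for tt in tasks:
        ref = ref.append(
            evaluate_pseudo_online(
                dec, aligned.subset(aligned.frame_tasks == tt), cfg, scheme="ref", task=tt
            )
        )
    assert rep.mean_cc(tasks=tasks) == pytest.approx(ref.mean_cc(tasks=tasks), abs=1e-9)


def test_gaa_pools_tasks_tsaa_does_not():
    sessions = build_study_sessions(seed=41, rotation_deg=0.0, gain_sigma=0.0)
    gaa = run_mirror(
        sessions.calib, sessions.other_arm, task_specific=False, mirror=sessions.mirror
    )
    tsaa = run_mirror(
        sessions.calib, sessions.other_arm, task_specific=True, mirror=sessions.mirror
    )
    assert gaa.metadata["scheme"] == "GAA"
    assert tsaa.metadata["scheme"] == "TSAA"
    # both report the four cued tasks plus the pooled stream
    assert {"T1", "T2", "T3", "T4", "all"} <= set(gaa.rows["task"])


def test_report_append_concatenates():
    r1 = PerformanceReport()
    aligned, _, names = _aligned_linear(seed=8)
    dec = fit_ridge(add_intercept(aligned.X), aligned.Y, 1.0, feature_names=names)
    r2 = evaluate_pseudo_online(dec, aligned, scheme="x")
    merged = r1.append(r2).append(r2)
    assert len(merged.rows) == 2 * len(r2.rows)
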