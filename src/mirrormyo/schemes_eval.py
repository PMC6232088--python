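"""Calibration/transfer decoding schemes and pseudo-online evaluation.

Five schemes are compared, mirroring the study design:

WS
    Within-session: calibrated and tested on the same session and arm with
    a 5-fold cross-validation over contiguous trial blocks; λ selected per
    DoF by nested CV.
SS
    Session-to-session: calibrated on one session, tested on a later
    session of the same arm; λ fixed at 1e4.
RSS
    Recalibrated session-to-session: the previous session plus the first
    ~10 minutes of the new session calibrate the decoder; testing uses only
    the remainder of the new session.
TSAA
    Task-specific arm-to-arm (mirror): per-task decoders calibrated on one
    arm with sign-flipped kinematics and tested on the same task performed
    by the other arm.
GAA
    General arm-to-arm (mirror): one decoder pooling tasks T1-T4, tested
    across tasks or on free movement for generalization runs.

Evaluation is pseudo-online: the stored test stream passes through the
causal pipeline frame by frame exactly as a real-time run would, and the
smoothed predicted kinematics are compared with the smoothed recorded
kinematics by Pearson correlation (CC) and range-normalized RMSE per DoF.
Aggregates are arithmetic means over DoFs, tasks, and runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    MirrorSpec,
    PipelineConfig,
    SessionDataset,
    ValidationError,
)
from .decoder import (
    RidgeDecoder,
    add_intercept,
    fit_ridge,
    mirror_transform,
    predict_stream,
    select_lambda_nested_cv,
    smooth_predictions,
)
from .features import AlignedFeatureSet, extract_features, normalize_online, synchronize
from .preprocess import bandpass_emg, bipolarize_grid, lowpass_kinematics, notch_emg

__all__ = [
    "SchemeSpec",
    "PerformanceReport",
    "prepare_session",
    "compute_cc",
    "compute_nrmse",
    "evaluate_pseudo_online",
    "run_within_session",
    "run_session_to_session",
    "run_recalibrated",
    "run_mirror",
]


@dataclass(frozen=True)
class SchemeSpec:
    """Declarative description of one decoding scheme run."""

    kind: str                       # WS | SS | RSS | TSAA | GAA
    calibration: tuple = ()         # session paths/ids (informational)
    testing: tuple = ()
    lambda_policy: str = "fixed"
    recalibration_minutes: float = 10.0
    task_specific: bool = False
    test_tasks: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("WS", "SS", "RSS", "TSAA", "GAA"):
            raise ValidationError(f"scheme.kind: {self.kind!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

# a recorded trajectory spanning less than this (device units: mm / deg)
# carries no motion; CC and NRMSE are reported missing for such streams
_MOTION_ATOL = 1e-3


def compute_cc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation; NaN (missing) when ``y`` is (numerically) constant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValidationError("compute_cc: need two equal-length 1-D arrays of length >= 2")
    if np.ptp(y) < _MOTION_ATOL:
        return float("nan")
    ys = y - y.mean()
    hs = yhat - yhat.mean()
    sy = np.sqrt((ys * ys).sum())
    sh = np.sqrt((hs * hs).sum())
    if sy <= 0 or sh <= 0:
        return float("nan")
    return float((ys * hs).sum() / (sy * sh))


def compute_nrmse(y: np.ndarray, yhat: np.ndarray, normalizer: str = "range") -> float:
    """RMSE normalized by the recorded trajectory's range (or std)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValidationError("compute_nrmse: need two equal-length 1-D arrays of length >= 2")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    denom = float(np.ptp(y)) if normalizer == "range" else float(np.std(y))
    if denom < _MOTION_ATOL:
        return float("nan")
    return rmse / denom


@dataclass
class PerformanceReport:
    """Tidy per-(scheme, task, DoF, fold) CC/NRMSE table plus aggregates.

    Aggregation follows the averaging convention of the study: arithmetic
    mean over the 7 DoFs, then tasks/folds/runs.  Missing CC values
    (constant recorded trajectory) are excluded from aggregates.
    """

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["scheme", "subject", "session", "task", "dof", "fold", "cc", "nrmse"]
        )
    )
    metadata: dict = field(default_factory=dict)

    def append(self, other: "PerformanceReport") -> "PerformanceReport":
        frames = [df for df in (self.rows, other.rows) if len(df)]
        rows = pd.concat(frames, ignore_index=True) if frames else self.rows
        return PerformanceReport(rows=rows, metadata={**self.metadata, **other.metadata})

    def _pooled(self, tasks=None) -> pd.DataFrame:
        df = self.rows
        if tasks is not None:
            return df[df["task"].isin(tasks)]
        return df[df["task"] == "all"] if (df["task"] == "all").any() else df

    def mean_cc(self, tasks=None) -> float:
        """Mean CC over the pooled stream rows (or the named task rows)."""
        return float(np.nanmean(self._pooled(tasks)["cc"].to_numpy(dtype=float)))

    def mean_nrmse(self, tasks=None) -> float:
        return float(np.nanmean(self._pooled(tasks)["nrmse"].to_numpy(dtype=float)))

    def per_dof(self) -> pd.DataFrame:
        return (
            self._pooled()
            .groupby("dof", sort=False)[["cc", "nrmse"]]
            .mean()
            .reset_index()
        )

    def summary(self) -> dict:
        pooled = self._pooled()
        return {
            "mean_cc": self.mean_cc(),
            "std_cc": float(np.nanstd(pooled["cc"].to_numpy(dtype=float))),
            "mean_nrmse": self.mean_nrmse(),
            "std_nrmse": float(np.nanstd(pooled["nrmse"].to_numpy(dtype=float))),
            "n_rows": int(len(self.rows)),
            "metadata": self.metadata,
        }

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.summary(), indent=2))


# ---------------------------------------------------------------------------
# session -> aligned decoder inputs
# ---------------------------------------------------------------------------

_PREPARE_CACHE: dict = {}


def prepare_session(
    session: SessionDataset,
    config: PipelineConfig | None = None,
    mirror: MirrorSpec | None = None,
) -> AlignedFeatureSet:
    """Full conditioning pipeline: filters, features, alignment, normalization.

    If ``mirror`` is given the recorded kinematics are sign-flipped before
    filtering (the arm-to-arm calibration path).  Frame task labels are
    carried over from the session's trial annotations.  Results are
    memoized per (session, config, mirror) object so scheme suites that
    revisit a session do not recompute the pipeline.
    """
    key = (
        id(session),
        id(config),
        (mirror.flip_mask, mirror.neutral) if mirror is not None else None,
    )
    if key in _PREPARE_CACHE:
        return _PREPARE_CACHE[key]
    out = _prepare_session_uncached(session, config, mirror)
    # hold a reference to the keyed objects so ids stay valid
    _PREPARE_CACHE[key] = out
    _PREPARE_CACHE.setdefault("_refs", []).append((session, config))
    return out


def _prepare_session_uncached(
    session: SessionDataset,
    config: PipelineConfig | None = None,
    mirror: MirrorSpec | None = None,
) -> AlignedFeatureSet:
    cfg = config or PipelineConfig()
    emg = session.emg
    if emg.channel_kind == "monopolar-grid":
        emg = bipolarize_grid(emg)
    emg = bandpass_emg(
        emg, cfg.bandpass_low_hz, cfg.bandpass_high_hz, zero_phase=cfg.zero_phase_filters
    )
    emg = notch_emg(emg, cfg.notch_hz, zero_phase=cfg.zero_phase_filters)

    kin = session.kin
    if mirror is not None:
        kin = mirror_transform(kin, mirror)
    kin = lowpass_kinematics(kin, cfg.kin_lowpass_hz, zero_phase=cfg.zero_phase_filters)

    feats = extract_features(
        emg,
        window_ms=cfg.feature_window_ms,
        out_rate_hz=cfg.output_rate_hz,
        feature_set=cfg.feature_set,
        threshold=cfg.wamp_zc_ssc_threshold,
    )
    feats = normalize_online(feats, cfg.norm_window_s)
    aligned = synchronize(feats, kin)
    if cfg.drop_norm_warmup:
        # normalization statistics stabilize once the trailing window is
        # full; drop up to one window of warm-up, keeping >= half the stream
        W = int(round(cfg.norm_window_s * cfg.output_rate_hz))
        k = min(W, aligned.n_frames // 2)
        aligned = aligned.subset(np.arange(aligned.n_frames) >= k)

    # frame -> task labels from trial intervals on the 18 Hz timeline
    kin_idx = (
        np.round((aligned.frame_times_s - session.kin.start_time_s) * session.kin.rate_hz)
        .astype(int)
        - 1
    )
    tasks = np.full(aligned.n_frames, "", dtype=object)
    for t in session.trials:
        tasks[(kin_idx >= t.start) & (kin_idx < t.end)] = t.task_id
    aligned.frame_tasks = tasks
    return aligned


# ---------------------------------------------------------------------------
# pseudo-online evaluation
# ---------------------------------------------------------------------------

def evaluate_pseudo_online(
    decoder: RidgeDecoder,
    test: AlignedFeatureSet,
    config: PipelineConfig | None = None,
    scheme: str = "",
    task: str | None = None,
    fold: int | None = None,
    subject: str = "",
    session: str = "",
) -> PerformanceReport:
    """Stream the test set through the decoder and score per DoF.

    Predictions and recorded kinematics are both smoothed with the backward
    550 ms linearly-weighted filter before comparison, matching what the
    exoskeleton would execute.  Rows are emitted per DoF for the pooled
    stream (task="all") and, when frame task labels exist, per task.
    """
    cfg = config or PipelineConfig()
    if test.n_frames < 2:
        return PerformanceReport(metadata={"scheme": scheme, "empty_stream": True})
    pred = predict_stream(decoder, test.X, test.feature_names)
    pred_s = smooth_predictions(pred, cfg.smooth_window_ms, cfg.output_rate_hz)
    y_s = smooth_predictions(test.Y, cfg.smooth_window_ms, cfg.output_rate_hz)

    rows = []

    def emit(label: str, mask: np.ndarray):
        if mask.sum() < 2:
            return
        for d, dof in enumerate(test.dof_names):
            rows.append(
                {
                    "scheme": scheme,
                    "subject": subject,
                    "session": session,
                    "task": label,
                    "dof": dof,
                    "fold": fold if fold is not None else -1,
                    "cc": compute_cc(y_s[mask, d], pred_s[mask, d]),
                    "nrmse": compute_nrmse(
                        y_s[mask, d], pred_s[mask, d], cfg.nrmse_normalizer
                    ),
                }
            )

    all_mask = np.ones(test.n_frames, dtype=bool)
    emit(task or "all", all_mask)
    if task is None:
        for t in pd.unique(test.frame_tasks):
            if t:
                emit(str(t), test.frame_tasks == t)
    return PerformanceReport(rows=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# scheme runners
# ---------------------------------------------------------------------------

def _as_aligned(
    s: SessionDataset | AlignedFeatureSet,
    config: PipelineConfig | None,
    mirror: MirrorSpec | None = None,
) -> AlignedFeatureSet:
    if isinstance(s, AlignedFeatureSet):
        return s
    return prepare_session(s, config, mirror)


def _fit(
    train: AlignedFeatureSet,
    config: PipelineConfig,
    lambda_policy: str,
    mirror: MirrorSpec | None = None,
    provenance: dict | None = None,
) -> RidgeDecoder:
    X1 = add_intercept(train.X)
    if lambda_policy == "nested_cv":
        lams = select_lambda_nested_cv(X1, train.Y, config.lambda_grid)
    else:
        lams = np.full(train.Y.shape[1], config.lambda_fixed)
    return fit_ridge(
        X1,
        train.Y,
        lams,
        feature_names=train.feature_names,
        dof_names=train.dof_names,
        mirror=mirror,
        provenance=provenance or {},
    )


def _concat_aligned(parts: list[AlignedFeatureSet]) -> AlignedFeatureSet:
    return AlignedFeatureSet(
        X=np.vstack([p.X for p in parts]),
        Y=np.vstack([p.Y for p in parts]),
        frame_times_s=np.concatenate([p.frame_times_s for p in parts]),
        feature_names=parts[0].feature_names,
        dof_names=parts[0].dof_names,
        frame_tasks=np.concatenate([p.frame_tasks for p in parts]),
        arm_side=parts[0].arm_side,
    )


def _fold_masks(
    session: SessionDataset,
    aligned: AlignedFeatureSet,
    folds: int,
    tasks: tuple[str, ...] | None = None,
):
    """Task-stratified trial-block folds plus an eligibility mask.

    Each task's trial sequence is split into ``folds`` contiguous groups and
    fold f unions group f across tasks, so every fold exercises every DoF
    (a task-pure fold would leave some DoFs at rest, making CC and
    range-normalized error degenerate there).  Fold boundaries never split
    a trial; the rest frames following a trial stay with that trial's fold.
    When ``tasks`` is given, frames owned by other tasks' trials are marked
    ineligible and excluded from both fitting and testing.
    """
    all_trials = sorted(session.trials, key=lambda t: t.start)
    included = [
        i for i, t in enumerate(all_trials) if tasks is None or t.task_id in tasks
    ]
    if len(included) < folds:
        raise ValidationError(
            f"within-session CV needs >= {folds} trials, session has {len(included)}"
        )
    by_task: dict[str, list[int]] = {}
    for i in included:
        by_task.setdefault(all_trials[i].task_id, []).append(i)
    trial_fold = np.full(len(all_trials), -1, dtype=int)
    for k, idxs in enumerate(by_task.values()):
        if len(idxs) >= folds:
            for f, group in enumerate(np.array_split(np.asarray(idxs), folds)):
                trial_fold[group] = f
        else:
            # too few trials for contiguous sub-blocks: round-robin with a
            # task-dependent offset so every fold stays populated
            for j, i in enumerate(idxs):
                trial_fold[i] = (j + k) % folds

    kin_idx = (
        np.round((aligned.frame_times_s - session.kin.start_time_s) * session.kin.rate_hz)
        .astype(int)
        - 1
    )
    starts = np.array([t.start for t in all_trials])
    # frame belongs to the most recent trial started at or before it
    owner = np.clip(np.searchsorted(starts, kin_idx, side="right") - 1, 0, len(all_trials) - 1)
    frame_fold = trial_fold[owner]
    eligible = frame_fold >= 0
    return [frame_fold == f for f in range(folds)], eligible


def run_within_session(
    session: SessionDataset,
    config: PipelineConfig | None = None,
    folds: int = 5,
    lambda_policy: str | None = None,
    tasks: tuple[str, ...] | None = None,
) -> PerformanceReport:
    """WS: 5-fold cross-validation over task-stratified trial blocks.

    Per fold the decoder is fitted on the remaining trial blocks (λ per DoF
    by nested CV unless overridden) and tested pseudo-online on the
    held-out block.  Fold boundaries never split a trial.  ``tasks``
    restricts the scheme to the named tasks (e.g. the cued tasks T1-T4,
    leaving free movement to the generalization analyses).
    """
    cfg = config or PipelineConfig()
    policy = lambda_policy or cfg.lambda_policy
    aligned = prepare_session(session, cfg)
    masks, eligible = _fold_masks(session, aligned, folds, tasks)
    report = PerformanceReport(metadata={"scheme": "WS", "folds": folds})
    for f, mask in enumerate(masks):
        test_mask = mask & eligible
        train_mask = ~mask & eligible
        if test_mask.sum() < 2 or train_mask.sum() < 2:
            continue  # fold emptied (e.g. its trials fell in the warm-up span)
        dec = _fit(
            aligned.subset(train_mask),
            cfg,
            policy,
            provenance={"scheme": "WS", "session": session.session_id, "fold": f},
        )
        report = report.append(
            evaluate_pseudo_online(
                dec,
                aligned.subset(test_mask),
                cfg,
                scheme="WS",
                fold=f,
                subject=session.subject_id,
                session=session.session_id,
            )
        )
    return report


def _owned_task_mask(
    session: SessionDataset, aligned: AlignedFeatureSet, tasks: tuple[str, ...]
) -> np.ndarray:
    """Frames owned by trials of the named tasks (trailing rests included)."""
    trials = sorted(session.trials, key=lambda t: t.start)
    if not trials:
        return np.zeros(aligned.n_frames, dtype=bool)
    kin_idx = (
        np.round((aligned.frame_times_s - session.kin.start_time_s) * session.kin.rate_hz)
        .astype(int)
        - 1
    )
    starts = np.array([t.start for t in trials])
    owner = np.clip(np.searchsorted(starts, kin_idx, side="right") - 1, 0, len(trials) - 1)
    owned = np.array([trials[i].task_id in tasks for i in range(len(trials))])
    return owned[owner]


def _snap_to_trial_end(session: SessionDataset, minutes: float, cfg: PipelineConfig) -> int:
    """Kin-timeline index of the trial end nearest ``minutes`` into the session."""
    cut_frame = minutes * 60.0 * cfg.output_rate_hz
    trial_ends = np.array(sorted(t.end for t in session.trials), dtype=float)
    if len(trial_ends) == 0 or cut_frame >= session.kin.n_samples:
        raise ValidationError(
            f"session {session.session_id} shorter than {minutes} min of data"
        )
    return int(trial_ends[np.argmin(np.abs(trial_ends - cut_frame))])


def run_within_vs_session_transfer(
    calib: SessionDataset,
    test: SessionDataset,
    config: PipelineConfig | None = None,
    folds: int = 5,
    tasks: tuple[str, ...] | None = None,
    lambda_policy: str | None = None,
) -> tuple[PerformanceReport, PerformanceReport]:
    """Stream-matched WS/SS pair on the same session.

    The test session is cross-validated as in WS; additionally a
    session-to-session decoder calibrated on ``calib`` is evaluated on
    exactly the same held-out fold streams.  The two reports therefore
    differ only in where the decoder was calibrated — same day (WS) or a
    previous day (SS) — which is the comparison the transfer analysis is
    about.
    """
    if calib.arm_side != test.arm_side:
        raise ValidationError("run_within_vs_session_transfer: arms differ")
    cfg = config or PipelineConfig()
    policy = lambda_policy or cfg.lambda_policy
    aligned = prepare_session(test, cfg)
    masks, eligible = _fold_masks(test, aligned, folds, tasks)

    train_ss = prepare_session(calib, cfg)
    if tasks is not None:
        train_ss = train_ss.subset(_owned_task_mask(calib, train_ss, tasks))
    dec_ss = _fit(train_ss, cfg, "fixed", provenance={"scheme": "SS", "calib": calib.session_id})

    ws = PerformanceReport(metadata={"scheme": "WS", "folds": folds})
    ss = PerformanceReport(metadata={"scheme": "SS", "stream_matched": True})
    for f, mask in enumerate(masks):
        test_mask = mask & eligible
        train_mask = ~mask & eligible
        if test_mask.sum() < 2 or train_mask.sum() < 2:
            continue
        stream = aligned.subset(test_mask)
        dec_ws = _fit(
            aligned.subset(train_mask),
            cfg,
            policy,
            provenance={"scheme": "WS", "session": test.session_id, "fold": f},
        )
        ws = ws.append(
            evaluate_pseudo_online(dec_ws, stream, cfg, scheme="WS", fold=f,
                                   subject=test.subject_id, session=test.session_id)
        )
        ss = ss.append(
            evaluate_pseudo_online(dec_ss, stream, cfg, scheme="SS", fold=f,
                                   subject=test.subject_id, session=test.session_id)
        )
    return ws, ss


def run_session_to_session(
    calib: SessionDataset,
    test: SessionDataset,
    config: PipelineConfig | None = None,
    skip_test_minutes: float = 0.0,
    calib_tasks: tuple[str, ...] | None = None,
) -> PerformanceReport:
    """SS: fit on the calibration session, test on the new session.

    ``calib_tasks`` restricts calibration to frames owned by trials of the
    named tasks (the study calibrates transfer decoders on the cued tasks,
    keeping free movement for generalization testing).
    ``skip_test_minutes`` drops the opening of the test stream — used when
    comparing against a recalibrated decoder so both schemes face the same
    frames.
    """
    if calib.arm_side != test.arm_side:
        raise ValidationError(
            "run_session_to_session: arms differ — use run_mirror for arm-to-arm transfer"
        )
    cfg = config or PipelineConfig()
    train = prepare_session(calib, cfg)
    if calib_tasks is not None:
        train = train.subset(_owned_task_mask(calib, train, calib_tasks))
    dec = _fit(train, cfg, "fixed", provenance={"scheme": "SS", "calib": calib.session_id})
    test_aligned = prepare_session(test, cfg)
    if skip_test_minutes > 0:
        # same trial-end snapping as run_recalibrated, so an SS/RSS pair
        # is evaluated on exactly the same frames
        cut = _snap_to_trial_end(test, skip_test_minutes, cfg)
        kin_idx = (
            np.round((test_aligned.frame_times_s - test.kin.start_time_s) * test.kin.rate_hz)
            .astype(int)
            - 1
        )
        test_aligned = test_aligned.subset(kin_idx >= cut)
    rep = evaluate_pseudo_online(
        dec,
        test_aligned,
        cfg,
        scheme="SS",
        subject=test.subject_id,
        session=test.session_id,
    )
    rep.metadata.update({"scheme": "SS", "skip_test_minutes": skip_test_minutes})
    return rep


def run_recalibrated(
    calib: SessionDataset,
    test: SessionDataset,
    config: PipelineConfig | None = None,
    minutes: float = 10.0,
    calib_tasks: tuple[str, ...] | None = None,
) -> PerformanceReport:
    """RSS: previous session plus the first `minutes` of the new session
    calibrate the decoder; testing uses only the remainder of the new
    session.  The boundary snaps to the nearest trial end so no trial is
    split between calibration and testing."""
    if calib.arm_side != test.arm_side:
        raise ValidationError("run_recalibrated: arms differ")
    cfg = config or PipelineConfig()
    old = prepare_session(calib, cfg)
    if calib_tasks is not None:
        old = old.subset(_owned_task_mask(calib, old, calib_tasks))
    new = prepare_session(test, cfg)
    # kin-timeline index of each aligned frame (comparable to trial bounds)
    kin_idx = (
        np.round((new.frame_times_s - test.kin.start_time_s) * test.kin.rate_hz).astype(int) - 1
    )

    if minutes > 0:
        cut = _snap_to_trial_end(test, minutes, cfg)
        recal_mask = kin_idx < cut
        if not (~recal_mask).any():
            raise ValidationError("run_recalibrated: no test data left after recalibration window")
    else:
        cut = 0
        recal_mask = np.zeros(new.n_frames, dtype=bool)

    train = _concat_aligned([old, new.subset(recal_mask)]) if recal_mask.any() else old
    dec = _fit(
        train,
        cfg,
        "fixed",
        provenance={"scheme": "RSS", "calib": calib.session_id, "minutes": minutes},
    )
    rep = evaluate_pseudo_online(
        dec,
        new.subset(~recal_mask),
        cfg,
        scheme="RSS",
        subject=test.subject_id,
        session=test.session_id,
    )
    rep.metadata.update({"scheme": "RSS", "cut_kin_index": cut})
    return rep


def run_mirror(
    calib_sessions: list[SessionDataset] | SessionDataset,
    test: SessionDataset,
    task_specific: bool,
    mirror: MirrorSpec | None = None,
    config: PipelineConfig | None = None,
    test_tasks: tuple[str, ...] | None = None,
) -> PerformanceReport:
    """TSAA/GAA: calibrate on one arm with mirrored kinematics, test on the other.

    ``task_specific=True`` fits one decoder per calibration task and tests
    each on its own task (or, for generalization runs, on the streams named
    by ``test_tasks``, e.g. ``("FM",)``).  ``False`` pools tasks T1-T4 into
    a single general decoder.
    """
    if isinstance(calib_sessions, SessionDataset):
        calib_sessions = [calib_sessions]
    for c in calib_sessions:
        if c.arm_side == test.arm_side:
            raise ValidationError(
                "run_mirror: calibration and test arms must differ (same-arm pairing "
                "is a session-to-session scheme)"
            )
    cfg = config or PipelineConfig()
    spec = mirror if mirror is not None else MirrorSpec()
    scheme = "TSAA" if task_specific else "GAA"

    prepared = [(s, prepare_session(s, cfg, mirror=spec)) for s in calib_sessions]
    calib_aligned = _concat_aligned([al for _, al in prepared])
    test_aligned = prepare_session(test, cfg)

    def calib_subset(tasks_sel: tuple[str, ...]) -> AlignedFeatureSet:
        # frames owned by the selected tasks' trials, rests included
        return _concat_aligned(
            [al.subset(_owned_task_mask(s, al, tasks_sel)) for s, al in prepared]
        )

    calib_tasks = [t for t in ("T1", "T2", "T3", "T4") if (calib_aligned.frame_tasks == t).any()]
    if test_tasks is None:
        eval_tasks = [t for t in calib_tasks if (test_aligned.frame_tasks == t).any()]
    else:
        eval_tasks = [t for t in test_tasks if (test_aligned.frame_tasks == t).any()]
    if not eval_tasks:
        raise ValidationError("run_mirror: no evaluable tasks shared by calibration and test")

    def smoothed(dec: RidgeDecoder, subset: AlignedFeatureSet):
        pred = predict_stream(dec, subset.X, subset.feature_names)
        return (
            smooth_predictions(subset.Y, cfg.smooth_window_ms, cfg.output_rate_hz),
            smooth_predictions(pred, cfg.smooth_window_ms, cfg.output_rate_hz),
        )

    # (label, smoothed recorded, smoothed predicted) per evaluated stream
    segments: list[tuple[str, np.ndarray, np.ndarray]] = []
    if task_specific:
        for ct in calib_tasks:
            dec = _fit(
                calib_subset((ct,)),
                cfg,
                "fixed",
                mirror=spec,
                provenance={"scheme": scheme, "task": ct},
            )
            targets = eval_tasks if test_tasks is not None else [ct]
            for tt in targets:
                sub = test_aligned.subset(test_aligned.frame_tasks == tt)
                if sub.n_frames < 2:
                    continue
                label = tt if tt == ct else f"{ct}->{tt}"
                segments.append((label, *smoothed(dec, sub)))
    else:
        dec = _fit(
            calib_subset(tuple(calib_tasks)),
            cfg,
            "fixed",
            mirror=spec,
            provenance={"scheme": scheme, "tasks": calib_tasks},
        )
        for tt in eval_tasks:
            sub = test_aligned.subset(test_aligned.frame_tasks == tt)
            if sub.n_frames < 2:
                continue
            segments.append((tt, *smoothed(dec, sub)))

    rows = []

    def emit(label: str, y_s: np.ndarray, p_s: np.ndarray):
        for d, dof in enumerate(test_aligned.dof_names):
            rows.append(
                {
                    "scheme": scheme,
                    "subject": test.subject_id,
                    "session": test.session_id,
                    "task": label,
                    "dof": dof,
                    "fold": -1,
                    "cc": compute_cc(y_s[:, d], p_s[:, d]),
                    "nrmse": compute_nrmse(y_s[:, d], p_s[:, d], cfg.nrmse_normalizer),
                }
            )

    if not segments:
        raise ValidationError("run_mirror: no evaluable frames in the test session")
    # pooled concatenated stream first (the headline per-DoF metric), then
    # the per-task breakdown the report tables use
    emit("all", np.vstack([y for _, y, _ in segments]), np.vstack([p for _, _, p in segments]))
    for label, y_s, p_s in segments:
        emit(label, y_s, p_s)
    return PerformanceReport(
        rows=pd.DataFrame(rows), metadata={"scheme": scheme, "mirror": spec.to_dict()}
    )
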