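"""Windowed time-domain EMG features, 18 Hz alignment, causal normalization.

Features are computed on right-aligned (causal) 200 ms windows of the
preprocessed EMG, one output frame per 18 Hz kinematic tick, so consecutive
windows overlap by roughly 144 ms.  Two feature sets are supported:

``seven``
    MAV, VAR, WL, RMS, WAMP, ZC, SSC per channel — 70 columns for the
    10-channel bipolar montage.
``five_patient``
    MAV, VAR, WL, RMS, logVAR: the threshold-dependent counters (WAMP, ZC,
    SSC) are dropped, because their counts are not comparable across arms
    with different EMG amplitudes, and the log-variance is added instead.

Definitions on a window ``x`` of n samples with threshold θ::

    MAV  = mean(|x|)
    VAR  = unbiased sample variance (n-1 denominator)
    WL   = Σ |x_i − x_{i−1}|
    RMS  = sqrt(mean(x²))
    WAMP = #{i : |x_i − x_{i−1}| ≥ θ}
    ZC   = #{i : x_i · x_{i+1} < 0  and  |x_i − x_{i+1}| ≥ θ}
    SSC  = #{interior i : (x_i − x_{i−1})(x_i − x_{i+1}) > 0
                          and max(|x_i − x_{i−1}|, |x_i − x_{i+1}|) ≥ θ}
    logVAR = ln(VAR + 1e-12)

θ defaults to 1% of the window's own RMS (causal, amplitude-relative);
an absolute θ, including 0, may be passed instead.

Normalization emulates the online setting: each feature column is z-scored
with the mean and standard deviation of the trailing 60 s of frames; before
60 s of history exists the growing window of all past frames is used, and a
zero-variance guard emits 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import EMGRecording, KinematicRecording, ValidationError

__all__ = [
    "FEATURES_SEVEN",
    "FEATURES_FIVE",
    "LOGVAR_EPS",
    "FeatureMatrix",
    "AlignedFeatureSet",
    "window_features",
    "extract_features",
    "synchronize",
    "normalize_online",
]

FEATURES_SEVEN = ("MAV", "VAR", "WL", "RMS", "WAMP", "ZC", "SSC")
FEATURES_FIVE = ("MAV", "VAR", "WL", "RMS", "logVAR")
LOGVAR_EPS = 1e-12

_SIGMA_EPS = 1e-12


@dataclass
class FeatureMatrix:
    """EMG features on the 18 Hz frame grid.

    ``values`` is ``[n_frames x (n_channels * n_features)]`` with columns
    ordered channel-major: all features of channel 0, then channel 1, ...
    ``warmup`` flags frames computed before one full window of history
    existed.  Every frame derives only from samples at or before its
    timestamp.
    """

    values: np.ndarray
    frame_times_s: np.ndarray
    feature_names: tuple[str, ...]
    feature_set: str
    rate_hz: float = 18.0
    warmup: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.values.shape[0] != self.frame_times_s.shape[0]:
            raise ValidationError("features: values and frame_times_s length mismatch")
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError("features: feature_names length mismatch")
        if self.warmup is None:
            self.warmup = np.zeros(self.values.shape[0], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class AlignedFeatureSet:
    """Decoder-ready (X, Y): normalized features and kinematics on one grid."""

    X: np.ndarray
    Y: np.ndarray
    frame_times_s: np.ndarray
    feature_names: tuple[str, ...]
    dof_names: tuple[str, ...]
    frame_tasks: np.ndarray = field(default=None)  # task label per frame, "" = rest
    arm_side: str = "right"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValidationError("aligned set: X and Y frame counts differ")
        if self.frame_tasks is None:
            self.frame_tasks = np.full(self.X.shape[0], "", dtype=object)

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "AlignedFeatureSet":
        return AlignedFeatureSet(
            X=self.X[mask],
            Y=self.Y[mask],
            frame_times_s=self.frame_times_s[mask],
            feature_names=self.feature_names,
            dof_names=self.dof_names,
            frame_tasks=self.frame_tasks[mask],
            arm_side=self.arm_side,
        )


def window_features(x: np.ndarray, feature_set: str, threshold: float | None) -> np.ndarray:
    """Features of a single window (1-D array). Reference path for one window."""
    wins = np.asarray(x, dtype=float)[None, :]
    return _block_features(wins, feature_set, threshold)[0]


def _block_features(wins: np.ndarray, feature_set: str, threshold: float | None) -> np.ndarray:
    """Features of a stack of equal-length windows: [n_windows x window_len]."""
    n, L = wins.shape
    mav = np.abs(wins).mean(axis=1)
    var = wins.var(axis=1, ddof=1) if L > 1 else np.zeros(n)
    rms = np.sqrt(np.square(wins).mean(axis=1))
    d = np.diff(wins, axis=1) if L > 1 else np.zeros((n, 0))
    wl = np.abs(d).sum(axis=1)

    if feature_set == "five_patient":
        logvar = np.log(var + LOGVAR_EPS)
        return np.column_stack([mav, var, wl, rms, logvar])
    if feature_set != "seven":
        raise ValidationError(f"feature_set: {feature_set!r}")

    if threshold is None:
        theta = 0.01 * rms  # per-window, amplitude-relative
    else:
        theta = np.full(n, float(threshold))
    th = theta[:, None]

    wamp = (np.abs(d) >= th).sum(axis=1) if L > 1 else np.zeros(n)
    if L > 1:
        prod = wins[:, :-1] * wins[:, 1:]
        zc = ((prod < 0) & (np.abs(d) >= th)).sum(axis=1)
    else:
        zc = np.zeros(n)
    if L > 2:
        d1 = wins[:, 1:-1] - wins[:, :-2]   # x_i − x_{i−1}
        d2 = wins[:, 1:-1] - wins[:, 2:]    # x_i − x_{i+1}
        ssc = ((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= th)).sum(axis=1)
    else:
        ssc = np.zeros(n)
    return np.column_stack([mav, var, wl, rms, wamp, zc, ssc])


def extract_features(
    emg: EMGRecording,
    window_ms: float = 200.0,
    out_rate_hz: float = 18.0,
    feature_set: str = "seven",
    threshold: float | None = None,
) -> FeatureMatrix:
    """Causal windowed feature extraction onto the 18 Hz frame grid.

    Frame ``k`` (k = 1..n_frames) sits at ``t = start + k / out_rate`` and is
    computed on the window of ``round(window_ms * rate / 1000)`` samples
    ending at that time.  Frames emitted before one full window of history
    exists use the available growing window and are flagged warm-up.
    """
    rate = emg.rate_hz
    L = int(round(window_ms * rate / 1000.0))
    if L < 2:
        raise ValidationError(f"feature window of {window_ms} ms holds <2 samples at {rate} Hz")
    names = FEATURES_SEVEN if feature_set == "seven" else FEATURES_FIVE
    n_feat = len(names)
    x = emg.samples
    n_samples = x.shape[0]
    n_frames = int(np.floor(n_samples / rate * out_rate_hz + 1e-9))
    if n_frames < 1:
        raise ValidationError("signal shorter than one output frame period")

    ends = np.minimum(
        np.round(np.arange(1, n_frames + 1) / out_rate_hz * rate).astype(int), n_samples
    )
    warmup = ends < L

    out = np.empty((n_frames, x.shape[1] * n_feat))
    full = ~warmup
    if full.any():
        idx = ends[full][:, None] - L + np.arange(L)[None, :]
        for c in range(x.shape[1]):
            out[full, c * n_feat:(c + 1) * n_feat] = _block_features(
                x[:, c][idx], feature_set, threshold
            )
    for k in np.nonzero(warmup)[0]:
        w = x[: ends[k], :]
        for c in range(x.shape[1]):
            out[k, c * n_feat:(c + 1) * n_feat] = window_features(
                w[:, c], feature_set, threshold
            )

    feature_names = tuple(
        f"{ch}__{f}" for ch in emg.channel_names for f in names
    )
    times = emg.start_time_s + np.arange(1, n_frames + 1) / out_rate_hz
    return FeatureMatrix(
        values=out,
        frame_times_s=times,
        feature_names=feature_names,
        feature_set=feature_set,
        rate_hz=out_rate_hz,
        warmup=warmup,
    )


def synchronize(features: FeatureMatrix, kin: KinematicRecording) -> AlignedFeatureSet:
    """Restrict features and kinematics to their common 18 Hz span.

    Each feature frame is matched to the kinematic sample nearest in time;
    matches farther than half a frame period are discarded.  Disjoint spans
    raise an error.
    """
    kt = kin.times()
    half = 0.5 / features.rate_hz
    idx = np.round((features.frame_times_s - kin.start_time_s) * kin.rate_hz).astype(int) - 1
    ok = (idx >= 0) & (idx < kin.n_samples)
    ok[ok] &= np.abs(features.frame_times_s[ok] - kt[idx[ok]]) <= half + 1e-9
    if not ok.any():
        raise ValidationError("synchronize: feature and kinematic spans do not overlap")
    return AlignedFeatureSet(
        X=features.values[ok],
        Y=kin.samples[idx[ok]],
        frame_times_s=features.frame_times_s[ok],
        feature_names=features.feature_names,
        dof_names=kin.dof_names,
        frame_tasks=None,
        arm_side=kin.arm_side,
    )


def normalize_online(
    features: FeatureMatrix, window_s: float = 60.0, clip: float | None = 10.0
) -> FeatureMatrix:
    """Causal z-normalization with a trailing 60 s window of past frames.

    For frame ``i`` the statistics are computed over frames
    ``max(0, i − W + 1) .. i`` with ``W = round(window_s * rate)``
    (population standard deviation).  Columns whose windowed σ falls below
    1e-12 emit 0 for that frame — as do quasi-constant columns whose σ is
    under 0.1% of their windowed mean magnitude, since a feature that never
    varies carries no control information and its standard score is pure
    noise amplification.  Normalized values are additionally clipped to
    ``±clip`` standard scores, the usual online guard against transients.
    """
    W = int(round(window_s * features.rate_hz))
    if W < 1:
        raise ValidationError(f"normalization window of {window_s} s holds no frames")
    x = features.values
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        win = x[max(0, i - W + 1): i + 1]
        mu = win.mean(axis=0)
        sd = win.std(axis=0)
        z = np.zeros(x.shape[1])
        okc = sd > np.maximum(_SIGMA_EPS, 1e-3 * np.abs(mu))
        z[okc] = (x[i, okc] - mu[okc]) / sd[okc]
        out[i] = z
    if clip is not None:
        np.clip(out, -clip, clip, out=out)
    return FeatureMatrix(
        values=out,
        frame_times_s=features.frame_times_s,
        feature_names=features.feature_names,
        feature_set=features.feature_set,
        rate_hz=features.rate_hz,
        warmup=features.warmup.copy(),
        normalized=True,
    )
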