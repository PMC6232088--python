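"""Domain containers, session I/O and configuration.

A recording session pairs raw multichannel surface EMG (sampled at the
amplifier rate, typically 2500 Hz for bipolar setups or 1000 Hz for the
patient protocol) with the 7-DoF exoskeleton trajectory sampled at 18 Hz.
The two streams are stored unsynchronized at their native rates; alignment
onto the 18 Hz frame grid happens downstream in :mod:`mirrormyo.features`.

Timestamp convention: a sample's timestamp marks the *end* of its
acquisition interval, so the k-th 18 Hz frame (0-based index ``k``) lives at
``t = (k + 1) / 18`` seconds plus the stream's start offset.  This makes
every frame a function of strictly past raw samples, which is what a causal
(pseudo-online) pipeline requires.

On disk a session is a directory of delimited text plus a JSON sidecar::

    session_dir/
      emg.csv     one row per EMG sample, header = channel names
      kin.csv     one row per 18 Hz kinematic sample, header = DoF names
      trials.csv  task_id,start,end  (0-based, half-open, 18 Hz timeline)
      meta.json   rates, arm side, condition, subject/session ids, ...

An equivalent single-file HDF5 container is provided for bulk storage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DOF_NAMES",
    "KIN_RATE_HZ",
    "TASKS",
    "EMGRecording",
    "KinematicRecording",
    "Trial",
    "SessionDataset",
    "MirrorSpec",
    "PipelineConfig",
    "ValidationError",
    "read_session",
    "write_session",
    "read_session_hdf5",
    "write_session_hdf5",
]

#: Canonical ordering of the exoskeleton's degrees of freedom.
DOF_NAMES = (
    "forearm_tx",      # forearm translation, x (mm)
    "forearm_ty",      # forearm translation, y (mm)
    "forearm_rot",     # forearm rotation (deg)
    "wrist_pronsup",   # wrist pronation-supination (deg)
    "thumb_flex",      # thumb flexion-extension (deg)
    "index_flex",      # index flexion-extension (deg)
    "mrp_flex",        # middle-ring-pinky flexion-extension (deg)
)

KIN_RATE_HZ = 18.0

#: Task vocabulary: four cued functional tasks plus free movement.
TASKS = ("T1", "T2", "T3", "T4", "FM")

_ARM_SIDES = ("left", "right")
_CONDITIONS = ("active", "compliant")


class ValidationError(ValueError):
    """A container invariant was violated; the message names the field."""


def _as_float_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name}: expected a 2-D samples matrix, got ndim={arr.ndim}")
    return arr


@dataclass
class EMGRecording:
    """Raw multichannel EMG.

    Parameters
    ----------
    samples : (n_samples, n_channels) float array
        Amplifier output in volts or arbitrary units.
    rate_hz : float
        Sampling rate; 2500 Hz (healthy protocol) or 1000 Hz (patients).
    channel_names : sequence of str
        Ordered channel labels.
    channel_kind : {"bipolar", "monopolar-grid"}
        Monopolar grids additionally carry ``grid_shape`` (rows, cols per
        array) and are turned into bipolar derivations by
        :func:`mirrormyo.preprocess.bipolarize_grid`.
    start_time_s : float
        Wall-clock offset of the first sample's acquisition-interval end.
    """

    samples: np.ndarray
    rate_hz: float
    channel_names: tuple[str, ...] = ()
    channel_kind: str = "bipolar"
    grid_shape: tuple[int, int] | None = None
    start_time_s: float = 0.0

    def __post_init__(self):
        self.samples = _as_float_matrix(self.samples, "emg.samples")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i:02d}" for i in range(self.samples.shape[1]))
        else:
            self.channel_names = tuple(self.channel_names)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if not self.rate_hz > 0:
            raise ValidationError(f"emg.rate_hz must be > 0, got {self.rate_hz}")
        if self.samples.shape[1] < 1:
            raise ValidationError("emg.samples: need at least one channel")
        if not np.isfinite(self.samples).all():
            raise ValidationError("emg.samples: non-finite values present")
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValidationError(
                f"emg.channel_names: {len(self.channel_names)} names for "
                f"{self.samples.shape[1]} channels"
            )
        if self.channel_kind not in ("bipolar", "monopolar-grid"):
            raise ValidationError(f"emg.channel_kind: unknown kind {self.channel_kind!r}")
        if self.channel_kind == "monopolar-grid":
            if self.grid_shape is None:
                raise ValidationError("emg.grid_shape: required for monopolar-grid recordings")
            rows, cols = self.grid_shape
            if self.samples.shape[1] % (rows * cols) != 0:
                raise ValidationError(
                    f"emg.grid_shape: {self.samples.shape[1]} channels not a multiple "
                    f"of grid size {rows}x{cols}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        """Per-sample timestamps (end-of-interval convention)."""
        return self.start_time_s + (np.arange(self.n_samples) + 1) / self.rate_hz

    def copy_with(self, **kw) -> "EMGRecording":
        return dataclasses.replace(self, **kw)


@dataclass
class KinematicRecording:
    """7-DoF exoskeleton trajectory at 18 Hz.

    Column order is fixed (:data:`DOF_NAMES`): two forearm translations,
    forearm rotation, wrist pronation-supination, and flexion-extension of
    thumb, index, and the middle-ring-pinky finger group.  Units are the
    device's (mm for translations, degrees elsewhere) and are carried
    through unchanged.
    """

    samples: np.ndarray
    rate_hz: float = KIN_RATE_HZ
    dof_names: tuple[str, ...] = DOF_NAMES
    arm_side: str = "right"
    start_time_s: float = 0.0

    def __post_init__(self):
        self.samples = _as_float_matrix(self.samples, "kin.samples")
        self.dof_names = tuple(self.dof_names)
        self.validate()

    def validate(self) -> None:
        if self.samples.shape[1] != 7:
            raise ValidationError(
                f"kin.samples: expected exactly 7 DoF columns, got {self.samples.shape[1]}"
            )
        if self.rate_hz != KIN_RATE_HZ:
            raise ValidationError(f"kin.rate_hz must be {KIN_RATE_HZ}, got {self.rate_hz}")
        if len(self.dof_names) != 7:
            raise ValidationError(f"kin.dof_names: expected 7 names, got {len(self.dof_names)}")
        if not np.isfinite(self.samples).all():
            raise ValidationError("kin.samples: non-finite values present")
        if self.arm_side not in _ARM_SIDES:
            raise ValidationError(f"kin.arm_side: must be left|right, got {self.arm_side!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + (np.arange(self.n_samples) + 1) / self.rate_hz

    def copy_with(self, **kw) -> "KinematicRecording":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Trial:
    """A trial interval on the 18 Hz timeline: 0-based, half-open [start, end)."""

    task_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.task_id not in TASKS:
            raise ValidationError(f"trial.task_id: unknown task {self.task_id!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"trial interval [{self.start}, {self.end}) is empty or negative"
            )


@dataclass
class SessionDataset:
    """One recording session: EMG + kinematics + trial annotations."""

    emg: EMGRecording
    kin: KinematicRecording
    trials: list[Trial] = field(default_factory=list)
    subject_id: str = "S0"
    session_id: str = "sess0"
    arm_side: str = "right"
    condition: str = "active"

    def __post_init__(self):
        self.trials = [t if isinstance(t, Trial) else Trial(*t) for t in self.trials]
        self.validate()

    def validate(self) -> None:
        self.emg.validate()
        self.kin.validate()
        if self.condition not in _CONDITIONS:
            raise ValidationError(
                f"session.condition: must be active|compliant, got {self.condition!r}"
            )
        if self.arm_side not in _ARM_SIDES:
            raise ValidationError(f"session.arm_side: must be left|right, got {self.arm_side!r}")
        if self.kin.arm_side != self.arm_side:
            raise ValidationError(
                f"session.arm_side {self.arm_side!r} disagrees with kin.arm_side "
                f"{self.kin.arm_side!r}"
            )
        n = self.kin.n_samples
        prev_end = -1
        for t in sorted(self.trials, key=lambda t: t.start):
            if t.end > n:
                raise ValidationError(
                    f"trial [{t.start},{t.end}) exceeds kinematic length {n}"
                )
            if t.start < prev_end:
                raise ValidationError(
                    f"trial [{t.start},{t.end}) overlaps a previous trial"
                )
            prev_end = t.end
        # EMG and kinematics must cover the same wall-clock span.
        if abs(self.emg.duration_s - self.kin.duration_s) >= 1.0 / KIN_RATE_HZ:
            raise ValidationError(
                f"emg duration {self.emg.duration_s:.4f}s and kin duration "
                f"{self.kin.duration_s:.4f}s differ by >= one kinematic sample period"
            )

    def trial_tasks(self) -> list[str]:
        return [t.task_id for t in self.trials]


@dataclass(frozen=True)
class MirrorSpec:
    """Which DoFs change sign when a trajectory transfers between arms.

    ``flip_mask[d]`` true means DoF ``d`` is negated about ``neutral[d]``
    when mirroring.  Applying the transform twice restores the original
    trajectory.  The default flips the axes whose sign convention reverses
    under left-right body symmetry: lateral forearm translation, forearm
    rotation, and wrist pronation-supination.
    """

    flip_mask: tuple[bool, ...] = (True, False, True, True, False, False, False)
    neutral: tuple[float, ...] = (0.0,) * 7

    def __post_init__(self):
        if len(self.flip_mask) != 7:
            raise ValidationError(f"mirror.flip_mask: expected length 7, got {len(self.flip_mask)}")
        if len(self.neutral) != 7:
            raise ValidationError(f"mirror.neutral: expected length 7, got {len(self.neutral)}")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.flip_mask, dtype=bool), np.asarray(self.neutral, dtype=float)

    def to_dict(self) -> dict:
        return {"flip_mask": list(self.flip_mask), "neutral": list(self.neutral)}

    @classmethod
    def from_dict(cls, d: dict) -> "MirrorSpec":
        return cls(tuple(bool(b) for b in d["flip_mask"]), tuple(float(x) for x in d["neutral"]))

    @classmethod
    def identity(cls) -> "MirrorSpec":
        return cls(flip_mask=(False,) * 7)


# regularization grid searched by nested CV: 15 consecutive powers of ten
LAMBDA_GRID = tuple(10.0 ** k for k in range(-7, 8))


@dataclass
class PipelineConfig:
    """End-to-end processing parameters with study defaults.

    The defaults reproduce the acquisition pipeline: 10-500 Hz band-pass and
    50 Hz notch on EMG, 1.5 Hz low-pass on kinematics, 200 ms right-aligned
    feature windows emitted at 18 Hz, causal 60 s z-normalization, and a
    550 ms backward linearly-weighted output smoother.  For 1000 Hz EMG the
    band-pass upper edge is clipped to ``0.45 * rate`` (see
    :func:`mirrormyo.preprocess.effective_band`).
    """

    bandpass_low_hz: float = 10.0
    bandpass_high_hz: float = 500.0
    notch_hz: float = 50.0
    kin_lowpass_hz: float = 1.5
    feature_window_ms: float = 200.0
    output_rate_hz: float = 18.0
    norm_window_s: float = 60.0
    smooth_window_ms: float = 550.0
    feature_set: str = "seven"          # seven | five_patient
    wamp_zc_ssc_threshold: float | None = None   # None -> 0.01 * window RMS
    lambda_policy: str = "nested_cv"    # nested_cv | fixed
    lambda_fixed: float = 1e4
    lambda_grid: tuple[float, ...] = LAMBDA_GRID
    zero_phase_filters: bool = True
    drop_norm_warmup: bool = True
    nrmse_normalizer: str = "range"     # range | std
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("bandpass_low_hz", "bandpass_high_hz", "notch_hz", "kin_lowpass_hz",
                     "feature_window_ms", "output_rate_hz", "norm_window_s",
                     "smooth_window_ms"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"config.{name}: must be strictly positive")
        if self.bandpass_low_hz >= self.bandpass_high_hz:
            raise ValidationError("config: bandpass_low_hz must be < bandpass_high_hz")
        if self.feature_set not in ("seven", "five_patient"):
            raise ValidationError(f"config.feature_set: {self.feature_set!r}")
        if self.lambda_policy not in ("nested_cv", "fixed"):
            raise ValidationError(f"config.lambda_policy: {self.lambda_policy!r}")
        if self.lambda_fixed < 0:
            raise ValidationError("config.lambda_fixed: must be >= 0")
        if self.nrmse_normalizer not in ("range", "std"):
            raise ValidationError(f"config.nrmse_normalizer: {self.nrmse_normalizer!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda_grid"] = list(self.lambda_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "lambda_grid" in d:
            d["lambda_grid"] = tuple(float(x) for x in d["lambda_grid"])
        return cls(**d)


# ---------------------------------------------------------------------------
# session I/O — delimited text + JSON sidecar
# ---------------------------------------------------------------------------

def write_session(dataset: SessionDataset, path: str | Path) -> None:
    """Write a session directory (emg.csv, kin.csv, trials.csv, meta.json).

    Floats are written with Python's shortest round-trip repr, so a
    read-back reproduces the arrays bit-exactly.
    """
    dataset.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(dataset.emg.samples, columns=list(dataset.emg.channel_names)).to_csv(
        path / "emg.csv", index=False
    )
    pd.DataFrame(dataset.kin.samples, columns=list(dataset.kin.dof_names)).to_csv(
        path / "kin.csv", index=False
    )
    pd.DataFrame(
        [(t.task_id, t.start, t.end) for t in dataset.trials],
        columns=["task_id", "start", "end"],
    ).to_csv(path / "trials.csv", index=False)

    meta = {
        "subject_id": dataset.subject_id,
        "session_id": dataset.session_id,
        "arm_side": dataset.arm_side,
        "condition": dataset.condition,
        "emg": {
            "rate_hz": dataset.emg.rate_hz,
            "channel_kind": dataset.emg.channel_kind,
            "grid_shape": list(dataset.emg.grid_shape) if dataset.emg.grid_shape else None,
            "start_time_s": dataset.emg.start_time_s,
        },
        "kin": {
            "rate_hz": dataset.kin.rate_hz,
            "start_time_s": dataset.kin.start_time_s,
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def read_session(path: str | Path) -> SessionDataset:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("emg.csv", "kin.csv", "trials.csv", "meta.json"):
        if not (path / fname).exists():
            raise ValidationError(f"session at {path}: missing {fname}")
    try:
        meta = json.loads((path / "meta.json").read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"session at {path}: malformed meta.json ({e})") from e

    emg_df = pd.read_csv(path / "emg.csv", float_precision="round_trip")
    kin_df = pd.read_csv(path / "kin.csv", float_precision="round_trip")
    trials_df = pd.read_csv(path / "trials.csv")

    grid = meta["emg"].get("grid_shape")
    emg = EMGRecording(
        samples=emg_df.to_numpy(dtype=float),
        rate_hz=float(meta["emg"]["rate_hz"]),
        channel_names=tuple(emg_df.columns),
        channel_kind=meta["emg"].get("channel_kind", "bipolar"),
        grid_shape=tuple(grid) if grid else None,
        start_time_s=float(meta["emg"].get("start_time_s", 0.0)),
    )
    if list(kin_df.columns) != list(DOF_NAMES) and len(kin_df.columns) != 7:
        raise ValidationError(
            f"session at {path}: kin.csv has {len(kin_df.columns)} DoF columns, expected 7"
        )
    kin = KinematicRecording(
        samples=kin_df.to_numpy(dtype=float),
        rate_hz=float(meta["kin"]["rate_hz"]),
        dof_names=tuple(kin_df.columns),
        arm_side=meta["arm_side"],
        start_time_s=float(meta["kin"].get("start_time_s", 0.0)),
    )
    trials = [
        Trial(str(r.task_id), int(r.start), int(r.end)) for r in trials_df.itertuples()
    ]
    return SessionDataset(
        emg=emg,
        kin=kin,
        trials=trials,
        subject_id=str(meta["subject_id"]),
        session_id=str(meta["session_id"]),
        arm_side=meta["arm_side"],
        condition=meta["condition"],
    )


# ---------------------------------------------------------------------------
# optional single-file HDF5 container (groups /emg, /kin, /trials)
# ---------------------------------------------------------------------------

def write_session_hdf5(dataset: SessionDataset, path: str | Path) -> None:
    import h5py

    dataset.validate()
    with h5py.File(path, "w") as f:
        g = f.create_group("emg")
        g.create_dataset("samples", data=dataset.emg.samples)
        g.attrs["rate_hz"] = dataset.emg.rate_hz
        g.attrs["channel_names"] = list(dataset.emg.channel_names)
        g.attrs["channel_kind"] = dataset.emg.channel_kind
        g.attrs["start_time_s"] = dataset.emg.start_time_s
        if dataset.emg.grid_shape:
            g.attrs["grid_shape"] = list(dataset.emg.grid_shape)
        g = f.create_group("kin")
        g.create_dataset("samples", data=dataset.kin.samples)
        g.attrs["rate_hz"] = dataset.kin.rate_hz
        g.attrs["dof_names"] = list(dataset.kin.dof_names)
        g.attrs["start_time_s"] = dataset.kin.start_time_s
        g = f.create_group("trials")
        g.create_dataset("task_id", data=np.array([t.task_id for t in dataset.trials], dtype="S8"))
        g.create_dataset("start", data=np.array([t.start for t in dataset.trials], dtype=np.int64))
        g.create_dataset("end", data=np.array([t.end for t in dataset.trials], dtype=np.int64))
        f.attrs["subject_id"] = dataset.subject_id
        f.attrs["session_id"] = dataset.session_id
        f.attrs["arm_side"] = dataset.arm_side
        f.attrs["condition"] = dataset.condition


def read_session_hdf5(path: str | Path) -> SessionDataset:
    import h5py

    with h5py.File(path, "r") as f:
        ge, gk, gt = f["emg"], f["kin"], f["trials"]
        grid = ge.attrs.get("grid_shape")
        emg = EMGRecording(
            samples=ge["samples"][()],
            rate_hz=float(ge.attrs["rate_hz"]),
            channel_names=tuple(str(c) for c in ge.attrs["channel_names"]),
            channel_kind=str(ge.attrs["channel_kind"]),
            grid_shape=tuple(int(x) for x in grid) if grid is not None else None,
            start_time_s=float(ge.attrs["start_time_s"]),
        )
        kin = KinematicRecording(
            samples=gk["samples"][()],
            rate_hz=float(gk.attrs["rate_hz"]),
            dof_names=tuple(str(c) for c in gk.attrs["dof_names"]),
            arm_side=str(f.attrs["arm_side"]),
            start_time_s=float(gk.attrs["start_time_s"]),
        )
        trials = [
            Trial(t.decode(), int(s), int(e))
            for t, s, e in zip(gt["task_id"][()], gt["start"][()], gt["end"][()])
        ]
        return SessionDataset(
            emg=emg,
            kin=kin,
            trials=trials,
            subject_id=str(f.attrs["subject_id"]),
            session_id=str(f.attrs["session_id"]),
            arm_side=str(f.attrs["arm_side"]),
            condition=str(f.attrs["condition"]),
        )
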