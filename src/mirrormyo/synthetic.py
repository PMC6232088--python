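"""Seeded generator of paired EMG + kinematics sessions.

The simulator produces sessions with the statistical structure the mirror
decoding method assumes, so every pipeline stage and transfer scheme can be
verified without the study's recordings:

* **Kinematics** follow the task protocol: minimum-jerk reaches over a
  70 x 50 cm workspace toward four targets (T1), static distal gestures at
  the rest posture (T2), reach + pointing and reach + grasp compounds
  (T3/T4), and a free-movement mode (FM) that wanders the whole workspace
  through minimum-jerk segments between random waypoints.  Trials are
  separated by 2-3 s rests.

* **EMG** is driven by a shared muscle-synergy structure: a nonnegative
  loading matrix ``S`` (channels x 7) maps a per-DoF drive signal — a
  tonic postural tone plus the signed normalized excursion from rest plus a
  weighted normalized speed term — to channel activation envelopes.  Each channel's signal is a band-limited
  (10-500 Hz) unit-RMS noise carrier amplitude-modulated by its envelope,
  plus white sensor noise at a configurable SNR.  This deliberately models
  envelope-scale statistics only (no motor-unit physiology): the decoding
  pipeline consumes nothing finer.

* **Two arms** share the same ``S``; a left-arm session records kinematics
  with the sign-convention DoFs flipped while the EMG derives from the
  intrinsic (unflipped) drive — the premise that healthy inter-limb synergy
  structure is equal.

* **Inter-session variability** is emulated by :func:`perturb_session`:
  per-channel gain jitter and a small rotation in channel space (each
  electrode picking up a neighboring mixture), standing in for electrode
  shift and impedance change across days.

* **A "paretic" mode** corrupts the synergy structure: the effective
  loading matrix is ``(1-γ)·S + γ·C`` where ``C`` merges pairs of synergy
  columns and adds antagonist co-activation — a stand-in for the merged
  post-stroke synergy phenomenology, not a pathology model.

Every output is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_data import (
    DOF_NAMES,
    KIN_RATE_HZ,
    EMGRecording,
    KinematicRecording,
    MirrorSpec,
    SessionDataset,
    Trial,
    ValidationError,
)

__all__ = [
    "SynthConfig",
    "DEFAULT_SYNERGY",
    "TRIAL_DURATION_S",
    "corruption_matrix",
    "minimum_jerk",
    "generate_kinematics",
    "generate_emg_from_kinematics",
    "generate_session",
    "perturb_session",
]

#: Cued trial durations in the active condition (seconds).
TRIAL_DURATION_S = {"T1": 5.0, "T2": 4.0, "T3": 8.0, "T4": 8.0}

# workspace geometry (mm): rest at origin, four targets on a 700 x 500 mat
_TARGETS = np.array([[-250.0, 150.0], [-90.0, 300.0], [90.0, 300.0], [250.0, 150.0]])

# per-DoF nominal span used to normalize drive signals
# (tx, ty in mm; rotations/flexions in deg)
_DOF_SPAN = np.array([250.0, 320.0, 45.0, 50.0, 55.0, 55.0, 55.0])

# T2 gesture targets on (rot, pronsup, thumb, index, mrp)
_GESTURES = {
    "pinch": (0.0, 0.0, 50.0, 50.0, 0.0),
    "cylindrical": (0.0, 0.0, 50.0, 50.0, 50.0),
    "point": (0.0, 0.0, 40.0, 0.0, 50.0),
    "supination": (0.0, 50.0, 0.0, 0.0, 0.0),
    "pronation": (0.0, -50.0, 0.0, 0.0, 0.0),
}
_GESTURE_ORDER = ("pinch", "cylindrical", "point", "supination", "pronation")

#: Default synergy loading matrix, 10 channels x 7 DoF drives.  Rows follow
#: the bipolar montage: thumb abductor, wrist/finger extensors, finger
#: flexor group, pronator, biceps, triceps, and three deltoid portions.
DEFAULT_SYNERGY = np.array(
    [
        # tx    ty    rot   ps    th    ix    mrp
        [0.00, 0.00, 0.00, 0.20, 1.00, 0.00, 0.00],  # abductor pollicis longus
        [0.00, 0.00, 0.00, 0.80, 0.00, 0.10, 0.40],  # extensor carpi ulnaris
        [0.00, 0.00, 0.00, 0.00, 0.15, 1.00, 0.25],  # extensor digitorum (index-dominant)
        [0.00, 0.00, 0.20, 0.30, 0.20, 0.25, 1.00],  # flexor carpi/palmaris group
        [0.00, 0.00, 0.30, 1.00, 0.00, 0.00, 0.20],  # pronator teres
        [0.20, 0.80, 0.60, 0.20, 0.00, 0.00, 0.00],  # biceps, long head
        [0.30, 0.90, 0.20, 0.00, 0.00, 0.00, 0.00],  # triceps, external head
        [0.50, 0.70, 0.00, 0.00, 0.00, 0.00, 0.00],  # deltoid, anterior
        [1.00, 0.30, 0.20, 0.00, 0.00, 0.00, 0.00],  # deltoid, lateral
        [0.80, 0.20, 0.70, 0.00, 0.00, 0.00, 0.00],  # deltoid, posterior
    ]
)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic session."""

    n_trials_per_task: int = 3
    tasks: tuple[str, ...] = ("T1", "T2", "T3", "T4")
    fm_duration_s: float = 40.0          # used when "FM" in tasks
    emg_rate_hz: float = 2500.0
    n_channels: int = 10
    synergy: np.ndarray | None = None    # None -> DEFAULT_SYNERGY
    mirror: MirrorSpec = field(default_factory=MirrorSpec)
    paretic_gamma: float = 0.0
    snr_db: float | None = 20.0          # None -> no sensor noise
    velocity_weight: float = 0.2         # 0 -> purely posture-driven (linear) envelopes
    carrier: str = "noise"               # noise | tone (deterministic, noise-free limit)
    # new-recording-day perturbations, applied to the loading matrix at
    # generation time: electrode shift re-mixes the muscle sources each
    # channel senses (rotation), impedance change rescales channels (gain)
    loading_rotation_deg: float = 0.0
    gain_jitter_sigma: float = 0.0
    trial_order: str = "blocked"         # blocked (protocol order) | interleaved
    arm_side: str = "right"
    condition: str = "active"
    subject_id: str = "synth"
    session_id: str = "sess0"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.paretic_gamma <= 1.0:
            raise ValidationError(f"synth.paretic_gamma must be in [0, 1], got {self.paretic_gamma}")
        if self.synergy is not None:
            self.synergy = np.asarray(self.synergy, dtype=float)
            if (self.synergy < 0).any():
                raise ValidationError("synth.synergy: loadings must be nonnegative")
            if self.synergy.shape != (self.n_channels, 7):
                raise ValidationError(
                    f"synth.synergy: expected shape ({self.n_channels}, 7), "
                    f"got {self.synergy.shape}"
                )
        for t in self.tasks:
            if t not in ("T1", "T2", "T3", "T4", "FM"):
                raise ValidationError(f"synth.tasks: unknown task {t!r}")
        if self.carrier not in ("noise", "tone"):
            raise ValidationError(f"synth.carrier: {self.carrier!r}")
        if self.trial_order not in ("blocked", "interleaved"):
            raise ValidationError(f"synth.trial_order: {self.trial_order!r}")

    def synergy_matrix(self) -> np.ndarray:
        """Loading matrix after any new-day perturbation (rotation + gains)."""
        if self.synergy is not None:
            S = self.synergy.copy()
        else:
            if self.n_channels != DEFAULT_SYNERGY.shape[0]:
                raise ValidationError(
                    f"synth: no default synergy for {self.n_channels} channels; pass one"
                )
            S = DEFAULT_SYNERGY.copy()
        if self.loading_rotation_deg != 0.0:
            S = np.clip(_channel_rotation(S.shape[0], self.loading_rotation_deg) @ S, 0.0, None)
        if self.gain_jitter_sigma > 0.0:
            rng = np.random.default_rng((self.seed, 0x6A17))
            S = S * np.exp(rng.normal(0.0, self.gain_jitter_sigma, size=S.shape[0]))[:, None]
        return S


def _channel_rotation(n_ch: int, angle_deg: float) -> np.ndarray:
    """Composed Givens rotations between adjacent channel pairs.

    Models each shifted electrode picking up a mixture of neighboring
    sources; angle 0 is the identity.
    """
    theta = np.deg2rad(angle_deg)
    R = np.eye(n_ch)
    for c in range(0, n_ch - 1, 2):
        G = np.eye(n_ch)
        G[c, c] = G[c + 1, c + 1] = np.cos(theta)
        G[c, c + 1] = np.sin(theta)
        G[c + 1, c] = -np.sin(theta)
        R = G @ R
    return R


def corruption_matrix(S: np.ndarray) -> np.ndarray:
    """Deterministic 'paretic' loading matrix: merged synergy columns plus
    antagonist co-activation, rescaled to the original column norms."""
    S = np.asarray(S, dtype=float)
    C = 0.5 * (S + np.roll(S, -1, axis=1)) + 0.3 * np.roll(S, 3, axis=1)
    norms_s = np.linalg.norm(S, axis=0)
    norms_c = np.linalg.norm(C, axis=0)
    scale = np.where(norms_c > 0, norms_s / np.maximum(norms_c, 1e-12), 1.0)
    return C * scale


def minimum_jerk(x0: np.ndarray, x1: np.ndarray, n_frames: int) -> np.ndarray:
    """Minimum-jerk interpolation over n_frames (endpoints included).

    ``x(τ) = x0 + (x1 − x0)(10τ³ − 15τ⁴ + 6τ⁵)`` — zero velocity and
    acceleration at both ends.
    """
    tau = np.linspace(0.0, 1.0, n_frames)[:, None]
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return np.asarray(x0) + (np.asarray(x1) - np.asarray(x0)) * s


def _frames(seconds: float) -> int:
    return int(round(seconds * KIN_RATE_HZ))


def _mj_segment(traj: np.ndarray, dofs, t0: int, t1: int, targets) -> None:
    """Fill traj[t0:t1, dofs] with a minimum-jerk move ending at `targets`."""
    t0 = max(0, min(t0, traj.shape[0] - 1))
    t1 = min(t1, traj.shape[0])
    if t1 - t0 < 2:
        return
    start = traj[t0, list(dofs)].copy()
    seg = minimum_jerk(start, np.asarray(targets, dtype=float), t1 - t0)
    traj[t0:t1, list(dofs)] = seg
    traj[t1:, list(dofs)] = seg[-1]


class _Protocol:
    """Per-trial choice source for the task builders.

    *Active* condition: targets, gestures and postural idiosyncrasies are
    randomized per trial (self-paced movement).  *Compliant* condition: the
    exoskeleton drives predefined movements kept constant across the trials
    of each task — fixed target, fixed reach pair, fixed gesture, zero
    idiosyncratic components, fixed rests — so the session stream is
    periodic.
    """

    _PAIRS = ((0, 2), (3, 1))

    def __init__(self, rng: np.random.Generator, compliant: bool):
        self.rng = rng
        self.compliant = compliant
        self._counts: dict[str, int] = {}

    def _tick(self, key: str) -> int:
        c = self._counts.get(key, 0)
        self._counts[key] = c + 1
        return c

    def target(self) -> int:
        if self.compliant:
            return 0
        return int(self.rng.integers(len(_TARGETS)))

    def pair(self) -> tuple[int, int]:
        if self.compliant:
            # alternates between the reach-pair prototypes of T3 and T4
            return self._PAIRS[self._tick("pair") % len(self._PAIRS)]
        a, b = self.rng.choice(len(_TARGETS), size=2, replace=False)
        return int(a), int(b)

    def gesture(self) -> str:
        if self.compliant:
            return "cylindrical"
        return _GESTURE_ORDER[int(self.rng.integers(len(_GESTURE_ORDER)))]

    def jitter(self, lo: float, hi: float) -> float:
        return 0.0 if self.compliant else float(self.rng.uniform(lo, hi))

    def rest_s(self) -> float:
        return 2.5 if self.compliant else float(self.rng.uniform(2.0, 3.0))


def _reach_pose(proto: _Protocol, target: np.ndarray) -> tuple[float, float]:
    """Forearm rotation / pron-sup posture adopted while reaching a target.

    Orientation follows the target laterally plus a per-reach idiosyncratic
    component, so the orientation DoFs are excited but not collinear with
    the translations.
    """
    rot = 25.0 * target[0] / 250.0 + proto.jitter(-18.0, 18.0)
    ps = 15.0 * target[0] / 250.0 + proto.jitter(-25.0, 25.0)
    return rot, ps


def _t1_trial(proto: _Protocol, duration_s: float) -> np.ndarray:
    n = _frames(duration_s)
    traj = np.zeros((n, 7))
    target = _TARGETS[proto.target()]
    rot, ps = _reach_pose(proto, target)
    reach, hold = _frames(1.8), _frames(0.6)
    t0 = _frames(0.3)
    _mj_segment(traj, (0, 1, 2, 3), t0, t0 + reach, (*target, rot, ps))
    t1 = t0 + reach + hold
    _mj_segment(traj, (0, 1, 2, 3), t1, min(t1 + reach, n), (0.0,) * 4)
    return traj


def _t2_trial(proto: _Protocol, duration_s: float, gesture: str | None = None) -> np.ndarray:
    n = _frames(duration_s)
    traj = np.zeros((n, 7))
    g = gesture or proto.gesture()
    targets = _GESTURES[g]
    rise, hold = _frames(0.8), _frames(1.4)
    t0 = _frames(0.3)
    _mj_segment(traj, (2, 3, 4, 5, 6), t0, t0 + rise, targets)
    t1 = t0 + rise + hold
    _mj_segment(traj, (2, 3, 4, 5, 6), t1, min(t1 + rise, n), (0.0,) * 5)
    return traj


def _t3_trial(proto: _Protocol, duration_s: float) -> np.ndarray:
    n = _frames(duration_s)
    traj = np.zeros((n, 7))
    a, b = proto.pair()
    reach = _frames(1.6)
    t = _frames(0.3)
    # reach target a while raising the pointing gesture (pronated wrist)
    rot_a, ps_a = _reach_pose(proto, _TARGETS[a])
    _mj_segment(traj, (0, 1, 2, 3), t, t + reach, (*_TARGETS[a], rot_a, ps_a - 20.0))
    _mj_segment(traj, (4, 6), t, t + _frames(0.8), (40.0, 50.0))  # point: thumb+mrp flex
    t += reach + _frames(0.4)
    rot_b, ps_b = _reach_pose(proto, _TARGETS[b])
    _mj_segment(traj, (0, 1, 2, 3), t, t + reach, (*_TARGETS[b], rot_b, ps_b - 20.0))
    t += reach + _frames(0.4)
    _mj_segment(traj, (0, 1, 2, 3), t, min(t + reach, n), (0.0,) * 4)
    _mj_segment(traj, (4, 6), min(t + _frames(0.6), n - 1), min(t + _frames(1.4), n), (0.0, 0.0))
    return traj


def _t4_trial(proto: _Protocol, duration_s: float) -> np.ndarray:
    n = _frames(duration_s)
    traj = np.zeros((n, 7))
    a, b = proto.pair()
    grasp = (50.0, 50.0, 35.0)  # thumb, index, mrp: cylindrical-like grip
    reach, act = _frames(1.6), _frames(0.6)
    t = _frames(0.3)
    rot_a, ps_a = _reach_pose(proto, _TARGETS[a])
    _mj_segment(traj, (0, 1, 2, 3), t, t + reach, (*_TARGETS[a], rot_a, ps_a))
    t += reach
    _mj_segment(traj, (4, 5, 6), t, t + act, grasp)       # grab the object
    t += act
    rot_b, ps_b = _reach_pose(proto, _TARGETS[b])
    _mj_segment(traj, (0, 1, 2, 3), t, t + reach, (*_TARGETS[b], rot_b, ps_b))  # carry
    t += reach
    _mj_segment(traj, (4, 5, 6), t, t + act, (0.0,) * 3)  # release
    t += act
    _mj_segment(traj, (0, 1, 2, 3), t, min(t + reach, n), (0.0,) * 4)
    return traj


def _fm_trial(proto: _Protocol, duration_s: float) -> np.ndarray:
    """Free movement: minimum-jerk hops between random workspace waypoints.

    Free movement is unconstrained in both conditions, so waypoints stay
    random even under the compliant protocol.
    """
    rng = proto.rng
    n = _frames(duration_s)
    traj = np.zeros((n, 7))
    lo = np.array([-250.0, 0.0, -45.0, -50.0, 0.0, 0.0, 0.0])
    hi = np.array([250.0, 320.0, 45.0, 50.0, 55.0, 55.0, 55.0])
    t = 0
    while t < n - 1:
        seg = min(_frames(float(rng.uniform(1.2, 2.4))), n - t)
        if seg < 2:
            break
        target = rng.uniform(lo, hi)
        _mj_segment(traj, tuple(range(7)), t, t + seg, target)
        t += seg
    return traj


_TRIAL_BUILDERS = {"T1": _t1_trial, "T2": _t2_trial, "T3": _t3_trial, "T4": _t4_trial,
                   "FM": _fm_trial}


def generate_kinematics(
    task: str, duration_s: float | None = None, seed: int = 0, condition: str = "active"
) -> KinematicRecording:
    """One trial's intrinsic (right-arm convention) 18 Hz trajectory."""
    if task not in _TRIAL_BUILDERS:
        raise ValidationError(f"generate_kinematics: unknown task {task!r}")
    dur = duration_s if duration_s is not None else TRIAL_DURATION_S.get(task, 10.0)
    proto = _Protocol(np.random.default_rng(seed), condition == "compliant")
    traj = _TRIAL_BUILDERS[task](proto, dur)
    return KinematicRecording(samples=traj, dof_names=DOF_NAMES, arm_side="right")


#: Tonic drive at the rest posture.  Keeps the drive nonnegative over the
#: workspace (signed excursion spans ±0.5 after scaling) and models the
#: postural muscle tone that lets activation fall below baseline for
#: movements against a muscle's preferred direction.
_TONIC = 0.5


def _drive(kin_samples: np.ndarray, velocity_weight: float, tonic: float = _TONIC) -> np.ndarray:
    """Per-DoF drive: tonic tone + signed normalized excursion + weighted speed."""
    p = tonic + 0.5 * kin_samples / _DOF_SPAN
    if velocity_weight > 0 and kin_samples.shape[0] > 1:
        v = np.abs(np.gradient(kin_samples, axis=0)) * KIN_RATE_HZ / _DOF_SPAN
        return p + velocity_weight * v
    return p


def generate_emg_from_kinematics(
    kin: KinematicRecording,
    S: np.ndarray,
    snr_db: float | None = 20.0,
    gamma: float = 0.0,
    seed: int = 0,
    emg_rate_hz: float = 2500.0,
    velocity_weight: float = 0.2,
    tonic: float = _TONIC,
    carrier: str = "noise",
) -> EMGRecording:
    """Synthesize synergy-driven EMG for a trajectory.

    Channel activation envelopes are ``rectify(S_eff @ g)`` with
    ``S_eff = (1−γ)·S + γ·C(S)`` and ``g`` the per-DoF drive; each envelope
    amplitude-modulates a unit-RMS carrier at the EMG rate, and white
    sensor noise is added at ``snr_db`` (None disables it).

    ``carrier='noise'`` (default) uses band-limited (10-500 Hz) Gaussian
    noise, the realistic interference-EMG model whose windowed features
    carry estimation noise.  ``carrier='tone'`` uses a deterministic
    sinusoid per channel (distinct in-band frequencies): windowed features
    then become noise-free functions of the envelope — the exactly-linear
    regime for parameter-recovery checks.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[1] != 7 or S.ndim != 2:
        raise ValidationError(f"generate_emg: synergy matrix must be [n_channels x 7], got {S.shape}")
    if not 0.0 <= gamma <= 1.0:
        raise ValidationError(f"generate_emg: gamma must be in [0, 1], got {gamma}")
    S_eff = (1.0 - gamma) * S + gamma * corruption_matrix(S)

    g = _drive(kin.samples, velocity_weight, tonic)   # frames x 7
    env = np.maximum(g @ S_eff.T, 0.0)                # frames x channels

    n_frames = kin.n_samples
    n_samples = int(round(n_frames / KIN_RATE_HZ * emg_rate_hz))
    t_frames = (np.arange(n_frames) + 1) / KIN_RATE_HZ
    t_samples = (np.arange(n_samples) + 1) / emg_rate_hz

    rng = np.random.default_rng(seed)
    n_ch = S.shape[0]
    low, high = 10.0, min(500.0, 0.45 * emg_rate_hz)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=emg_rate_hz, output="sos")

    out = np.empty((n_samples, n_ch))
    for c in range(n_ch):
        if carrier == "tone":
            # distinct high in-band frequencies: many periods per 200 ms
            # window keep the windowed-feature ripple small without making
            # the feature columns exactly collinear
            f_c = 311.0 + 13.0 * c
            wave = np.sqrt(2.0) * np.sin(2 * np.pi * f_c * t_samples + rng.uniform(0, 2 * np.pi))
        else:
            wave = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
            wave /= max(np.sqrt(np.mean(wave**2)), 1e-12)
        out[:, c] = np.interp(t_samples, t_frames, env[:, c]) * wave

    if snr_db is not None and np.isfinite(snr_db):
        signal_rms = float(np.sqrt(np.mean(out**2)))
        scale = signal_rms if signal_rms > 0 else 1.0
        noise_rms = scale * 10.0 ** (-snr_db / 20.0)
        out = out + noise_rms * rng.standard_normal(out.shape)

    return EMGRecording(
        samples=out,
        rate_hz=emg_rate_hz,
        channel_names=tuple(f"ch{i:02d}" for i in range(n_ch)),
        channel_kind="bipolar",
    )


def generate_session(config: SynthConfig) -> SessionDataset:
    """Assemble a full session: trials with 2-3 s inter-trial rests, task
    annotations, synergy-driven EMG, and metadata.

    For a left-arm session the *recorded* kinematics are the mirror image
    (sign-convention DoFs flipped) of the intrinsic trajectories, while the
    EMG derives from the intrinsic drive — both arms share the synergy
    matrix.
    """
    rng = np.random.default_rng(config.seed)
    proto = _Protocol(rng, config.condition == "compliant")
    S = config.synergy_matrix()

    # blocked: all trials of a task before the next task (protocol order);
    # interleaved: tasks cycle T1,T2,...,T1,T2,... (keeps the trailing
    # normalization window representative of every task at all times)
    cued = [t for t in config.tasks if t != "FM"]
    if config.trial_order == "blocked":
        order = [t for t in cued for _ in range(config.n_trials_per_task)]
    else:
        order = [t for _ in range(config.n_trials_per_task) for t in cued]
    if "FM" in config.tasks:
        order.append("FM")

    segments: list[np.ndarray] = [np.zeros((_frames(2.0), 7))]  # lead-in rest
    trials: list[Trial] = []
    cursor = segments[0].shape[0]
    for task in order:
        dur = config.fm_duration_s if task == "FM" else TRIAL_DURATION_S[task]
        traj = _TRIAL_BUILDERS[task](proto, dur)
        trials.append(Trial(task, cursor, cursor + traj.shape[0]))
        segments.append(traj)
        cursor += traj.shape[0]
        rest = np.zeros((_frames(proto.rest_s()), 7))
        segments.append(rest)
        cursor += rest.shape[0]

    intrinsic = np.vstack(segments)
    kin_intrinsic = KinematicRecording(samples=intrinsic, dof_names=DOF_NAMES, arm_side="right")

    emg = generate_emg_from_kinematics(
        kin_intrinsic,
        S,
        snr_db=config.snr_db,
        gamma=config.paretic_gamma,
        seed=int(rng.integers(2**31 - 1)),
        emg_rate_hz=config.emg_rate_hz,
        velocity_weight=config.velocity_weight,
        carrier=config.carrier,
    )

    if config.arm_side == "left":
        mask, neutral = config.mirror.as_arrays()
        recorded = intrinsic.copy()
        recorded[:, mask] = 2.0 * neutral[mask] - recorded[:, mask]
    else:
        recorded = intrinsic
    kin = KinematicRecording(samples=recorded, dof_names=DOF_NAMES, arm_side=config.arm_side)

    return SessionDataset(
        emg=emg,
        kin=kin,
        trials=trials,
        subject_id=config.subject_id,
        session_id=config.session_id,
        arm_side=config.arm_side,
        condition=config.condition,
    )


def perturb_session(
    session: SessionDataset,
    gain_sigma: float = 0.05,
    rotation_deg: float = 5.0,
    seed: int = 0,
) -> SessionDataset:
    """Emulate a new recording day: channel gain jitter + channel-space rotation.

    Gains are ``exp(N(0, σ_g))`` per channel; the rotation composes Givens
    rotations of the given angle between adjacent channel pairs, modeling
    each shifted electrode picking up a mixture of neighboring sources.
    With ``gain_sigma = 0`` and ``rotation_deg = 0`` the session is returned
    unchanged (bit-identical samples).
    """
    emg = session.emg.samples
    n_ch = emg.shape[1]
    if gain_sigma > 0:
        rng = np.random.default_rng(seed)
        gains = np.exp(rng.normal(0.0, gain_sigma, size=n_ch))
        emg = emg * gains
    if rotation_deg != 0:
        emg = emg @ _channel_rotation(n_ch, rotation_deg).T

    return SessionDataset(
        emg=session.emg.copy_with(samples=np.ascontiguousarray(emg)),
        kin=session.kin.copy_with(samples=session.kin.samples.copy()),
        trials=list(session.trials),
        subject_id=session.subject_id,
        session_id=session.session_id + "_perturbed",
        arm_side=session.arm_side,
        condition=session.condition,
    )
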