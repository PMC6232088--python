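"""Signal conditioning ahead of feature extraction.

EMG is band-pass filtered (default 10-500 Hz) and power-line notch filtered
(default 50 Hz); kinematics are low-pass filtered at 1.5 Hz.  Filters are
4th-order Butterworth (2nd-order IIR for the notch), applied forward-backward
by default: the stored stream is conditioned zero-phase, which a
pseudo-online replay tolerates because conditioning happens before the causal
stages.  A strictly causal single-pass variant is available via
``zero_phase=False`` for strict-causality experiments.

For 1000 Hz patient recordings the nominal 500 Hz band edge sits exactly at
Nyquist; :func:`effective_band` clips the upper edge to ``0.45 * rate``.

High-density monopolar grids are reduced to bipolar derivations by
:func:`bipolarize_grid` (default: vertical-adjacent differences along the
fiber direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_data import EMGRecording, KinematicRecording, ValidationError

__all__ = [
    "FilterSpec",
    "effective_band",
    "bandpass_emg",
    "notch_emg",
    "lowpass_kinematics",
    "bipolarize_grid",
]


@dataclass(frozen=True)
class FilterSpec:
    """A serializable filter description (kind, band edges, order, phase)."""

    kind: str                  # bandpass | notch | lowpass
    edges_hz: tuple[float, ...]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if self.kind not in ("bandpass", "notch", "lowpass"):
            raise ValidationError(f"filter.kind: {self.kind!r}")
        if any(e <= 0 for e in self.edges_hz):
            raise ValidationError(f"filter.edges_hz: edges must be positive, got {self.edges_hz}")


def effective_band(low_hz: float, high_hz: float, rate_hz: float) -> tuple[float, float]:
    """Clip the band-pass upper edge to 0.45 x rate when it reaches Nyquist."""
    high = min(high_hz, 0.45 * rate_hz)
    if not (0 < low_hz < high < rate_hz / 2):
        raise ValidationError(
            f"band edges ({low_hz}, {high_hz}) invalid for rate {rate_hz} Hz "
            f"(clipped high edge {high})"
        )
    return low_hz, high


def _apply_sos(x: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def bandpass_emg(
    emg: EMGRecording,
    low_hz: float = 10.0,
    high_hz: float = 500.0,
    order: int = 4,
    zero_phase: bool = True,
) -> EMGRecording:
    """Band-pass filter every channel; shape and rate are preserved."""
    low, high = effective_band(low_hz, high_hz, emg.rate_hz)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=emg.rate_hz, output="sos")
    return emg.copy_with(samples=_apply_sos(emg.samples, sos, zero_phase))


def notch_emg(
    emg: EMGRecording,
    notch_hz: float = 50.0,
    quality: float = 30.0,
    zero_phase: bool = True,
) -> EMGRecording:
    """Power-line notch filter (IIR, Q=30 by default)."""
    if not notch_hz < emg.rate_hz / 2:
        raise ValidationError(f"notch frequency {notch_hz} >= Nyquist ({emg.rate_hz / 2})")
    b, a = signal.iirnotch(notch_hz, quality, fs=emg.rate_hz)
    sos = signal.tf2sos(b, a)
    return emg.copy_with(samples=_apply_sos(emg.samples, sos, zero_phase))


def lowpass_kinematics(
    kin: KinematicRecording,
    cutoff_hz: float = 1.5,
    order: int = 4,
    zero_phase: bool = True,
) -> KinematicRecording:
    """Low-pass filter the 18 Hz trajectories (default 1.5 Hz cutoff)."""
    if not cutoff_hz < kin.rate_hz / 2:
        raise ValidationError(f"kin low-pass cutoff {cutoff_hz} >= Nyquist ({kin.rate_hz / 2})")
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=kin.rate_hz, output="sos")
    return kin.copy_with(samples=_apply_sos(kin.samples, sos, zero_phase))


def bipolarize_grid(emg: EMGRecording, scheme: str = "vertical") -> EMGRecording:
    """Derive bipolar channels from monopolar grid arrays.

    The recording's channels are interpreted as one or more row-major
    ``rows x cols`` arrays (per ``emg.grid_shape``).  ``scheme='vertical'``
    differences vertically adjacent electrodes (along the fiber direction),
    yielding ``(rows-1) * cols`` channels per array; ``'horizontal'``
    differences horizontally adjacent ones, ``rows * (cols-1)`` per array.
    Output channel names encode the electrode pair.  Any signal component
    common to both electrodes of a pair cancels exactly.
    """
    if emg.channel_kind != "monopolar-grid":
        raise ValidationError("bipolarize_grid: recording is not monopolar-grid")
    if scheme not in ("vertical", "horizontal"):
        raise ValidationError(f"bipolarize_grid: unknown scheme {scheme!r}")
    rows, cols = emg.grid_shape
    per_array = rows * cols
    n_arrays = emg.n_channels // per_array

    out_cols: list[np.ndarray] = []
    names: list[str] = []
    for a in range(n_arrays):
        block = emg.samples[:, a * per_array:(a + 1) * per_array]
        for r in range(rows):
            for c in range(cols):
                if scheme == "vertical":
                    if r + 1 >= rows:
                        continue
                    i, j = r * cols + c, (r + 1) * cols + c
                    names.append(f"g{a}_r{r}c{c}-r{r + 1}c{c}")
                else:
                    if c + 1 >= cols:
                        continue
                    i, j = r * cols + c, r * cols + (c + 1)
                    names.append(f"g{a}_r{r}c{c}-r{r}c{c + 1}")
                out_cols.append(block[:, i] - block[:, j])
    return EMGRecording(
        samples=np.column_stack(out_cols),
        rate_hz=emg.rate_hz,
        channel_names=tuple(names),
        channel_kind="bipolar",
        start_time_s=emg.start_time_s,
    )
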