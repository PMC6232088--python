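"""Shared fixtures: small deterministic synthetic sessions.

Sessions are generated once per test run (module-scoped where heavier) so
the suite stays fast; everything derives from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirrormyo.core_data import (
    EMGRecording,
    KinematicRecording,
    SessionDataset,
    Trial,
)
from mirrormyo.synthetic import SynthConfig, generate_session


@pytest.fixture(scope="session")
def tiny_session() -> SessionDataset:
    """Small noisy session: one T1 + one T2 trial, ~16 s, 2500 Hz EMG."""
    return generate_session(
        SynthConfig(n_trials_per_task=1, tasks=("T1", "T2"), seed=7, session_id="tiny")
    )


@pytest.fixture(scope="session")
def study_session() -> SessionDataset:
    """Session with all four tasks, two trials each (WS-capable)."""
    return generate_session(
        SynthConfig(n_trials_per_task=2, tasks=("T1", "T2", "T3", "T4"), seed=11)
    )


@pytest.fixture()
def handmade_session() -> SessionDataset:
    """A fully hand-built 2-channel, 2-second session for I/O tests."""
    rng = np.random.default_rng(123)
    emg = EMGRecording(
        samples=rng.standard_normal((5000, 2)),
        rate_hz=2500.0,
        channel_names=("biceps", "triceps"),
    )
    kin = KinematicRecording(samples=rng.standard_normal((36, 7)), arm_side="left")
    return SessionDataset(
        emg=emg,
        kin=kin,
        trials=[Trial("T1", 0, 18), Trial("T2", 20, 30)],
        subject_id="H1",
        session_id="hand",
        arm_side="left",
        condition="compliant",
    )
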