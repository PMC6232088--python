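"""Desk-scale study harness: paired synthetic sessions and scheme sweeps.

Builds the session constellation the transfer analyses need — a calibration
session, a second same-arm session on a "new day" (perturbed electrodes),
and an other-arm session sharing the synergy structure — and runs the five
decoding schemes on it.  Used by the CLI demo, the test suite, and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_data import MirrorSpec, PipelineConfig, SessionDataset
from .schemes_eval import (
    PerformanceReport,
    run_mirror,
    run_recalibrated,
    run_session_to_session,
    run_within_session,
    run_within_vs_session_transfer,
)
from .synthetic import SynthConfig, generate_session

__all__ = [
    "StudySessions",
    "build_study_sessions",
    "run_scheme_suite",
    "noise_free_linear_config",
    "recovery_config",
    "scheme_ordering_experiment",
    "mirror_premise_experiment",
    "paretic_sweep",
]


@dataclass
class StudySessions:
    """The minimal session constellation for transfer analyses."""

    calib: SessionDataset        # day 1, arm A
    retest: SessionDataset       # day 2, arm A, perturbed electrodes
    other_arm: SessionDataset    # day 3, arm B, shared synergy structure
    mirror: MirrorSpec


def build_study_sessions(
    seed: int,
    base: SynthConfig | None = None,
    gain_sigma: float = 0.1,
    rotation_deg: float = 25.0,
    include_fm: bool = True,
    paretic_gamma: float = 0.0,
) -> StudySessions:
    """Generate the calibration / new-day / other-arm session triple.

    The new-day session uses fresh trial and carrier realizations plus an
    electrode-shift perturbation of the loading matrix (rotation mixes the
    muscle sources each channel senses; gain jitter rescales channels); the
    other-arm session shares the synergy matrix (the mirror premise) and
    optionally a paretic corruption weight γ.  All randomness derives from
    ``seed``.
    """
    # interleaved task order: desk-scale sessions lose their first minute to
    # normalization warm-up, and interleaving keeps every task represented
    # in the remaining stream (a blocked session would lose whole tasks)
    cfg = base or SynthConfig(n_trials_per_task=4, trial_order="interleaved")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31 - 1, size=4)
    tasks = cfg.tasks + (("FM",) if include_fm and "FM" not in cfg.tasks else ())

    calib = generate_session(
        replace(cfg, seed=int(seeds[0]), tasks=tasks, session_id="S1", arm_side="right")
    )
    retest = generate_session(
        replace(
            cfg,
            seed=int(seeds[1]),
            tasks=tasks,
            session_id="S2",
            arm_side="right",
            loading_rotation_deg=rotation_deg,
            gain_jitter_sigma=gain_sigma,
        )
    )
    other = generate_session(
        replace(
            cfg,
            seed=int(seeds[3]),
            tasks=tasks,
            session_id="S3",
            arm_side="left",
            paretic_gamma=paretic_gamma,
        )
    )
    return StudySessions(calib=calib, retest=retest, other_arm=other, mirror=cfg.mirror)


def noise_free_linear_config(seed: int, n_trials_per_task: int = 5) -> SynthConfig:
    """The noise-free exactly-linear verification condition.

    Deterministic tone carriers (features are noise-free functions of the
    envelopes), no sensor noise, purely posture-driven envelopes (linear in
    the recorded kinematics), the compliant protocol's constant trial
    prototypes, and interleaved task order so the trailing normalization
    window sees a stationary task mix.
    """
    return SynthConfig(
        n_trials_per_task=n_trials_per_task,
        tasks=("T1", "T2", "T3", "T4"),
        snr_db=None,
        velocity_weight=0.0,
        carrier="tone",
        condition="compliant",
        trial_order="interleaved",
        seed=seed,
    )


def recovery_config(seed: int, n_trials_per_task: int = 5) -> SynthConfig:
    """The noisy recovery condition: realistic carriers at 20 dB SNR,
    velocity-weighted drive, same protocol as the noise-free condition."""
    return SynthConfig(
        n_trials_per_task=n_trials_per_task,
        tasks=("T1", "T2", "T3", "T4"),
        snr_db=20.0,
        condition="compliant",
        trial_order="interleaved",
        seed=seed,
    )


def run_scheme_suite(
    sessions: StudySessions,
    config: PipelineConfig | None = None,
    recalib_minutes: float = 2.0,
    ws_folds: int = 5,
) -> dict[str, PerformanceReport]:
    """Run WS, SS, RSS, TSAA, GAA (plus FM generalization runs) on a triple.

    WS appears twice, as in the study design: WS1 cross-validates the
    calibration session and WS2 the new-day session — WS2 shares its test
    session with SS/RSS, making those comparisons stream-matched.  The
    within-session and transfer schemes cover the cued tasks; free movement
    is reserved for the generalization runs.
    """
    cued = ("T1", "T2", "T3", "T4")
    cfg = config or PipelineConfig()
    out: dict[str, PerformanceReport] = {}
    out["WS"] = run_within_session(sessions.calib, cfg, folds=ws_folds, tasks=cued)
    out["WS2"], out["SS_folds"] = run_within_vs_session_transfer(
        sessions.calib, sessions.retest, cfg, folds=ws_folds, tasks=cued
    )
    out["SS"] = run_session_to_session(
        sessions.calib, sessions.retest, cfg, calib_tasks=cued
    )
    out["RSS"] = run_recalibrated(
        sessions.calib, sessions.retest, cfg, minutes=recalib_minutes, calib_tasks=cued
    )
    # SS restricted to the frames RSS is tested on, so the two transfer
    # schemes face identical streams in paired comparisons
    out["SS_matched"] = run_session_to_session(
        sessions.calib,
        sessions.retest,
        cfg,
        skip_test_minutes=recalib_minutes,
        calib_tasks=cued,
    )
    out["TSAA"] = run_mirror(
        sessions.calib, sessions.other_arm, task_specific=True, mirror=sessions.mirror, config=cfg
    )
    out["GAA"] = run_mirror(
        sessions.calib, sessions.other_arm, task_specific=False, mirror=sessions.mirror, config=cfg
    )
    if any(t.task_id == "FM" for t in sessions.other_arm.trials):
        out["TSAA_FM"] = run_mirror(
            sessions.calib,
            sessions.other_arm,
            task_specific=True,
            mirror=sessions.mirror,
            config=cfg,
            test_tasks=("FM",),
        )
        out["GAA_FM"] = run_mirror(
            sessions.calib,
            sessions.other_arm,
            task_specific=False,
            mirror=sessions.mirror,
            config=cfg,
            test_tasks=("FM",),
        )
    return out


def scheme_ordering_experiment(
    seeds,
    config: PipelineConfig | None = None,
    rotation_deg: float = 25.0,
    gain_sigma: float = 0.1,
    recalib_minutes: float = 2.0,
) -> pd.DataFrame:
    """Per-seed scheme metrics for the transfer-structure analysis.

    Runs the full suite on paired session triples for each seed and
    tabulates the mean CC (and, for the free-movement generalization pair,
    mean NRMSE) of every scheme.  SS appears twice: the full-stream run and
    the stream-matched run that faces exactly the frames RSS is tested on.
    """
    rows = []
    for seed in seeds:
        sessions = build_study_sessions(
            int(seed), gain_sigma=gain_sigma, rotation_deg=rotation_deg
        )
        out = run_scheme_suite(sessions, config, recalib_minutes=recalib_minutes)
        cued = ("T1", "T2", "T3", "T4")
        rows.append(
            {
                "seed": int(seed),
                "ws1_cc": out["WS"].mean_cc(),
                "ws2_cc": out["WS2"].mean_cc(),
                "ss_folds_cc": out["SS_folds"].mean_cc(),
                "ss_cc": out["SS"].mean_cc(tasks=cued),
                "ss_matched_cc": out["SS_matched"].mean_cc(tasks=cued),
                "rss_cc": out["RSS"].mean_cc(tasks=cued),
                "tsaa_cc": out["TSAA"].mean_cc(),
                "gaa_cc": out["GAA"].mean_cc(),
                "tsaa_fm_nrmse": out["TSAA_FM"].mean_nrmse(),
                "gaa_fm_nrmse": out["GAA_FM"].mean_nrmse(),
                "tsaa_fm_cc": out["TSAA_FM"].mean_cc(),
                "gaa_fm_cc": out["GAA_FM"].mean_cc(),
            }
        )
    return pd.DataFrame(rows).set_index("seed")


def mirror_premise_experiment(
    seeds, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Same-arm SS vs arm-to-arm GAA under identical synergy structure.

    No new-day perturbation and exact sign mirroring; both schemes are
    scored on the matched per-task (T1-T4) rows so stream composition does
    not bias the comparison.
    """
    tasks = ("T1", "T2", "T3", "T4")
    rows = []
    for seed in seeds:
        sessions = build_study_sessions(int(seed), gain_sigma=0.0, rotation_deg=0.0)
        cfg = config or PipelineConfig()
        ss = run_session_to_session(sessions.calib, sessions.retest, cfg)
        gaa = run_mirror(
            sessions.calib,
            sessions.other_arm,
            task_specific=False,
            mirror=sessions.mirror,
            config=cfg,
        )
        rows.append(
            {
                "seed": int(seed),
                "ss_task_cc": ss.mean_cc(tasks=tasks),
                "gaa_task_cc": gaa.mean_cc(tasks=tasks),
            }
        )
    return pd.DataFrame(rows).set_index("seed")


def paretic_sweep(
    seeds,
    gammas=(0.0, 0.5, 1.0),
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """GAA performance vs the paretic synergy-corruption weight γ.

    Seeds are paired across γ: the corrupted arm's kinematics and carrier
    realizations are identical within a seed, only the effective loading
    matrix changes.
    """
    rows = []
    for seed in seeds:
        for gamma in gammas:
            sessions = build_study_sessions(
                int(seed), gain_sigma=0.0, rotation_deg=0.0, paretic_gamma=float(gamma)
            )
            rep = run_mirror(
                sessions.calib,
                sessions.other_arm,
                task_specific=False,
                mirror=sessions.mirror,
                config=config,
            )
            rows.append({"seed": int(seed), "gamma": float(gamma), "gaa_cc": rep.mean_cc()})
    return pd.DataFrame(rows)
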