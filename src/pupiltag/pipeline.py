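"""End-to-end drivers: simulate, clean, chunk and decode whole sessions."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cycles import CycleRecord, extract_cycles
from .decoding import decode_session
from .io import (
    CONDITION_PHASE_DIFF,
    PerceptTimeline,
    PreprocessParams,
    PupilTrace,
    RunConfig,
    StimulusSchedule,
)
from .preprocessing import CleaningReport, preprocess
from .synthetic import SimulationParams, simulate_block

__all__ = [
    "analyze_block",
    "schedule_for_condition",
    "simulate_session_cycles",
    "run_synthetic_study",
]


def analyze_block(
    raw: PupilTrace,
    reported: PerceptTimeline,
    schedule: StimulusSchedule,
    pre_params: PreprocessParams | None = None,
) -> tuple[list[CycleRecord], CleaningReport]:
    """Clean one raw block and extract its labelled per-cycle Z values."""
    clean, report = preprocess(raw, pre_params)
    return extract_cycles(clean, reported, schedule), report


def schedule_for_condition(
    base: StimulusSchedule, condition: str, eye_assignment: str = "face_left"
) -> StimulusSchedule:
    """Specialize a base schedule to one named condition."""
    return dataclasses.replace(
        base,
        condition=condition,
        phase_diff_deg=CONDITION_PHASE_DIFF[condition],
        eye_assignment=eye_assignment,
        attend_first="face" if condition.endswith("attend") else None,
    )


def simulate_session_cycles(
    n_subjects: int,
    conditions: list[str],
    params: SimulationParams,
    base_schedule: StimulusSchedule | None = None,
    seed: int = 0,
    pre_params: PreprocessParams | None = None,
) -> dict[tuple[str, str], list[CycleRecord]]:
    """Simulate one block per subject and condition and run the full
    cleaning + per-cycle analysis on each.

    Every block draws from an RNG substream keyed by (seed, subject,
    condition), so subjects are independent and the whole session is
    reproducible from ``seed``.
    """
    base = base_schedule or StimulusSchedule()
    cycles: dict[tuple[str, str], list[CycleRecord]] = {}
    for s in range(n_subjects):
        for ci, cond in enumerate(conditions):
            sched = schedule_for_condition(
                base, cond, "face_left" if (s + ci) % 2 == 0 else "house_left"
            )
            rng = np.random.default_rng([seed, s, ci])
            trace, reported, _, _ = simulate_block(params, sched, rng)
            recs, _ = analyze_block(trace, reported, sched, pre_params)
            cycles[(f"S{s + 1:02d}", cond)] = recs
    return cycles


def run_synthetic_study(
    config: RunConfig,
    conditions: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-subject study and decode it.

    Returns the per-subject and per-condition decoding tables (see
    :func:`pupiltag.decoding.decode_session`).
    """
    conditions = conditions or ["mod180_naive", "mod90_naive", "mod0_control"]
    cycles = simulate_session_cycles(
        config.n_subjects,
        conditions,
        config.simulation,
        config.schedule,
        seed=config.seed,
        pre_params=config.preprocess,
    )
    return decode_session(cycles, config.analysis.rotation_step_deg)
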