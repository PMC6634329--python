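"""Per-cycle F1 extraction: chunk a standardized trace into presentation
cycles, label each with the exclusively reported percept, and compute the
complex component of the pupil signal at the modulation frequency.

A presentation cycle is one period of the luminance modulation
(1/1.7 Hz = 588 ms at the design frequency), aligned so each window
contains one full period of the left-eye modulation sinusoid starting at
phase -90 deg.  The sample count per cycle is fixed at
``N = round(sample_rate / freq)`` while window onsets are re-anchored by
rounding the exact boundary ``k / freq`` per cycle, so the fractional
period (1000/1.7 = 588.235 samples) never accumulates into drift: the
alignment error is at most half a sample for every cycle.

The F1 component Z of a cycle ``x`` is defined by

    Re(Z) = (2/N) sum_n x_n cos(2 pi n / N)      (cosinusoidal content)
    Im(Z) = (2/N) sum_n x_n sin(2 pi n / N)      (sinusoidal content)

so a unit sine in reference phase gives Z = i and a unit cosine gives
Z = 1.  Im(Z) > 0 therefore means "in phase with the left-eye reference
sinusoid".  This equals the conjugated bin-1 coefficient of the cycle's
FFT scaled by 2/N, which is how it is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    EXCLUSIVE_LABELS,
    PerceptTimeline,
    PupilTrace,
    StimulusSchedule,
)

__all__ = [
    "EXCLUDED",
    "CycleRecord",
    "segment_cycles",
    "label_cycles",
    "f1_component",
    "extract_cycles",
    "cycles_to_frame",
]

EXCLUDED = "EXCLUDED"


@dataclass
class CycleRecord:
    """One presentation cycle of one block."""

    index: int  # cycle number from block start
    onset_ms: float
    offset_ms: float
    label: str  # LEFT_EYE / RIGHT_EYE / EXCLUDED
    z: complex  # complex F1 component, z-units
    frac_interpolated: float  # fraction of window samples that were filled


def segment_cycles(
    trace: PupilTrace, schedule: StimulusSchedule
) -> list[tuple[int, int]]:
    """Cycle windows as half-open sample-index spans ``[i, i + N)``.

    Cycle ``k`` starts at sample ``round(k * sample_rate / freq)`` and runs
    for ``N = round(sample_rate / freq)`` samples; a trailing partial cycle
    is dropped.
    """
    n = len(trace)
    samples_per_cycle = trace.sample_rate / schedule.freq
    N = int(round(samples_per_cycle))
    if n < N:
        raise ValueError(
            f"trace of {n} samples is shorter than one {N}-sample cycle"
        )
    windows = []
    k = 0
    while True:
        i = int(round(k * samples_per_cycle))
        if i + N > n:
            break
        windows.append((i, i + N))
        k += 1
    return windows


def label_cycles(
    windows: list[tuple[int, int]],
    timeline: PerceptTimeline,
    sample_rate: float = 1000.0,
) -> list[str]:
    """Exclusive-dominance label per cycle window.

    A cycle is LEFT_EYE (resp. RIGHT_EYE) iff a single exclusive interval
    of that label covers the entire window; any cycle touched by a switch,
    a mixed percept or an unreported stretch is EXCLUDED.
    """
    ms = 1000.0 / sample_rate
    labels = []
    for i, j in windows:
        lab = timeline.covering_label(i * ms, j * ms)
        labels.append(lab if lab in EXCLUSIVE_LABELS else EXCLUDED)
    return labels


def f1_component(x: np.ndarray) -> complex:
    """Complex F1 component of one cycle (sine/cosine convention above)."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    if N < 8:
        raise ValueError("cycle must contain at least 8 samples")
    if np.any(np.isnan(x)):
        raise ValueError("cycle contains NaN samples")
    return complex(2.0 / N * np.conj(np.fft.fft(x)[1]))


def extract_cycles(
    trace: PupilTrace,
    timeline: PerceptTimeline,
    schedule: StimulusSchedule,
) -> list[CycleRecord]:
    """Segment, label and Fourier-analyze one standardized block.

    EXCLUDED cycles keep their Z for diagnostics; statistics downstream use
    only the exclusively labelled ones.
    """
    if not trace.standardized:
        raise ValueError("extract_cycles expects a z-standardized trace")
    windows = segment_cycles(trace, schedule)
    labels = label_cycles(windows, timeline, trace.sample_rate)
    ms = 1000.0 / trace.sample_rate
    records = []
    for k, ((i, j), lab) in enumerate(zip(windows, labels)):
        z = f1_component(trace.pupil[i:j])
        frac = float((~trace.valid[i:j]).mean())
        records.append(
            CycleRecord(
                index=k,
                onset_ms=i * ms,
                offset_ms=j * ms,
                label=lab,
                z=z,
                frac_interpolated=frac,
            )
        )
    return records


def cycles_to_frame(records: list[CycleRecord]) -> pd.DataFrame:
    """Tabular view (index, onset_ms, label, re_z, im_z, frac_interpolated)."""
    return pd.DataFrame(
        {
            "index": [r.index for r in records],
            "onset_ms": [r.onset_ms for r in records],
            "label": [r.label for r in records],
            "re_z": [r.z.real for r in records],
            "im_z": [r.z.imag for r in records],
            "frac_interpolated": [r.frac_interpolated for r in records],
        }
    )
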