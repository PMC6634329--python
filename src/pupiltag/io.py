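"""Tabular data formats and run configuration.

Pupil samples and percept reports travel as plain TSV so every stage of the
pipeline can be inspected with a text editor.  Three containers are defined
here and shared by all other modules:

``PupilTrace``
    A uniformly sampled pupil-size time series for one block, with a
    per-sample validity mask (``False`` marks blink / artifact / removed
    samples) and an optional blink flag recording which invalid samples
    originate from a detected blink.

``PerceptTimeline``
    An ordered, non-overlapping partition of the block into intervals
    labelled ``LEFT_EYE`` / ``RIGHT_EYE`` / ``MIXED`` / ``NONE``.  Labels
    refer to the *eye* whose image is reported dominant; the eye-to-image
    assignment lives in the stimulus schedule.

``StimulusSchedule``
    The dichoptic luminance-modulation design of one block: modulation
    frequency, per-eye phases, display gamma, modulation bounds.

Time is integer milliseconds from block onset; intervals are half-open
``[onset, offset)`` so boundary samples are never double-counted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LEFT_EYE",
    "RIGHT_EYE",
    "MIXED",
    "NONE",
    "PERCEPT_LABELS",
    "EXCLUSIVE_LABELS",
    "FormatError",
    "PupilTrace",
    "PerceptTimeline",
    "StimulusSchedule",
    "RunConfig",
    "read_pupil_trace",
    "write_pupil_trace",
    "read_percept_events",
    "write_percept_timeline",
    "load_config",
    "dump_config",
]

LEFT_EYE = "LEFT_EYE"
RIGHT_EYE = "RIGHT_EYE"
MIXED = "MIXED"
NONE = "NONE"
PERCEPT_LABELS = (LEFT_EYE, RIGHT_EYE, MIXED, NONE)
EXCLUSIVE_LABELS = (LEFT_EYE, RIGHT_EYE)

CONDITIONS = (
    "static",
    "mod180_naive",
    "mod90_naive",
    "mod0_control",
    "mod180_attend",
    "mod90_attend",
)

#: phase offset (right minus left, degrees) implied by each condition
CONDITION_PHASE_DIFF = {
    "static": 0.0,
    "mod0_control": 0.0,
    "mod90_naive": 90.0,
    "mod90_attend": 90.0,
    "mod180_naive": 180.0,
    "mod180_attend": 180.0,
}


class FormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PupilTrace:
    """Uniformly sampled pupil-size series for one block.

    Parameters
    ----------
    times
        Sample times in ms from block onset, strictly increasing with a
        constant step of ``1000 / sample_rate``.
    pupil
        Pupil size per sample: arbitrary units raw, z-units once
        ``standardized`` is set.
    valid
        Per-sample mask; ``False`` marks blink/artifact/removed samples.
    blink
        Subset of ``~valid`` that originates from a detected blink (drives
        the blink-padding rule).  Optional; defaults to all-``False``.
    """

    times: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    sample_rate: float = 1000.0
    block_id: str = "block"
    standardized: bool = False
    blink: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.blink is None:
            self.blink = np.zeros(self.times.shape, dtype=bool)
        else:
            self.blink = np.asarray(self.blink, dtype=bool)
        n = len(self.times)
        if len(self.pupil) != n or len(self.valid) != n or len(self.blink) != n:
            raise FormatError("times, pupil, valid and blink must share one length")
        if n >= 2:
            step = 1000.0 / self.sample_rate
            d = np.diff(self.times)
            bad = np.nonzero(~np.isclose(d, step, rtol=0.0, atol=1e-6))[0]
            if bad.size:
                i = int(bad[0])
                raise FormatError(
                    f"non-uniform sampling at row {i + 1}: step {d[i]:g} ms, "
                    f"expected {step:g} ms"
                )
        if self.standardized and n:
            m = float(np.mean(self.pupil))
            s = float(np.std(self.pupil))
            if abs(m) > 1e-6 or abs(s - 1.0) > 1e-6:
                raise FormatError(
                    f"standardized trace has mean {m:g}, SD {s:g}"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_ms(self) -> float:
        return len(self) * 1000.0 / self.sample_rate

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            times=self.times.copy(),
            pupil=self.pupil.copy(),
            valid=self.valid.copy(),
            sample_rate=self.sample_rate,
            block_id=self.block_id,
            standardized=self.standardized,
            blink=self.blink.copy(),
        )


@dataclass
class PerceptTimeline:
    """Partition of a block into percept-report intervals.

    ``intervals`` is an ordered list of ``(onset_ms, offset_ms, label)``
    tuples with half-open extent, non-overlapping and jointly covering
    ``[0, block_duration_ms)``.
    """

    intervals: list[tuple[float, float, str]]
    block_id: str = "block"

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b), str(lab)) for a, b, lab in self.intervals]
        ivs.sort(key=lambda iv: iv[0])
        prev_end = None
        for a, b, lab in ivs:
            if lab not in PERCEPT_LABELS:
                raise FormatError(f"unknown percept label {lab!r}")
            if not a < b:
                raise FormatError(f"empty or inverted interval ({a}, {b})")
            if prev_end is not None and a < prev_end - 1e-9:
                raise FormatError(f"overlapping intervals at {a} ms")
            prev_end = b
        self.intervals = ivs

    @property
    def duration_ms(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def label_at(self, t_ms: float) -> str:
        """Label of the interval containing time ``t_ms`` (NONE outside)."""
        for a, b, lab in self.intervals:
            if a <= t_ms < b:
                return lab
        return NONE

    def covering_label(self, onset_ms: float, offset_ms: float) -> str | None:
        """Common label of the intervals covering ``[onset, offset)``.

        Returns the label if intervals sharing one label jointly cover the
        whole window (equivalently: every sample in the window has that
        label), else ``None``.
        """
        labels = set()
        covered = 0.0
        for a, b, lab in self.intervals:
            lo, hi = max(a, onset_ms), min(b, offset_ms)
            if hi <= lo:
                continue
            labels.add(lab)
            covered += hi - lo
        if len(labels) == 1 and abs(covered - (offset_ms - onset_ms)) < 1e-9:
            return labels.pop()
        return None

    def durations(self, label: str) -> np.ndarray:
        """Durations (ms) of all intervals with the given label."""
        return np.array([b - a for a, b, lab in self.intervals if lab == label])

    def shifted(self, lag_ms: float, block_duration_ms: float) -> "PerceptTimeline":
        """Timeline delayed by ``lag_ms`` and truncated to the block.

        The first ``lag_ms`` of the block, for which no shifted report
        exists, is filled with ``NONE``.
        """
        out: list[tuple[float, float, str]] = []
        if lag_ms > 0:
            out.append((0.0, min(lag_ms, block_duration_ms), NONE))
        for a, b, lab in self.intervals:
            a2, b2 = a + lag_ms, b + lag_ms
            if a2 >= block_duration_ms:
                break
            out.append((max(a2, 0.0), min(b2, block_duration_ms), lab))
        return PerceptTimeline(_merge_adjacent(out), block_id=self.block_id)


def _merge_adjacent(
    intervals: Iterable[tuple[float, float, str]]
) -> list[tuple[float, float, str]]:
    out: list[tuple[float, float, str]] = []
    for a, b, lab in intervals:
        if b - a <= 0:
            continue
        if out and out[-1][2] == lab and math.isclose(out[-1][1], a):
            out[-1] = (out[-1][0], b, lab)
        else:
            out.append((a, b, lab))
    return out


@dataclass
class StimulusSchedule:
    """Dichoptic sinusoidal luminance-modulation design for one block.

    The left-eye modulation is the phase reference: with the default
    ``phase_left_deg = -90`` the left-eye luminance starts each analysis
    cycle at its minimum, i.e. the cycle window contains one full period of
    a sine starting at -90 deg.  The right eye is shifted by
    ``phase_diff_deg`` (0, 90 or 180 in the experimental design, with the
    left eye leading).
    """

    freq: float = 1.7
    phase_left_deg: float = -90.0
    phase_diff_deg: float = 180.0
    gamma: float = 2.26
    lum_lo: float = 0.5
    lum_hi: float = 1.0
    refresh_hz: float = 85.0
    block_duration_s: float = 300.0
    condition: str = "mod180_naive"
    eye_assignment: str = "face_left"  # which image sits in which eye
    attend_first: str | None = None  # "face"/"house" for attention blocks
    attend_interval_s: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lum_lo < self.lum_hi <= 1.0):
            raise ValueError("require 0 <= lum_lo < lum_hi <= 1")
        if self.gamma <= 0 or self.freq <= 0 or self.refresh_hz <= 0:
            raise ValueError("gamma, freq and refresh_hz must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.eye_assignment not in ("face_left", "house_left"):
            raise ValueError("eye_assignment must be 'face_left' or 'house_left'")

    @property
    def frames_per_cycle(self) -> float:
        """Display frames per modulation cycle (50 for 85 Hz / 1.7 Hz)."""
        return self.refresh_hz / self.freq

    @property
    def cycle_ms(self) -> float:
        return 1000.0 / self.freq

    @property
    def modulated(self) -> bool:
        return self.condition != "static"

    def image_in_eye(self, eye: str) -> str:
        """Which image ('face'/'house') is shown to 'left' or 'right'."""
        face_left = self.eye_assignment == "face_left"
        if eye == "left":
            return "face" if face_left else "house"
        if eye == "right":
            return "house" if face_left else "face"
        raise ValueError(f"unknown eye {eye!r}")

    def eye_of_image(self, image: str) -> str:
        return "left" if self.image_in_eye("left") == image else "right"

    def attended_image(self, t_ms: float) -> str | None:
        """Image under attention instruction at time ``t_ms`` (None if naive)."""
        if self.attend_first is None:
            return None
        k = int(t_ms // (self.attend_interval_s * 1000.0))
        other = "house" if self.attend_first == "face" else "face"
        return self.attend_first if k % 2 == 0 else other


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class PreprocessParams:
    k_sd: float = 5.0  # change-rate rejection threshold, in SDs
    pad_ms: float = 50.0  # removed before and after each blink
    min_rate_run_ms: float = 10.0  # rate-rejection runs >= this are padded too
    sd_exclude_blink_ms: float = 50.0  # blink neighborhood kept out of the SD
    interp: str = "cubic"

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.pad_ms < 0 or self.min_rate_run_ms < 0:
            raise ValueError("padding durations must be non-negative")
        if self.interp not in ("cubic", "linear"):
            raise ValueError("interp must be 'cubic' or 'linear'")


@dataclass
class AnalysisParams:
    rotation_step_deg: float = 1.0
    positive_class: str = RIGHT_EYE

    def __post_init__(self) -> None:
        if self.rotation_step_deg <= 0:
            raise ValueError("rotation_step_deg must be positive")
        if self.positive_class not in EXCLUSIVE_LABELS:
            raise ValueError("positive_class must be LEFT_EYE or RIGHT_EYE")


@dataclass
class RunConfig:
    """Full parameter set for a simulated or real analysis run."""

    schedule: StimulusSchedule = field(default_factory=StimulusSchedule)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    simulation: "object" = None  # SimulationParams; set lazily to avoid cycle
    seed: int = 0
    n_subjects: int = 12
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None:
            from .synthetic import SimulationParams

            self.simulation = SimulationParams()


def _nested_types() -> dict:
    from .synthetic import SimulationParams  # late import: synthetic imports io

    return {
        "schedule": StimulusSchedule,
        "preprocess": PreprocessParams,
        "analysis": AnalysisParams,
        "simulation": SimulationParams,
    }


def _from_mapping(cls, data: dict, path: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise FormatError(f"{path or 'config'}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    nested = _nested_types()
    kwargs = {}
    for key, val in data.items():
        if key not in names:
            raise FormatError(f"unknown config key {path + key!r}")
        if isinstance(val, dict) and key in nested:
            val = _from_mapping(nested[key], val, path + key + ".")
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path or 'config'}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) run configuration.

    Unknown keys are rejected with the offending key path; omitted keys take
    the design defaults (1.7 Hz modulation, gamma 2.26, 5-SD change-rate
    threshold, 50 ms blink padding, ...).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    return _from_mapping(RunConfig, doc, "")


def dump_config(config: RunConfig, path: str | Path) -> None:
    doc = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# pupil trace TSV
# ---------------------------------------------------------------------------

_PUPIL_FMT = "%.6f"


def write_pupil_trace(trace: PupilTrace, path: str | Path) -> None:
    """Write a trace as TSV (columns time_ms, pupil, blink, valid).

    Metadata (sample rate, block id, standardized flag) goes into a single
    ``#`` header comment so a round-trip preserves every field.  Floats are
    printed at fixed precision, making round-trips bit-stable at the printed
    precision.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# pupiltag trace sample_rate={trace.sample_rate:g} "
            f"block_id={trace.block_id} standardized={int(trace.standardized)}\n"
        )
        fh.write("time_ms\tpupil\tblink\tvalid\n")
        for t, p, bl, va in zip(trace.times, trace.pupil, trace.blink, trace.valid):
            cell = "" if np.isnan(p) else _PUPIL_FMT % p
            fh.write(f"{t:g}\t{cell}\t{int(bl)}\t{int(va)}\n")


def read_pupil_trace(path: str | Path, sample_rate: float = 1000.0) -> PupilTrace:
    """Read a pupil trace TSV/CSV.

    The minimal dialect has columns ``time_ms`` and ``pupil`` with an
    optional ``blink`` flag; empty/NaN pupil cells and blink-flagged samples
    become ``valid=False``.  Files written by :func:`write_pupil_trace`
    additionally carry an explicit ``valid`` column and a metadata comment,
    both honoured on read.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                meta[k] = v
    sep = "\t" if "\t" in _first_data_line(path) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if "time_ms" not in df.columns or "pupil" not in df.columns:
        raise FormatError(
            f"{path.name}: header must contain time_ms and pupil "
            f"(got {list(df.columns)})"
        )
    sr = float(meta.get("sample_rate", sample_rate))
    times = df["time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        row = int(np.nonzero(np.diff(times) <= 0)[0][0]) + 2
        raise FormatError(f"{path.name}: non-monotonic time at data row {row}")
    pupil = df["pupil"].to_numpy(dtype=float)
    blink = (
        df["blink"].fillna(0).to_numpy(dtype=float).astype(bool)
        if "blink" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    if "valid" in df.columns:
        valid = df["valid"].to_numpy(dtype=float).astype(bool)
    else:
        valid = ~blink
    valid &= ~np.isnan(pupil)
    return PupilTrace(
        times=times,
        pupil=pupil,
        valid=valid,
        sample_rate=sr,
        block_id=meta.get("block_id", path.stem),
        standardized=bool(int(meta.get("standardized", "0"))),
        blink=blink,
    )


def _first_data_line(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return line
    return ""


# ---------------------------------------------------------------------------
# percept events
# ---------------------------------------------------------------------------

_EVENTS = ("L_down", "L_up", "R_down", "R_up")


def read_percept_events(path: str | Path, block_duration_ms: float) -> PerceptTimeline:
    """Read percept reports as either intervals or raw button events.

    The dialect is auto-detected from the header: ``onset_ms, offset_ms,
    label`` (interval format) or ``time_ms, event`` with events in
    ``{L_down, L_up, R_down, R_up}``.  Event streams are converted by a
    button-state machine: exactly one button held maps to that eye's label,
    both held to MIXED, none to NONE.  At equal timestamps releases are
    processed before presses (so a clean switch never creates a zero-length
    MIXED interval).  The result always partitions ``[0, block_duration_ms)``;
    zero-length intervals are dropped.
    """
    path = Path(path)
    sep = "\t" if "\t" in _first_data_line(path) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = set(df.columns)
    if {"onset_ms", "offset_ms", "label"} <= cols:
        ivs = [
            (float(r.onset_ms), float(r.offset_ms), str(r.label))
            for r in df.itertuples()
        ]
        for a, b, lab in ivs:
            if a < 0:
                raise FormatError(f"{path.name}: negative onset {a}")
            if lab not in PERCEPT_LABELS:
                raise FormatError(f"{path.name}: unknown label {lab!r}")
        return PerceptTimeline(
            _fill_none(ivs, block_duration_ms), block_id=path.stem
        )
    if {"time_ms", "event"} <= cols:
        events = [(float(r.time_ms), str(r.event)) for r in df.itertuples()]
        return events_to_timeline(events, block_duration_ms, block_id=path.stem)
    raise FormatError(
        f"{path.name}: header must be (onset_ms, offset_ms, label) or "
        f"(time_ms, event)"
    )


def events_to_timeline(
    events: Sequence[tuple[float, str]],
    block_duration_ms: float,
    block_id: str = "block",
) -> PerceptTimeline:
    """Convert button press/release events into a percept timeline."""
    for t, ev in events:
        if t < 0:
            raise FormatError(f"negative event time {t}")
        if ev not in _EVENTS:
            raise FormatError(f"unknown event {ev!r}")
    # releases before presses at equal timestamps
    order = {"L_up": 0, "R_up": 0, "L_down": 1, "R_down": 1}
    evs = sorted(events, key=lambda e: (e[0], order[e[1]]))
    held = {"L": False, "R": False}

    def state_label() -> str:
        if held["L"] and held["R"]:
            return MIXED
        if held["L"]:
            return LEFT_EYE
        if held["R"]:
            return RIGHT_EYE
        return NONE

    out: list[tuple[float, float, str]] = []
    t_prev = 0.0
    for t, ev in evs:
        if t > block_duration_ms:
            break
        if t > t_prev:
            out.append((t_prev, t, state_label()))
            t_prev = t
        btn, act = ev.split("_")
        if act == "down":
            if held[btn]:
                raise FormatError(f"button {btn} pressed twice at {t} ms")
            held[btn] = True
        else:
            if not held[btn]:
                raise FormatError(f"button {btn} released while up at {t} ms")
            held[btn] = False
    if t_prev < block_duration_ms:
        out.append((t_prev, block_duration_ms, state_label()))
    return PerceptTimeline(_merge_adjacent(out), block_id=block_id)


def _fill_none(
    intervals: list[tuple[float, float, str]], block_duration_ms: float
) -> list[tuple[float, float, str]]:
    ivs = sorted((iv for iv in intervals if iv[1] > iv[0]), key=lambda iv: iv[0])
    out: list[tuple[float, float, str]] = []
    t = 0.0
    for a, b, lab in ivs:
        if a > t:
            out.append((t, a, NONE))
        out.append((a, min(b, block_duration_ms), lab))
        t = min(b, block_duration_ms)
        if t >= block_duration_ms:
            break
    if t < block_duration_ms:
        out.append((t, block_duration_ms, NONE))
    return _merge_adjacent(out)


def write_percept_timeline(timeline: PerceptTimeline, path: str | Path) -> None:
    """Write a timeline in the interval TSV dialect."""
    with open(path, "w") as fh:
        fh.write("onset_ms\toffset_ms\tlabel\n")
        for a, b, lab in timeline.intervals:
            fh.write(f"{a:g}\t{b:g}\t{lab}\n")
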