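"""Synthetic dichoptic rivalry sessions with known ground truth.

Emulates the luminance-modulation experiment the analysis is built for:
300 s blocks sampled at 1000 Hz, two images modulated sinusoidally at
1.7 Hz with a 0/90/180 degree inter-eye phase offset, stochastic
alternations of exclusive perceptual dominance separated by mixed-percept
interludes, and a pupil that tracks the *perceived* luminance — inverted
(dimmer stimulus, larger pupil), delayed, and weighted toward the dominant
eye's signal.  Slow drift, white measurement noise and blink artifacts are
added so the preprocessing stage has real work to do.

The generative model for the pupil is deliberately the simplest one
consistent with the analysis assumptions (phase-consistent linear
response):

    pupil(t) = baseline - gain * [ w_L(t) * L_left(t - delay)
                                 + w_R(t) * L_right(t - delay) ]
               + drift(t) + noise(t)

where during exclusive dominance the dominant eye carries weight ``w_dom``
and the suppressed eye ``1 - w_dom``, and both weights are 0.5 during
mixed/none periods.  With noise off this reproduces the two-source mixture
amplitude |w + (1-w) e^{i dphi}| exactly (see ``decoding.mixture_amplitude``).

Dominance durations follow a gamma law — the standard description of
rivalry phase durations — calibrated by its median (default 2.7 s, the
order observed for face/house rivalry).  All randomness flows from a
single seed, so identical parameters give bit-identical sessions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy import stats

from .io import (
    CONDITION_PHASE_DIFF,
    LEFT_EYE,
    MIXED,
    NONE,
    RIGHT_EYE,
    PerceptTimeline,
    PupilTrace,
    RunConfig,
    StimulusSchedule,
    write_percept_timeline,
    write_pupil_trace,
)

__all__ = [
    "SimulationParams",
    "luminance_signal",
    "gamma_corrected_multiplier",
    "simulate_reports",
    "simulate_pupil",
    "simulate_block",
    "make_fixture_session",
    "SESSION_CONDITION_ORDER",
]

#: block order of the seven-block session design: static bookends, naive
#: modulation blocks, the in-phase control in the middle, then the
#: attention-instruction modulation blocks.
SESSION_CONDITION_ORDER = (
    "static",
    "mod180_naive",
    "mod90_naive",
    "mod0_control",
    "mod180_attend",
    "mod90_attend",
    "static",
)

# gamma median for shape k at scale 1 (used to calibrate the scale)
_GAMMA_SHAPE_DEFAULT = 3.5
_GAMMA_MEDIAN_UNIT = float(stats.gamma.ppf(0.5, _GAMMA_SHAPE_DEFAULT))


@dataclass
class SimulationParams:
    """Tunable knobs of the synthetic session generator.

    Durations are seconds or milliseconds as suffixed; pupil quantities are
    in arbitrary raw units (they are z-scored downstream, so only ratios
    matter: ``gain`` vs ``noise_sd``/``drift_sd`` sets the effective SNR).
    """

    dominance_shape: float = _GAMMA_SHAPE_DEFAULT
    dominance_median_s: float = 2.7  # median exclusive-dominance duration
    mixed_frac: float = 0.29  # expected fraction of time in MIXED
    report_lag_ms: float = 400.0  # constant button-report latency
    w_dom: float = 0.9  # pupil weight of the dominant stimulus
    pupil_delay_ms: float = 400.0  # pupil response latency
    gain: float = 150.0  # oscillation gain, raw pupil units
    baseline: float = 2000.0  # mean pupil size, raw units
    drift_sd: float = 100.0  # SD of the slow (<0.2 Hz) wander
    noise_sd: float = 20.0  # white measurement noise SD
    blink_rate_hz: float = 0.25
    blink_dur_ms: float = 150.0  # mean blink gap duration
    blink_spike_ms: float = 60.0  # artifact spikes flanking each gap
    blink_spike_sd: float = 10.0  # spike amplitude in trace-SD units
    attend_gain: float = 0.3  # dominance-duration boost when attended
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.w_dom <= 1.0:
            raise ValueError("w_dom must lie in [0.5, 1]")
        if not 0.0 <= self.mixed_frac < 1.0:
            raise ValueError("mixed_frac must lie in [0, 1)")
        for name in (
            "dominance_shape",
            "dominance_median_s",
            "gain",
            "blink_dur_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("report_lag_ms", "pupil_delay_ms", "drift_sd", "noise_sd",
                     "blink_rate_hz", "attend_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dominance_scale_s(self) -> float:
        """Gamma scale theta giving the requested median at the given shape."""
        return self.dominance_median_s / float(
            stats.gamma.ppf(0.5, self.dominance_shape)
        )

    @property
    def mean_dominance_s(self) -> float:
        return self.dominance_shape * self.dominance_scale_s


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------


def luminance_signal(
    schedule: StimulusSchedule, eye: str, times_ms: np.ndarray
) -> np.ndarray:
    """Luminance fraction presented to one eye at the given times.

    ``L(t) = lum_lo + (lum_hi - lum_lo) * (sin(2 pi f t + phi_eye) + 1) / 2``
    with the left eye at the schedule's reference phase and the right eye
    shifted by ``phase_diff_deg``.  For a static block the luminance is
    constant at ``lum_hi``.
    """
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    t = np.asarray(times_ms, dtype=float)
    if not schedule.modulated:
        return np.full(t.shape, schedule.lum_hi)
    phi = np.deg2rad(schedule.phase_left_deg)
    if eye == "right":
        phi += np.deg2rad(schedule.phase_diff_deg)
    s = np.sin(2.0 * np.pi * schedule.freq * t / 1000.0 + phi)
    return schedule.lum_lo + (schedule.lum_hi - schedule.lum_lo) * (s + 1.0) / 2.0


def gamma_corrected_multiplier(
    schedule: StimulusSchedule, luminance: np.ndarray
) -> np.ndarray:
    """Pixel multiplier producing the requested *luminance* on the display.

    CRT output is ``pixel^gamma``, so the multiplier is ``L^(1/gamma)``.
    """
    return np.asarray(luminance, dtype=float) ** (1.0 / schedule.gamma)


# ---------------------------------------------------------------------------
# percept reports
# ---------------------------------------------------------------------------


def simulate_reports(
    params: SimulationParams,
    schedule: StimulusSchedule,
    rng: np.random.Generator | None = None,
) -> tuple[PerceptTimeline, PerceptTimeline]:
    """Draw a rivalry report stream for one block.

    Returns ``(reported, truth)``: the lag-free ground-truth timeline of
    perceptual states, and the same timeline delayed by ``report_lag_ms``
    (the button report) and truncated to the block.  Exclusive dominance
    periods alternate between eyes with gamma-distributed durations; MIXED
    interludes between them are exponential with a mean chosen so MIXED
    occupies ``mixed_frac`` of the block in expectation.  In
    attention-instruction blocks the attended image's dominance durations
    are lengthened by ``(1 + attend_gain)`` and the other image's shortened
    by ``(1 - attend_gain)``.
    """
    if schedule.block_duration_s <= 0:
        raise ValueError("block_duration_s must be positive")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    block_ms = schedule.block_duration_s * 1000.0
    mean_mixed_s = (
        params.mean_dominance_s * params.mixed_frac / (1.0 - params.mixed_frac)
    )
    gamma_dist = stats.gamma(params.dominance_shape, scale=params.dominance_scale_s)

    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    eye = LEFT_EYE if rng.random() < 0.5 else RIGHT_EYE
    while t < block_ms:
        dur_s = float(gamma_dist.rvs(random_state=rng))
        attended = schedule.attended_image(t)
        if attended is not None:
            this_image = schedule.image_in_eye("left" if eye == LEFT_EYE else "right")
            factor = (
                1.0 + params.attend_gain
                if this_image == attended
                else 1.0 - params.attend_gain
            )
            dur_s *= factor
        end = min(t + dur_s * 1000.0, block_ms)
        if end > t:
            intervals.append((t, end, eye))
        t = end
        if t >= block_ms:
            break
        if mean_mixed_s > 0:
            mix_end = min(t + float(rng.exponential(mean_mixed_s)) * 1000.0, block_ms)
            if mix_end > t:
                intervals.append((t, mix_end, MIXED))
            t = mix_end
        eye = RIGHT_EYE if eye == LEFT_EYE else LEFT_EYE

    truth = PerceptTimeline(intervals, block_id=schedule.condition)
    reported = truth.shifted(params.report_lag_ms, block_ms)
    return reported, truth


# ---------------------------------------------------------------------------
# pupil trace
# ---------------------------------------------------------------------------

_DRIFT_CUTOFF_HZ = 0.2


def simulate_pupil(
    params: SimulationParams,
    schedule: StimulusSchedule,
    truth: PerceptTimeline,
    rng: np.random.Generator | None = None,
    sample_rate: float = 1000.0,
) -> tuple[PupilTrace, dict]:
    """Generate a raw pupil trace (with blinks) for one block.

    The trace follows the inverted, delayed, percept-weighted luminance
    model described in the module docstring.  Blinks are inserted as gaps
    of missing samples (``valid=False``, empty on disk) flanked by
    high-amplitude spike artifacts — mimicking the rapid apparent
    pupil-size changes that survive vendor blink detection and that the
    5-SD change-rate rule is there to catch.

    Returns the trace and an ``artifacts`` dict with the injected gap and
    spike spans (sample indices, half-open) for ground-truth bookkeeping.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    block_ms = schedule.block_duration_s * 1000.0
    if params.pupil_delay_ms > block_ms:
        raise ValueError("pupil delay exceeds block duration")
    n = int(round(block_ms * sample_rate / 1000.0))
    t = np.arange(n) * (1000.0 / sample_rate)

    # percept weight of the left eye at each sample (ground truth, lag-free)
    w_left = np.full(n, 0.5)
    for a, b, lab in truth.intervals:
        i, j = int(np.ceil(a * sample_rate / 1000.0)), int(
            np.ceil(b * sample_rate / 1000.0)
        )
        if lab == LEFT_EYE:
            w_left[i:j] = params.w_dom
        elif lab == RIGHT_EYE:
            w_left[i:j] = 1.0 - params.w_dom

    td = t - params.pupil_delay_ms
    lum_l = luminance_signal(schedule, "left", td)
    lum_r = luminance_signal(schedule, "right", td)
    clean = params.baseline - params.gain * (
        w_left * lum_l + (1.0 - w_left) * lum_r
    )

    drift = np.zeros(n)
    if params.drift_sd > 0:
        walk = np.cumsum(rng.standard_normal(n))
        b, a = sps.butter(2, _DRIFT_CUTOFF_HZ / (sample_rate / 2.0), "low")
        walk = sps.filtfilt(b, a, walk)
        sd = walk.std()
        if sd > 0:
            drift = walk / sd * params.drift_sd
    noise = (
        rng.standard_normal(n) * params.noise_sd if params.noise_sd > 0 else 0.0
    )
    pupil = clean + drift + noise
    valid = np.ones(n, dtype=bool)
    blink = np.zeros(n, dtype=bool)

    gaps: list[tuple[int, int]] = []
    spikes: list[tuple[int, int]] = []
    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * schedule.block_duration_s)
        onsets = np.sort(rng.uniform(0, block_ms, size=n_blinks))
        spike_n = int(round(params.blink_spike_ms * sample_rate / 1000.0))
        trace_sd = float(np.std(clean - clean.mean() + drift))
        trace_sd = max(trace_sd, params.noise_sd, 1.0)
        for onset in onsets:
            dur = max(float(rng.exponential(params.blink_dur_ms)), 50.0)
            i = int(onset * sample_rate / 1000.0)
            j = min(int((onset + dur) * sample_rate / 1000.0), n)
            if j <= i:
                continue
            pupil[i:j] = np.nan
            valid[i:j] = False
            blink[i:j] = True
            gaps.append((i, j))
            pre_i = max(i - spike_n, 0)
            post_j = min(j + spike_n, n)
            for lo, hi in ((pre_i, i), (j, post_j)):
                if hi > lo:
                    amp = params.blink_spike_sd * trace_sd
                    # sign alternates sample to sample: the artifact is a
                    # rapid apparent size change, not a plateau
                    sign = float(rng.choice([-1.0, 1.0]))
                    alt = sign * (-1.0) ** np.arange(hi - lo)
                    pupil[lo:hi] += alt * amp
                    spikes.append((lo, hi))

    trace = PupilTrace(
        times=t,
        pupil=pupil,
        valid=valid,
        sample_rate=sample_rate,
        block_id=truth.block_id,
        blink=blink,
    )
    return trace, {"gaps": gaps, "spikes": spikes}


def simulate_block(
    params: SimulationParams,
    schedule: StimulusSchedule,
    rng: np.random.Generator | None = None,
) -> tuple[PupilTrace, PerceptTimeline, PerceptTimeline, dict]:
    """Convenience: one block end to end.

    Returns ``(raw trace, reported timeline, ground-truth timeline,
    artifacts)`` drawn from a single RNG stream.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    reported, truth = simulate_reports(params, schedule, rng)
    trace, artifacts = simulate_pupil(params, schedule, truth, rng)
    return trace, reported, truth, artifacts


# ---------------------------------------------------------------------------
# fixture sessions
# ---------------------------------------------------------------------------


def make_fixture_session(config: RunConfig, outdir: str | Path) -> dict:
    """Write a full seven-block session to disk with a ground-truth manifest.

    Blocks follow the canonical session order (static bookends, naive
    modulation, in-phase control, attention-instruction modulation) and the
    image-to-eye assignment alternates with each new block.  Every block
    gets ``<block>_trace.tsv`` and ``<block>_events.tsv``; the manifest
    records the seed, parameters, per-block ground truth and artifact spans.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params: SimulationParams = config.simulation
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "params": dataclasses.asdict(params),
        "block_duration_s": config.schedule.block_duration_s,
        "condition_order": list(SESSION_CONDITION_ORDER),
        "blocks": [],
    }
    base = config.schedule
    for k, condition in enumerate(SESSION_CONDITION_ORDER):
        schedule = dataclasses.replace(
            base,
            condition=condition,
            phase_diff_deg=CONDITION_PHASE_DIFF[condition],
            eye_assignment="face_left" if k % 2 == 0 else "house_left",
            attend_first="face" if condition.endswith("attend") else None,
        )
        trace, reported, truth, artifacts = simulate_block(params, schedule, rng)
        block_name = f"block{k + 1}_{condition}"
        trace.block_id = block_name
        write_pupil_trace(trace, outdir / f"{block_name}_trace.tsv")
        write_percept_timeline(reported, outdir / f"{block_name}_events.tsv")
        manifest["blocks"].append(
            {
                "name": block_name,
                "condition": condition,
                "eye_assignment": schedule.eye_assignment,
                "phase_diff_deg": schedule.phase_diff_deg,
                "attend_first": schedule.attend_first,
                "truth_intervals": [list(iv) for iv in truth.intervals],
                "artifact_gaps": [list(g) for g in artifacts["gaps"]],
                "artifact_spikes": [list(s) for s in artifacts["spikes"]],
            }
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
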