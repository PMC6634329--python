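"""Behavioral dominance statistics and design sensitivity.

Covers the report-stream side of the experiment: median exclusive-dominance
durations and time-proportion summaries per subject, condition and stimulus
type (face/house); a 2 (stimulus type) x 7 (condition) repeated-measures
ANOVA with generalized eta-squared; paired t-tests with the d_s effect
size; and a post-hoc sensitivity analysis based on the noncentral t
distribution (the smallest effect size d a paired/one-sample t design of
given n, alpha and power can reliably detect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import LEFT_EYE, MIXED, NONE, RIGHT_EYE, PerceptTimeline, StimulusSchedule

__all__ = [
    "PairedTestResult",
    "AnovaResult",
    "summarize_behavior",
    "attention_proportions",
    "rm_anova_2x7",
    "paired_t_with_ds",
    "sensitivity_min_d",
    "t_power",
]


# ---------------------------------------------------------------------------
# paired t with effect sizes
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    d_s: float  # mean difference over pooled SD of the two sets
    d_z: float  # t / sqrt(n): SD of the differences as the scaler


def paired_t_with_ds(a: np.ndarray, b: np.ndarray) -> PairedTestResult:
    """Two-sided paired t-test with d_s and d_z effect sizes.

    ``d_s`` divides the mean difference by the pooled SD of the two sets of
    observations (the between-groups scaler applied to a paired design, as
    in the convention this pipeline reproduces); ``d_z`` is the standard
    paired effect size ``t / sqrt(n)`` and is reported alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-d vectors")
    n = len(a)
    if n < 2:
        raise ValueError("paired test needs at least 2 pairs")
    res = stats.ttest_rel(a, b)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # identical pairs: zero variance of differences
        t, p = 0.0, 1.0
    sd_pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    d_s = float((a.mean() - b.mean()) / sd_pooled) if sd_pooled > 0 else 0.0
    return PairedTestResult(t=t, df=n - 1, p=p, d_s=d_s, d_z=t / np.sqrt(n))


# ---------------------------------------------------------------------------
# behavioral summaries
# ---------------------------------------------------------------------------


def summarize_behavior(
    timelines: dict[tuple[str, str], PerceptTimeline],
    schedules: dict[tuple[str, str], StimulusSchedule],
) -> pd.DataFrame:
    """Per subject x condition x stimulus-type dominance summary.

    ``timelines``/``schedules`` are keyed by ``(subject_id, block_name)``.
    Eye labels are mapped to stimulus type (face/house) through each
    block's eye assignment.  Returns one row per subject, condition and
    stimulus type with the median exclusive-dominance duration (s), the
    exclusive time proportion, and the block's mixed/none proportions.
    Cells with no exclusive periods get a missing median (NaN), never zero.
    """
    rows = []
    for key, tl in timelines.items():
        subject, block = key
        sched = schedules[key]
        total = tl.duration_ms
        mixed_prop = tl.durations(MIXED).sum() / total
        none_prop = tl.durations(NONE).sum() / total
        for image in ("face", "house"):
            eye_lab = LEFT_EYE if sched.eye_of_image(image) == "left" else RIGHT_EYE
            durs = tl.durations(eye_lab)
            rows.append(
                {
                    "subject": subject,
                    "block": block,
                    "condition": sched.condition,
                    "stimulus_type": image,
                    "median_dominance_s": (
                        float(np.median(durs)) / 1000.0 if durs.size else np.nan
                    ),
                    "prop_exclusive": float(durs.sum()) / total,
                    "prop_mixed": float(mixed_prop),
                    "prop_none": float(none_prop),
                }
            )
    return pd.DataFrame(rows)


def attention_proportions(
    timeline: PerceptTimeline, schedule: StimulusSchedule
) -> dict[str, float]:
    """Time each image was part of the percept while it was the instructed
    attention target.

    "Part of the percept" counts exclusive dominance of the image's eye and
    MIXED periods (the image need not be exclusively dominant).  Returns
    ``{"face": p, "house": p}``: the proportion of attend-face time with
    face in the percept, and likewise for house.
    """
    if schedule.attend_first is None:
        raise ValueError("block has no attention instruction")
    out = {}
    for image in ("face", "house"):
        eye_lab = (
            LEFT_EYE if schedule.eye_of_image(image) == "left" else RIGHT_EYE
        )
        instructed = 0.0
        present = 0.0
        step = schedule.attend_interval_s * 1000.0
        block_ms = timeline.duration_ms
        starts = np.arange(0.0, block_ms, step)
        for s in starts:
            if schedule.attended_image(s) != image:
                continue
            e = min(s + step, block_ms)
            instructed += e - s
            for a, b, lab in timeline.intervals:
                lo, hi = max(a, s), min(b, e)
                if hi > lo and lab in (eye_lab, MIXED):
                    present += hi - lo
        out[image] = present / instructed if instructed > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    table: pd.DataFrame  # one row per effect: F, df1, df2, p, eta2_g
    sums_of_squares: dict[str, float]


def rm_anova_2x7(
    data: pd.DataFrame,
    dv: str = "median_dominance_s",
    within_a: str = "stimulus_type",
    within_b: str = "condition",
    subject: str = "subject",
) -> AnovaResult:
    """Two-factor fully-within-subjects ANOVA on a balanced table.

    ``data`` holds one observation per subject x level-of-A x level-of-B
    cell (long format).  The classical decomposition is used: each effect
    is tested against its own interaction-with-subjects error term, with no
    sphericity correction.  Generalized eta-squared follows the
    Olejnik-Algina definition for a fully within design:

        eta2_G = SS_effect / (SS_effect + SS_subjects + SS_AxS + SS_BxS
                              + SS_AxBxS)

    With all observations equal (no variance anywhere) F is reported as 0
    with p = 1.
    """
    piv = data.pivot_table(
        index=subject, columns=[within_a, within_b], values=dv, aggfunc="mean"
    )
    if piv.isna().any().any():
        missing = piv.columns[piv.isna().any()].tolist()
        raise ValueError(f"missing cells in ANOVA table: {missing}")
    a_levels = sorted({c[0] for c in piv.columns})
    b_levels = sorted({c[1] for c in piv.columns})
    n = piv.shape[0]
    a, b = len(a_levels), len(b_levels)
    # y[s, i, j]
    y = np.empty((n, a, b))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            y[:, i, j] = piv[(al, bl)].to_numpy()

    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_s = a * b * np.sum((m_s - g) ** 2)
    ss_a = n * b * np.sum((m_a - g) ** 2)
    ss_b = n * a * np.sum((m_b - g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + g) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + g) ** 2)
    ss_t = np.sum((y - g) ** 2)
    ss_abs = ss_t - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    denom_g = ss_s + ss_as + ss_bs + ss_abs

    def effect(name, ss_eff, df_eff, ss_err, df_err):
        if ss_err <= 0:
            f, p = 0.0, 1.0
        else:
            f = (ss_eff / df_eff) / (ss_err / df_err)
            p = float(stats.f.sf(f, df_eff, df_err))
        eta = ss_eff / (ss_eff + denom_g) if (ss_eff + denom_g) > 0 else 0.0
        return {
            "effect": name,
            "F": float(f),
            "df1": df_eff,
            "df2": df_err,
            "p": p,
            "eta2_g": float(eta),
        }

    table = pd.DataFrame(
        [
            effect(within_a, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
            effect(within_b, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
            effect(
                f"{within_a} x {within_b}",
                ss_ab,
                (a - 1) * (b - 1),
                ss_abs,
                (a - 1) * (b - 1) * (n - 1),
            ),
        ]
    )
    ss = {
        "subjects": float(ss_s),
        "A": float(ss_a),
        "B": float(ss_b),
        "AB": float(ss_ab),
        "AxS": float(ss_as),
        "BxS": float(ss_bs),
        "AxBxS": float(ss_abs),
        "total": float(ss_t),
    }
    return AnovaResult(table=table, sums_of_squares=ss)


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------


def t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of a two-sided one-sample/paired t-test at true effect size d.

    Uses the noncentral t distribution with df = n - 1 and noncentrality
    d * sqrt(n).  The lower-tail rejection probability is negligible for
    any positive d of interest; where scipy's noncentral CDF underflows to
    NaN deep in that tail it is treated as zero.
    """
    df = n - 1
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    ncp = d * np.sqrt(n)
    upper = stats.nct.sf(tc, df, ncp)
    lower = stats.nct.cdf(-tc, df, ncp)
    if not np.isfinite(upper):
        upper = 1.0 if ncp > tc else 0.0
    if not np.isfinite(lower):
        lower = 0.0
    return float(upper + lower)


def sensitivity_min_d(n: int, alpha: float = 0.05, power: float = 0.8) -> float:
    """Smallest effect size d detectable at the given n, alpha and power.

    Solves ``t_power(d, n, alpha) = power`` for d by bisection to 1e-4 —
    the post-hoc sensitivity analysis for a two-sided paired/one-sample t
    design.  Raises if the target power is unattainable for any d <= 20.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    hi = 20.0
    if t_power(hi, n, alpha) < power:
        raise ValueError("target power unattainable")
    return float(
        optimize.brentq(
            lambda d: t_power(d, n, alpha) - power, 1e-9, hi, xtol=1e-6
        )
    )
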