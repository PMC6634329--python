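"""Percept decoding from the per-cycle F1 component Z.

Two complementary questions are answered here.  First, does the complex
F1 component of the pupil oscillation depend on which eye's stimulus is
perceptually dominant?  That is tested with a two-sided paired t-test on
the imaginary part of the per-subject mean Z for left-eye-reported versus
right-eye-reported cycles.  Second, how well does Z predict the percept
cycle by cycle?  Sweeping a threshold over a per-cycle score yields an ROC
curve; its area (AUC) measures single-cycle discrimination, with 0.5 as
chance.  The default score is Im(Z); an upper bound on decodability is
obtained by rotating Z in the complex plane in 1-degree steps and taking
the best AUC over all projection angles.

The module also carries the analytic two-source mixture model: if the
dominant stimulus drives the pupil with weight w and the suppressed one
with 1 - w, the summed oscillation has amplitude |w + (1-w) e^{i dphi}|
relative to a single source — e.g. 91% for w = 0.9 at a 90-degree offset,
80% at 180 degrees, and sqrt(0.5) = 71% / 0 for equal weights.  Amplitudes
are therefore not comparable across phase-offset conditions, which is why
every condition is tested separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .behavior import PairedTestResult, paired_t_with_ds
from .cycles import CycleRecord
from .io import LEFT_EYE, RIGHT_EYE

__all__ = [
    "SubjectConditionZ",
    "DecodingResult",
    "mixture_amplitude",
    "paired_im_test",
    "roc_auc",
    "optimal_rotation",
    "decode_session",
    "collect_subject_z",
]


def mixture_amplitude(w: float, delta_phi_deg: float) -> float:
    """Oscillation amplitude of a two-source mixture, as a fraction of a
    single source.

    ``|w + (1 - w) * exp(i * delta_phi)|`` for dominant weight ``w`` and
    inter-source phase offset ``delta_phi`` (degrees).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return float(abs(w + (1.0 - w) * np.exp(1j * np.deg2rad(delta_phi_deg))))


@dataclass
class SubjectConditionZ:
    """Per-cycle Z values of one subject in one condition."""

    subject_id: str
    condition: str
    z_left: np.ndarray  # complex, LEFT_EYE cycles
    z_right: np.ndarray  # complex, RIGHT_EYE cycles

    @property
    def mean_z_left(self) -> complex:
        return complex(np.mean(self.z_left)) if len(self.z_left) else complex("nan")

    @property
    def mean_z_right(self) -> complex:
        return complex(np.mean(self.z_right)) if len(self.z_right) else complex("nan")


@dataclass
class DecodingResult:
    """Single-subject, single-condition decoding summary."""

    subject_id: str
    condition: str
    n_left: int
    n_right: int
    auc_im: float  # AUC along the imaginary axis
    theta_opt: float  # best projection angle, degrees in [0, 180)
    auc_opt: float  # AUC at theta_opt (after orientation folding)
    auc_by_angle: np.ndarray = field(repr=False)  # folded AUC per angle


def collect_subject_z(
    cycles: dict[tuple[str, str], list[CycleRecord]]
) -> list[SubjectConditionZ]:
    """Group exclusive-labelled cycles into per-subject/condition Z sets.

    ``cycles`` is keyed by ``(subject_id, condition)``; EXCLUDED cycles are
    dropped here and never reach any statistic.
    """
    out = []
    for (subject, condition), recs in cycles.items():
        zl = np.array([r.z for r in recs if r.label == LEFT_EYE], dtype=complex)
        zr = np.array([r.z for r in recs if r.label == RIGHT_EYE], dtype=complex)
        out.append(
            SubjectConditionZ(
                subject_id=subject, condition=condition, z_left=zl, z_right=zr
            )
        )
    return out


def paired_im_test(group: list[SubjectConditionZ]) -> PairedTestResult:
    """Two-sided paired t-test on Im(mean Z) between reported percepts.

    Each subject contributes the imaginary part of the complex mean of Z
    over left-eye-reported and over right-eye-reported cycles; subjects
    lacking either class are excluded.
    """
    pairs = [
        (s.mean_z_left.imag, s.mean_z_right.imag)
        for s in group
        if len(s.z_left) and len(s.z_right)
    ]
    if len(pairs) < 2:
        raise ValueError("need at least 2 subjects with both percepts reported")
    a, b = map(np.array, zip(*pairs))
    return paired_t_with_ds(a, b)


def roc_auc(
    scores_left: np.ndarray, scores_right: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC analysis of per-cycle scores; RIGHT_EYE is the positive class.

    Sweeping a threshold over the scores gives hit and false-alarm rates
    (right-eye cycles above threshold are hits, left-eye cycles above it
    false alarms); the area under the resulting curve is returned together
    with the (FPR, TPR) points.  Tied scores contribute half, making the
    AUC identical to the Mann-Whitney U statistic scaled to [0, 1].
    """
    scores_left = np.asarray(scores_left, dtype=float)
    scores_right = np.asarray(scores_right, dtype=float)
    if len(scores_left) == 0 or len(scores_right) == 0:
        raise ValueError("both classes must be non-empty")
    y = np.concatenate(
        [np.zeros(len(scores_left), dtype=int), np.ones(len(scores_right), dtype=int)]
    )
    s = np.concatenate([scores_left, scores_right])
    fpr, tpr, _ = skm.roc_curve(y, s, drop_intermediate=False)
    return float(skm.auc(fpr, tpr)), fpr, tpr


def optimal_rotation(
    z_left: np.ndarray, z_right: np.ndarray, step_deg: float = 1.0
) -> tuple[float, float, np.ndarray]:
    """Best complex-plane projection angle for percept discrimination.

    For each angle theta in ``[0, 180)`` degrees (in ``step_deg`` steps)
    the cycles are scored by ``Im(Z * exp(-i theta))`` and the AUC computed;
    since AUC(theta + 180) = 1 - AUC(theta), orientation is folded by
    taking ``max(AUC, 1 - AUC)`` per angle, which makes the half-circle
    search equivalent to scanning all rotations and keeping the maximum.
    Returns ``(theta_opt, auc_opt, folded AUC per angle)`` with the
    smallest angle winning ties.
    """
    z_left = np.asarray(z_left, dtype=complex)
    z_right = np.asarray(z_right, dtype=complex)
    thetas = np.arange(0.0, 180.0, step_deg)
    aucs = np.empty(len(thetas))
    for k, th in enumerate(thetas):
        rot = np.exp(-1j * np.deg2rad(th))
        a, _, _ = roc_auc((z_left * rot).imag, (z_right * rot).imag)
        aucs[k] = max(a, 1.0 - a)
    k_best = int(np.argmax(aucs))  # argmax returns the first (smallest) angle
    return float(thetas[k_best]), float(aucs[k_best]), aucs


def decode_session(
    cycles: dict[tuple[str, str], list[CycleRecord]],
    step_deg: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full decoding analysis over a session of subjects and conditions.

    Per subject and condition: the Im(Z) AUC and the optimal-rotation AUC
    over that subject's exclusive cycles.  Per condition: the group-level
    paired t-test on Im(mean Z) and a two-sided one-sample t-test of the
    per-subject Im(Z) AUCs against chance (0.5).

    Returns ``(per_subject, per_condition)`` data frames.  Subjects
    missing a percept class in some condition are reported with NaN
    results there (missing, not zero) and skipped in group tests.
    """
    groups = collect_subject_z(cycles)
    rows = []
    for s in groups:
        if len(s.z_left) == 0 or len(s.z_right) == 0:
            rows.append(
                {
                    "subject": s.subject_id,
                    "condition": s.condition,
                    "n_left": len(s.z_left),
                    "n_right": len(s.z_right),
                    "auc_im": np.nan,
                    "theta_opt": np.nan,
                    "auc_opt": np.nan,
                }
            )
            continue
        auc_im, _, _ = roc_auc(s.z_left.imag, s.z_right.imag)
        theta, auc_opt, _ = optimal_rotation(s.z_left, s.z_right, step_deg)
        rows.append(
            {
                "subject": s.subject_id,
                "condition": s.condition,
                "n_left": len(s.z_left),
                "n_right": len(s.z_right),
                "auc_im": auc_im,
                "theta_opt": theta,
                "auc_opt": auc_opt,
            }
        )
    per_subject = pd.DataFrame(rows)

    cond_rows = []
    for condition, sub in per_subject.groupby("condition"):
        ok = sub.dropna(subset=["auc_im"])
        group = [
            g
            for g in groups
            if g.condition == condition and len(g.z_left) and len(g.z_right)
        ]
        if len(ok) >= 2:
            im_test = paired_im_test(group)
            res = stats_ttest_1samp(ok["auc_im"].to_numpy(), 0.5)
            cond_rows.append(
                {
                    "condition": condition,
                    "n_subjects": len(ok),
                    "mean_auc_im": float(ok["auc_im"].mean()),
                    "mean_auc_opt": float(ok["auc_opt"].mean()),
                    "im_t": im_test.t,
                    "im_df": im_test.df,
                    "im_p": im_test.p,
                    "im_d_s": im_test.d_s,
                    "auc_t": res[0],
                    "auc_p": res[1],
                }
            )
        else:
            cond_rows.append(
                {
                    "condition": condition,
                    "n_subjects": len(ok),
                    "mean_auc_im": np.nan,
                    "mean_auc_opt": np.nan,
                    "im_t": np.nan,
                    "im_df": np.nan,
                    "im_p": np.nan,
                    "im_d_s": np.nan,
                    "auc_t": np.nan,
                    "auc_p": np.nan,
                }
            )
    return per_subject, pd.DataFrame(cond_rows)


def stats_ttest_1samp(x: np.ndarray, popmean: float) -> tuple[float, float]:
    from scipy import stats

    res = stats.ttest_1samp(x, popmean)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        t, p = 0.0, 1.0
    return t, p
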