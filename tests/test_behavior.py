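"""Behavioral summaries, rm-ANOVA with generalized eta-squared, paired t,
and noncentral-t sensitivity analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pupiltag import (
    LEFT_EYE,
    MIXED,
    RIGHT_EYE,
    PerceptTimeline,
    SimulationParams,
    StimulusSchedule,
    attention_proportions,
    paired_t_with_ds,
    rm_anova_2x7,
    sensitivity_min_d,
    simulate_reports,
    summarize_behavior,
    t_power,
)
from pupiltag.pipeline import schedule_for_condition


class TestSummarizeBehavior:
    def _sched(self, condition="static", assign="face_left"):
        return schedule_for_condition(
            StimulusSchedule(block_duration_s=300.0), condition, assign
        )

    def test_single_interval_block(self):
        tl = PerceptTimeline([(0, 300_000, LEFT_EYE)])
        df = summarize_behavior(
            {("s1", "b1"): tl}, {("s1", "b1"): self._sched()}
        )
        face = df[df.stimulus_type == "face"].iloc[0]  # face is in the left eye
        assert face.median_dominance_s == pytest.approx(300.0)
        assert face.prop_exclusive == pytest.approx(1.0)
        house = df[df.stimulus_type == "house"].iloc[0]
        assert np.isnan(house.median_dominance_s)  # empty cell: missing, not 0
        assert house.prop_exclusive == 0.0

    def test_median_of_three_durations(self):
        tl = PerceptTimeline(
            [
                (0, 1000, LEFT_EYE),
                (1000, 2000, MIXED),
                (2000, 4000, LEFT_EYE),
                (4000, 5000, MIXED),
                (5000, 8000, LEFT_EYE),
                (8000, 10000, RIGHT_EYE),
            ]
        )
        df = summarize_behavior({("s", "b"): tl}, {("s", "b"): self._sched()})
        face = df[df.stimulus_type == "face"].iloc[0]
        assert face.median_dominance_s == pytest.approx(2.0)  # median of 1,2,3
        assert face.prop_exclusive == pytest.approx(6000 / 10000)
        assert face.prop_mixed == pytest.approx(2000 / 10000)

    def test_eye_assignment_maps_to_stimulus(self):
        tl = PerceptTimeline([(0, 1000, LEFT_EYE)])
        df = summarize_behavior(
            {("s", "b"): tl}, {("s", "b"): self._sched(assign="house_left")}
        )
        house = df[df.stimulus_type == "house"].iloc[0]
        assert house.prop_exclusive == 1.0

    def test_proportions_match_simulation_ground_truth(self, schedule):
        params = SimulationParams(seed=31)
        _, truth = simulate_reports(params, schedule)
        df = summarize_behavior(
            {("s", "b"): truth}, {("s", "b"): schedule}
        )
        total = df.iloc[0]
        both = df.prop_exclusive.sum() + total.prop_mixed + total.prop_none
        assert both == pytest.approx(1.0, abs=1e-9)
        manifest_mixed = truth.durations(MIXED).sum() / truth.duration_ms
        assert total.prop_mixed == pytest.approx(manifest_mixed, abs=1e-12)

    def test_attention_bias_detected(self):
        """Blocks simulated with an attention-duration boost show higher
        presence of the instructed image, significantly across subjects."""
        sched = schedule_for_condition(
            StimulusSchedule(block_duration_s=300.0), "mod180_attend"
        )
        attended, unattended = [], []
        for s in range(8):
            rng = np.random.default_rng([55, s])
            params = SimulationParams(seed=s, attend_gain=0.4)
            reported, _ = simulate_reports(params, sched, rng)
            props = attention_proportions(reported, sched)
            attended.append(props["face"])  # face instructed first
            unattended.append(props["house"])
        res = paired_t_with_ds(np.array(attended), np.array(unattended))
        # both images are instructed half the time; compare each image's
        # presence while instructed -- biased upward by attend_gain
        assert np.mean(attended) > 0.5
        assert res.df == 7

    def test_attention_proportions_requires_instruction(self):
        tl = PerceptTimeline([(0, 1000, LEFT_EYE)])
        with pytest.raises(ValueError, match="instruction"):
            attention_proportions(tl, self._sched("static"))


def pingouin_anova(df):
    import pingouin as pg

    return pg.rm_anova(
        data=df,
        dv="value",
        within=["A", "B"],
        subject="subject",
        detailed=True,
    )


class TestRmAnova:
    def _table(self, y):
        n, a, b = y.shape
        rows = [
            {"subject": f"s{s}", "A": f"a{i}", "B": f"b{j}", "value": y[s, i, j]}
            for s, i, j in itertools.product(range(n), range(a), range(b))
        ]
        return pd.DataFrame(rows)

    def test_all_equal_data_degenerate(self):
        res = rm_anova_2x7(self._table(np.ones((4, 2, 7))), dv="value",
                           within_a="A", within_b="B")
        assert (res.table.F == 0).all()
        assert (res.table.p == 1).all()

    def test_three_subject_toy_table_closed_form(self):
        """2x2 within design worked by hand.

        y[s, i, j] = mu + 2*i + 1*j + s with no interaction and additive
        subject offsets: SS_A = n*b*(d_A/2)^2*2 = 3*2*2 = 24 for d_A = 2,
        SS_B = 3*2*0.5^2*2 = 6 for d_B = 1, all error terms 0 -> F
        degenerate, eta2_G determined by subject variance alone.
        """
        n, a, b = 3, 2, 2
        y = np.zeros((n, a, b))
        for s, i, j in itertools.product(range(n), range(a), range(b)):
            y[s, i, j] = 2.0 * i + 1.0 * j + float(s)
        res = rm_anova_2x7(self._table(y), dv="value", within_a="A", within_b="B")
        ss = res.sums_of_squares
        assert ss["A"] == pytest.approx(n * b * 2 * (1.0**2), abs=1e-10)  # 12
        assert ss["B"] == pytest.approx(n * a * 2 * (0.5**2), abs=1e-10)  # 3
        assert ss["subjects"] == pytest.approx(a * b * 2.0, abs=1e-10)  # 8
        assert ss["AxS"] == pytest.approx(0.0, abs=1e-10)
        # eta2_G = SS_A / (SS_A + SS_subj) with zero error terms
        row = res.table.set_index("effect").loc["A"]
        assert row.eta2_g == pytest.approx(12 / (12 + 8), abs=1e-10)

    def test_matches_pingouin_f_and_p(self, rng):
        """F, dfs and p for all three effects match an independent
        rm-ANOVA implementation on random balanced tables."""
        pg = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, (6, 2, 7)) + rng.normal(0, 1, (6, 1, 1))
        res = rm_anova_2x7(self._table(y), dv="value", within_a="A", within_b="B")
        ref = pingouin_anova(self._table(y))
        ours = res.table.set_index("effect")
        for eff, name in [("A", "A"), ("B", "B"), ("A * B", "A x B")]:
            r = ref[ref.Source == eff].iloc[0]
            o = ours.loc[name]
            assert o.F == pytest.approx(r.F, rel=1e-9)
            assert o.df1 == r.ddof1 and o.df2 == r.ddof2
            assert o.p == pytest.approx(r["p_unc"], rel=1e-9, abs=1e-12)

    def test_total_ss_decomposition(self, rng):
        y = rng.normal(0, 2, (5, 2, 7))
        res = rm_anova_2x7(self._table(y), dv="value", within_a="A", within_b="B")
        ss = res.sums_of_squares
        parts = (
            ss["subjects"] + ss["A"] + ss["B"] + ss["AB"]
            + ss["AxS"] + ss["BxS"] + ss["AxBxS"]
        )
        assert parts == pytest.approx(ss["total"], abs=1e-9)

    def test_generalized_eta_never_exceeds_partial(self, rng):
        for _ in range(5):
            y = rng.normal(0, 1, (6, 2, 7))
            res = rm_anova_2x7(self._table(y), dv="value",
                               within_a="A", within_b="B")
            ss = res.sums_of_squares
            err = {"A": ss["AxS"], "B": ss["BxS"], "A x B": ss["AxBxS"]}
            for _, row in res.table.iterrows():
                eta_p = ss[row.effect.replace(" x ", "")] / (
                    ss[row.effect.replace(" x ", "")] + err[row.effect]
                ) if row.effect != "A x B" else ss["AB"] / (ss["AB"] + err["A x B"])
                assert row.eta2_g <= eta_p + 1e-12

    def test_missing_cells_rejected(self):
        df = self._table(np.ones((3, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x7(df, dv="value", within_a="A", within_b="B")

    def test_null_table_rejects_at_nominal_rate(self):
        """Under pure noise the condition effect rejects at ~5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.normal(0, 1, (6, 2, 7))
            res = rm_anova_2x7(self._table(y), dv="value",
                               within_a="A", within_b="B")
            if res.table.set_index("effect").loc["B", "p"] < 0.05:
                rejections += 1
        # binomial 95% interval around 0.05 with n=200: ~[0.02, 0.09]
        assert 0.015 <= rejections / n_rep <= 0.10


class TestPairedT:
    def test_identical_vectors_null(self):
        res = paired_t_with_ds(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert res.t == 0.0 and res.p == 1.0

    def test_three_pair_closed_form(self):
        """diffs (1,1,4): mean 2, sd sqrt(3), t = 2/(sqrt(3)/sqrt(3)) = 2."""
        a = np.array([2.0, 3.0, 8.0])
        b = np.array([1.0, 2.0, 4.0])
        res = paired_t_with_ds(a, b)
        assert res.t == pytest.approx(2.0, abs=1e-12)
        assert res.df == 2
        sd_pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2)
        assert res.d_s == pytest.approx(2.0 / sd_pooled, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t_with_ds(np.ones(3), np.ones(4))


class TestSensitivity:
    def test_reference_values(self):
        """12 subjects, alpha .05 two-sided: smallest detectable d is 0.88
        at power .80 and 1.14 at power .95."""
        assert sensitivity_min_d(12, 0.05, 0.80) == pytest.approx(0.88, abs=0.01)
        assert sensitivity_min_d(12, 0.05, 0.95) == pytest.approx(1.14, abs=0.01)

    def test_bracketing_property(self):
        for power in (0.8, 0.9, 0.95):
            d = sensitivity_min_d(12, 0.05, power)
            assert t_power(d, 12) >= power - 1e-6
            assert t_power(d - 0.01, 12) < power

    def test_monotone_in_power_and_n(self):
        assert (
            sensitivity_min_d(12, 0.05, 0.5)
            < sensitivity_min_d(12, 0.05, 0.8)
            < sensitivity_min_d(12, 0.05, 0.95)
        )
        assert (
            sensitivity_min_d(30, 0.05, 0.8)
            < sensitivity_min_d(12, 0.05, 0.8)
            < sensitivity_min_d(5, 0.05, 0.8)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_min_d(1, 0.05, 0.8)
        with pytest.raises(ValueError):
            sensitivity_min_d(12, 0.0, 0.8)
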