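"""Filters, summaries, the mixed ANOVA contrasts and paired-t power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualsource.behavior_stats import (
    condition_summary,
    mixed_anova,
    paired_contrast,
    power_paired_t,
    preprocess,
)
from dualsource.synthetic_data import TASK_CONDITIONS


def toy_trials(rows):
    defaults = dict(subject_id=0, group_angle=20, block=1, condition="CON",
                    c1=0.15, c2=0.05, direction="left", choice="left",
                    rt=1.0, is_valid=True)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestPreprocess:
    def test_fast_and_nonresponse_trials_removed(self):
        rows = [{} for _ in range(7)]
        rows += [{"rt": 0.2}, {"rt": 0.15}]
        rows += [{"choice": "none", "rt": np.nan, "is_valid": False}]
        kept, report = preprocess(toy_trials(rows))
        assert len(kept) == 7
        assert report.n_fast == 2
        assert report.n_no_response == 1
        assert report.removed_fraction == pytest.approx(0.30)

    def test_low_accuracy_block_pair_excludes_subject(self):
        # subject 0: 50% correct in blocks 1-2; subject 1 clean
        rows = []
        for b in (1, 2):
            for i in range(10):
                rows.append({"subject_id": 0, "block": b,
                             "choice": "left" if i < 5 else "right"})
        for b in (1, 2):
            for _ in range(10):
                rows.append({"subject_id": 1, "block": b, "choice": "left"})
        kept, report = preprocess(toy_trials(rows))
        assert report.excluded_subjects == (0,)
        assert set(kept.subject_id) == {1}

    def test_control_trials_dropped_from_analysis_set(self):
        rows = [{}, {"condition": "CONTROL", "c1": 0.6, "c2": 0.0}]
        kept, report = preprocess(toy_trials(rows))
        assert "CONTROL" not in set(kept.condition)
        assert report.n_control_dropped == 1

    def test_clean_data_pass_through(self, small_cohort):
        trials, _ = small_cohort
        kept, report = preprocess(trials)
        assert report.excluded_subjects == ()
        assert len(kept) <= len(trials)

    def test_idempotence(self, small_cohort):
        trials, _ = small_cohort
        once, _ = preprocess(trials)
        twice, report2 = preprocess(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report2.removed_fraction == 0.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            preprocess(toy_trials([{"condition": "WAT"}]))


class TestConditionSummary:
    def test_single_trial_cell_equals_that_trial(self):
        rows = [{"condition": c, "rt": 0.8 + i * 0.1, "choice": "left"}
                for i, c in enumerate(TASK_CONDITIONS)]
        summary = condition_summary(toy_trials(rows))
        con = summary[summary.condition == "CON"].iloc[0]
        assert con.accuracy == 1.0 and con.mean_rt == pytest.approx(0.8)

    def test_permutation_invariance(self, small_cohort):
        trials, _ = small_cohort
        kept, _ = preprocess(trials)
        s1 = condition_summary(kept)
        s2 = condition_summary(kept.sample(frac=1.0, random_state=3))
        merged = s1.merge(s2, on=["subject_id", "condition"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged.accuracy_a, merged.accuracy_b)
        np.testing.assert_allclose(merged.mean_rt_a, merged.mean_rt_b)

    def test_generative_monotonicity(self, small_cohort):
        """CON was generated with lower drift than CON_BSL, so group accuracy
        should be ordered the same way."""
        trials, _ = small_cohort
        kept, _ = preprocess(trials)
        summary = condition_summary(kept)
        means = summary.groupby("condition").accuracy.mean()
        assert means["CON"] < means["CON_BSL"]


def synth_summary(rng, n_per_group=20, effects=None):
    """Directly simulated subject x condition summaries under a normal model."""
    effects = effects or {}
    rows = []
    sid = 0
    for angle in (20, 45):
        for _ in range(n_per_group):
            subj = rng.normal(0, 0.5)
            for cond in TASK_CONDITIONS:
                rows.append(dict(
                    subject_id=sid, group_angle=angle, condition=cond,
                    accuracy=subj + effects.get(cond, 0.0) + rng.normal(0, 1.0),
                    mean_rt=1.0, n_trials=96))
            sid += 1
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_type_i_error_calibration(self):
        """Under the null, each 1-df test rejects at ~the nominal 5% rate."""
        rng = np.random.default_rng(314)
        effects = {"source": 0, "coherence": 0, "group": 0}
        rejections = {k: 0 for k in effects}
        n_rep = 400
        for _ in range(n_rep):
            table = mixed_anova(synth_summary(rng), dependent="accuracy")
            for eff in effects:
                p = table.loc[table.effect == eff, "p"].iloc[0]
                rejections[eff] += p < 0.05
        for eff, k in rejections.items():
            assert k / n_rep == pytest.approx(0.05, abs=0.025), eff

    def test_detects_source_main_effect(self):
        """A true double-vs-single gap of ~0.8 within-subject SD at the
        experiment's sample size is detected essentially always."""
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(25):
            effects = {"CON": -0.8, "INC": -0.8}  # double-source deficit
            table = mixed_anova(synth_summary(rng, n_per_group=23, effects=effects))
            hits += table.loc[table.effect == "source", "p"].iloc[0] < 0.05
        assert hits >= 23

    def test_rt_location_invariance(self, small_cohort):
        trials, _ = small_cohort
        kept, _ = preprocess(trials)
        summary = condition_summary(kept)
        shifted = summary.assign(mean_rt=summary.mean_rt + 5.0)
        f1 = mixed_anova(summary, dependent="rt")
        f2 = mixed_anova(shifted, dependent="rt")
        within = f1.effect != "group"  # the between effect is not shift-free
        np.testing.assert_allclose(f1.F[within], f2.F[within], rtol=1e-9)

    def test_reports_all_effects(self, small_cohort):
        trials, _ = small_cohort
        summary = condition_summary(preprocess(trials)[0])
        table = mixed_anova(summary)
        assert set(table.effect) == {
            "source", "coherence", "source_x_coherence", "group",
            "group_x_source", "group_x_coherence", "group_x_source_x_coherence",
        }
        assert ((table.partial_eta_sq >= 0) & (table.partial_eta_sq <= 1)).all()

    def test_agrees_with_scipy_on_paired_reduction(self):
        """With one group, the source main effect F equals the squared paired
        t statistic on the per-subject contrast."""
        rng = np.random.default_rng(5)
        summary = synth_summary(rng, n_per_group=12)
        summary = summary[summary.group_angle == 20]
        # add a second pseudo-group of size 12 is avoided: compare against
        # a paired t on the contrast with group regressed out instead
        wide = summary.pivot_table(index=["subject_id", "group_angle"],
                                   columns="condition", values="accuracy")
        contrast = (wide["CON"] + wide["INC"] - wide["CON_BSL"] - wide["INC_BSL"]) / 2
        t, _ = stats.ttest_1samp(contrast, 0.0)
        # mixed_anova needs two groups; build them by duplicating with new ids
        dup = summary.copy()
        dup["group_angle"] = 45
        dup["subject_id"] += 1000
        table = mixed_anova(pd.concat([summary, dup]), dependent="accuracy")
        f = table.loc[table.effect == "source", "F"].iloc[0]
        # duplicated groups double n; F should equal (sqrt(2)*t)^2 up to df
        assert f == pytest.approx(2 * t**2, rel=1e-6)


class TestPairedContrast:
    def test_identical_columns_give_null_result(self):
        rng = np.random.default_rng(0)
        summary = synth_summary(rng, n_per_group=5)
        wide = summary.pivot_table(index="subject_id", columns="condition",
                                   values="accuracy").reset_index()
        dup = summary.copy()
        dup.loc[dup.condition == "CON_BSL", "accuracy"] = (
            wide.set_index("subject_id").loc[dup.loc[dup.condition == "CON_BSL",
                                                     "subject_id"], "CON"].to_numpy())
        c = paired_contrast(dup, "CON", "CON_BSL")
        assert c.t == 0.0 and c.p == 1.0 and c.degenerate

    def test_constant_positive_difference_is_degenerate_infinite_t(self):
        rows = []
        for sid in range(5):
            rows.append(dict(subject_id=sid, group_angle=20, condition="CON",
                             accuracy=0.8, mean_rt=1.0, n_trials=96))
            rows.append(dict(subject_id=sid, group_angle=20, condition="CON_BSL",
                             accuracy=0.7, mean_rt=1.0, n_trials=96))
        c = paired_contrast(pd.DataFrame(rows), "CON", "CON_BSL")
        assert np.isinf(c.t) and c.t > 0 and c.degenerate

    def test_rejection_rate_matches_power(self):
        """Simulated d=0.5 at n=44 rejects at about the noncentral-t power."""
        rng = np.random.default_rng(8)
        n, d, reps = 44, 0.5, 400
        hits = 0
        for _ in range(reps):
            diff = rng.normal(d, 1.0, size=n)
            t, p = stats.ttest_1samp(diff, 0.0)
            hits += p < 0.05
        power = power_paired_t(n, d, 0.05)
        se = np.sqrt(power * (1 - power) / reps)
        assert hits / reps == pytest.approx(power, abs=4 * se)

    def test_missing_condition_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            paired_contrast(synth_summary(rng), "CON", "NOPE")


class TestPower:
    def test_preregistration_sample_size_has_90pct_power(self):
        assert power_paired_t(44, 0.5, 0.05) >= 0.90

    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.2):
            assert power_paired_t(30, 0.0, alpha) == pytest.approx(alpha, abs=1e-10)

    def test_power_increases_with_n(self):
        powers = [power_paired_t(n, 0.5) for n in (10, 20, 44, 100)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            power_paired_t(1, 0.5)
        with pytest.raises(ValueError):
            power_paired_t(44, 0.5, alpha=1.5)
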