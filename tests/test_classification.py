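"""Sample/participant classification, group assignment, tabulation, adherence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flavatrial import (
    CohortParams,
    adherence_summary,
    classify_participants,
    classify_samples,
    generate_cohort,
    tabulate,
)
from flavatrial.calibration import ThresholdPair
from flavatrial.classify import round_half_up_pct

from oracles import prob_above_background

T = ThresholdPair(18.2, 7.8)


def sample_row(pid, visit, gvlm, srem):
    return {"participant_id": pid, "visit": visit, "gvlm": gvlm, "srem": srem}


class TestSampleRule:
    @pytest.mark.parametrize(
        "gvlm, srem, expected",
        [
            (20.0, 1.0, True),   # gVLM alone suffices (OR rule)
            (1.0, 9.0, True),    # SREM alone suffices
            (0.0, 0.0, False),
            (18.2, 0.0, True),   # boundary counts as above
            (0.0, 7.8, True),
            (18.1999, 7.7999, False),
        ],
    )
    def test_or_rule_with_boundary(self, gvlm, srem, expected):
        samples = pd.DataFrame([sample_row(1, "baseline", gvlm, srem)])
        assert classify_samples(samples, T)["above"].iloc[0] == expected

    def test_both_missing_is_an_error(self):
        samples = pd.DataFrame([sample_row(1, "baseline", np.nan, np.nan)])
        with pytest.raises(ValueError, match="both biomarkers missing"):
            classify_samples(samples, T)

    def test_one_missing_uses_the_other(self):
        samples = pd.DataFrame([sample_row(1, "baseline", np.nan, 9.0)])
        assert classify_samples(samples, T)["above"].iloc[0]


class TestGroupAssignment:
    @pytest.mark.parametrize(
        "arm, base, fus, expected",
        [
            ("intervention", 1.0, [], "excluded"),          # below baseline, no follow-up
            ("placebo", 1.0, [], "biomarker_control"),      # exclusion is arm-specific
            ("intervention", 30.0, [], "biomarker_active"), # baseline above, no follow-up
            ("intervention", 30.0, [1.0, 1.0], "biomarker_active"),  # OR across visits
            ("placebo", 1.0, [1.0, 25.0], "biomarker_active"),
            ("intervention", 1.0, [1.0], "biomarker_control"),
        ],
    )
    def test_rule_table(self, arm, base, fus, expected):
        participants = pd.DataFrame({"participant_id": [1], "arm": [arm]})
        rows = [sample_row(1, "baseline", base, 0.1)]
        rows += [sample_row(1, f"year{k+1}", g, 0.1) for k, g in enumerate(fus)]
        cls = classify_participants(participants, pd.DataFrame(rows), T)
        assert cls["group"].iloc[0] == expected

    def test_no_baseline_flags_unclassifiable(self):
        participants = pd.DataFrame({"participant_id": [1, 2], "arm": ["placebo"] * 2})
        samples = pd.DataFrame(
            [sample_row(1, "baseline", 30.0, 0.1), sample_row(2, "year1", 30.0, 0.1)]
        )
        cls = classify_participants(participants, samples, T).set_index("participant_id")
        assert cls.loc[2, "group"] == "unclassifiable"
        assert cls.loc[1, "group"] == "biomarker_active"

    def test_duplicate_baseline_rejected(self):
        participants = pd.DataFrame({"participant_id": [1], "arm": ["placebo"]})
        samples = pd.DataFrame(
            [sample_row(1, "baseline", 1.0, 0.1), sample_row(1, "baseline", 2.0, 0.1)]
        )
        with pytest.raises(ValueError, match="multiple baseline"):
            classify_participants(participants, samples, T)


@settings(deadline=None, max_examples=15)
@given(seed=st.integers(0, 10_000), tg=st.floats(1.0, 50.0), ts=st.floats(1.0, 30.0))
def test_partition_and_determinism_properties(seed, tg, ts):
    """Groups always partition the cohort; classification is a pure function."""
    params = CohortParams(n_total=300, seed=seed)
    participants, samples, _, _, _ = generate_cohort(params)
    pair = ThresholdPair(tg, ts)
    cls1 = classify_participants(participants, samples, pair)
    cls2 = classify_participants(participants, samples, pair)
    pd.testing.assert_frame_equal(cls1, cls2)
    counts = cls1["group"].value_counts()
    assert counts.sum() == params.n_total
    assert set(counts.index) <= {
        "biomarker_active", "biomarker_control", "excluded", "unclassifiable"
    }


@settings(deadline=None, max_examples=10)
@given(seed=st.integers(0, 10_000))
def test_threshold_monotonicity(seed):
    """Raising either threshold never grows the active group and never
    shrinks the excluded group."""
    params = CohortParams(n_total=400, seed=seed)
    participants, samples, _, _, _ = generate_cohort(params)
    ladder = [ThresholdPair(5.0, 3.0), ThresholdPair(15.0, 3.0),
              ThresholdPair(15.0, 9.0), ThresholdPair(40.0, 25.0)]
    actives, excludeds = [], []
    for pair in ladder:
        cls = classify_participants(participants, samples, pair)
        actives.append((cls["group"] == "biomarker_active").sum())
        excludeds.append((cls["group"] == "excluded").sum())
    assert all(a >= b for a, b in zip(actives, actives[1:]))
    assert all(a <= b for a, b in zip(excludeds, excludeds[1:]))


class TestTabulate:
    def test_fixture_reproduces_printed_table(self, fixture_cohort, thresholds):
        participants, samples, _ = fixture_cohort
        cls = classify_participants(participants, samples, thresholds)
        t = tabulate(cls, participants, samples)
        assert (t["baseline"]["all"]["above"], t["baseline"]["all"]["pct"]) == (1249, 19)
        assert (t["baseline"]["placebo"]["above"], t["baseline"]["placebo"]["pct"]) == (603, 19)
        assert (t["baseline"]["intervention"]["above"], t["baseline"]["intervention"]["pct"]) == (646, 20)
        fu = t["followup_subset"]
        assert (fu["all"]["baseline"]["above"], fu["all"]["baseline"]["pct"]) == (414, 20)
        assert (fu["all"]["followup"]["above"], fu["all"]["followup"]["pct"]) == (881, 43)
        assert (fu["placebo"]["baseline"]["above"], fu["placebo"]["followup"]["above"]) == (186, 175)
        assert (fu["intervention"]["baseline"]["above"], fu["intervention"]["followup"]["above"]) == (228, 706)
        assert fu["intervention"]["followup"]["pct"] == 67

    def test_all_above_cohort_saturates(self):
        participants = pd.DataFrame(
            {"participant_id": range(4), "arm": ["placebo", "placebo", "intervention", "intervention"]}
        )
        rows = [sample_row(i, "baseline", 100.0, 50.0) for i in range(4)]
        rows += [sample_row(i, "year1", 100.0, 50.0) for i in range(2)]
        cls = classify_participants(participants, pd.DataFrame(rows), T)
        t = tabulate(cls, participants)
        assert t["baseline"]["all"]["pct"] == 100
        assert t["groups"]["excluded"]["n"] == 0
        assert t["groups"]["biomarker_active"]["n"] == 4

    def test_huge_thresholds_exclude_all_interv_without_followup(self, fixture_cohort):
        participants, samples, _ = fixture_cohort
        huge = ThresholdPair(1e6, 1e6)
        cls = classify_participants(participants, samples, huge)
        t = tabulate(cls, participants, samples)
        assert t["baseline"]["all"]["above"] == 0
        has_fu = set(samples.loc[samples["visit"] != "baseline", "participant_id"])
        expected = (
            (participants["arm"] == "intervention")
            & ~participants["participant_id"].isin(has_fu)
        ).sum()
        assert t["groups"]["excluded"]["n"] == expected

    def test_empty_denominator_reported_as_undefined(self):
        assert round_half_up_pct(0, 0) is None


class TestAdherence:
    def test_fixture_biomarker_and_selfreport_adherence(self, fixture_cohort, thresholds):
        participants, samples, reports = fixture_cohort
        cls = classify_participants(participants, samples, thresholds)
        summary = adherence_summary(cls, reports)
        assert summary["biomarker_adherence_pct"] == 67
        assert summary["selfreport_adherence_pct"] == 85

    def test_all_adherent_reports_give_full_selfreport_adherence(self, fixture_cohort, thresholds):
        participants, samples, reports = fixture_cohort
        cls = classify_participants(participants, samples, thresholds)
        clean = reports.assign(status="adherent")
        assert adherence_summary(cls, clean)["selfreport_adherence_pct"] == 100

    def test_biomarker_adherence_matches_misclassification_adjusted_oracle(self):
        """At scale, measured adherence is p_adh * P(above | dosed) +
        (1 - p_adh) * P(above | background only) — not p_adh itself."""
        null_hr = {k: 0.0 for k in ("total_cvd", "cvd_mortality", "all_cause_mortality", "major_cvd")}
        params = CohortParams(n_total=50000, seed=17, true_log_hr=null_hr)
        participants, samples, reports, _, _ = generate_cohort(params)
        cls = classify_participants(participants, samples, T)
        frac = adherence_summary(cls, reports)["biomarker_adherence_frac"]
        p_above_dosed = prob_above_background(params, T, extra_dose=params.dose_ref)
        p_above_bg = prob_above_background(params, T)
        oracle = params.p_adherent * p_above_dosed + (1 - params.p_adherent) * p_above_bg
        n = ((participants["arm"] == "intervention")).sum() * params.p_followup_sample
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert abs(frac - oracle) < 3 * se
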