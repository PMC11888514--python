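"""Cox fitting, per-protocol censoring, contrasts, imputation, incidence curves."""

import numpy as np
import pandas as pd
import pytest

from flavatrial import (
    COSMOS_THRESHOLDS,
    CohortParams,
    classify_participants,
    cumulative_incidence,
    fit_cox,
    generate_cohort,
    impute_missing,
    pool_cox_results,
    pp_censor,
    run_contrasts,
)
from flavatrial.cohort import inject_mcar
from flavatrial.survival import (
    MODEL_SPECS,
    NotEstimableError,
    SurvivalDataset,
    build_survival_dataset,
)

from oracles import breslow_baseline_cumhaz, cox_loghr_brute


def exposure_dataset(frame):
    return SurvivalDataset("total_cvd", "itt", 0, frame)


class TestFitCox:
    def test_null_two_group_recovery(self):
        rng = np.random.default_rng(1)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / 0.05, n)
        frame = pd.DataFrame(
            {"exposure": x, "time": np.minimum(t, 10.0), "event": t <= 10.0}
        )
        res = fit_cox(exposure_dataset(frame))
        assert abs(res.log_hr) < 3 * res.log_hr_se
        assert res.ci_low <= res.hr <= res.ci_high

    def test_six_subject_brute_force_oracle(self):
        """Log-HR equals grid maximization of the explicit partial likelihood."""
        frame = pd.DataFrame(
            {
                "exposure": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
                "time": [1.3, 2.1, 5.4, 0.9, 3.3, 4.2],
                "event": [True, True, False, True, True, True],
            }
        )
        res = fit_cox(exposure_dataset(frame))
        oracle = cox_loghr_brute(frame["exposure"], frame["time"], frame["event"])
        assert res.log_hr == pytest.approx(oracle, abs=1e-4)

    def test_generator_truth_recovered_with_perfect_classification(self):
        params = CohortParams(n_total=20000, seed=21)
        participants, _, _, events, _ = generate_cohort(params)
        ev = events[events["endpoint"] == "total_cvd"]
        frame = participants[["participant_id", "true_exposed"]].merge(ev, on="participant_id")
        ds = exposure_dataset(
            pd.DataFrame(
                {
                    "exposure": frame["true_exposed"].astype(float),
                    "time": frame["time"],
                    "event": frame["event"],
                }
            )
        )
        res = fit_cox(ds)
        truth = params.true_log_hr["total_cvd"]
        # composite endpoint: CVD-death component has its own log-HR, so allow
        # the blend a small systematic offset on top of sampling error
        assert abs(res.log_hr - truth) < 3 * res.log_hr_se + 0.02

    def test_empty_or_eventless_group_not_estimable(self):
        frame = pd.DataFrame(
            {"exposure": [1.0, 1.0, 0.0], "time": [1.0, 2.0, 3.0], "event": [True, True, False]}
        )
        with pytest.raises(NotEstimableError, match="events"):
            fit_cox(exposure_dataset(frame))
        frame_all_one = frame.assign(exposure=1.0)
        with pytest.raises(NotEstimableError, match="rows"):
            fit_cox(exposure_dataset(frame_all_one))


class TestPPCensor:
    def reports(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "report_date", "status"])

    def events(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "endpoint", "time", "event"])

    def test_all_adherent_changes_nothing(self):
        ev = self.events([(1, "total_cvd", 3.0, True)])
        rep = self.reports([(1, 182, "adherent"), (1, 364, "adherent")])
        out = pp_censor(ev, rep)
        pd.testing.assert_frame_equal(out, ev)

    def test_censors_at_first_bad_report(self):
        ev = self.events([(1, "total_cvd", 500 / 365.25, True)])
        rep = self.reports([(1, 182, "adherent"), (1, 365, "missed_gt8_per_month")])
        out = pp_censor(ev, rep)
        assert not out["event"].iloc[0]
        assert out["time"].iloc[0] == pytest.approx(365 / 365.25)

    def test_report_after_event_ignored_with_diagnostic(self):
        ev = self.events([(1, "total_cvd", 0.5, True)])
        rep = self.reports([(1, 364, "unsure")])
        out, diag = pp_censor(ev, rep, return_diagnostics=True)
        pd.testing.assert_frame_equal(out, ev)
        assert diag["n_reports_after_event"] == 1

    def test_pp_never_gains_events_and_matches_enumeration(self, small_cohort):
        """Censored-row set equals a direct per-participant enumeration of
        first-bad-report times, and events never increase."""
        _, participants, _, reports, events = small_cohort
        ev = events[events["endpoint"] == "total_cvd"].reset_index(drop=True)
        out = pp_censor(ev, reports)
        assert out["event"].sum() <= ev["event"].sum()

        bad_statuses = {"missed_gt8_per_month", "unsure", "outside_supplement_use"}
        first_bad = {}
        for pid, grp in reports.groupby("participant_id"):
            bad = grp[grp["status"].isin(bad_statuses)]
            if len(bad):
                first_bad[pid] = bad["report_date"].min() / 365.25
        expected_changed = {
            row.participant_id
            for row in ev.itertuples()
            if row.participant_id in first_bad and first_bad[row.participant_id] < row.time
        }
        changed = set(ev.loc[(out["time"] != ev["time"]) | (out["event"] != ev["event"]),
                             "participant_id"])
        assert changed == expected_changed
        for pid in changed:
            assert out.loc[out["participant_id"] == pid, "time"].iloc[0] == pytest.approx(
                first_bad[pid]
            )


class TestContrasts:
    def test_no_misclassification_aligns_all_contrasts(self):
        """With no background intake and full adherence, ITT, PP and biomarker
        contrasts estimate the same quantity."""
        params = CohortParams(
            n_total=12000, seed=23, p_background_high=0.0, p_background_zero=0.0,
            p_adherent=1.0,
            p_selfreport_nonadherent_given_adherent=0.0,
        )
        participants, samples, reports, events, _ = generate_cohort(params)
        cls = classify_participants(participants, samples, COSMOS_THRESHOLDS)
        table, _ = run_contrasts(
            participants, events, self_reports=reports, classifications=cls,
            model_ids=[0], endpoints=["total_cvd"],
        )
        t = table.set_index("contrast")
        for a, b in (("itt", "pp"), ("itt", "biomarker")):
            diff = abs(t.loc[a, "log_hr"] - t.loc[b, "log_hr"])
            se = np.hypot(t.loc[a, "log_hr_se"], t.loc[b, "log_hr_se"])
            assert diff < 3 * se

    def test_model4_se_not_smaller_than_model2(self, small_cohort):
        """Adjusting the biomarker contrast for randomization is collinear
        with exposure and cannot sharpen it."""
        _, participants, samples, _, events = small_cohort
        cls = classify_participants(participants, samples, COSMOS_THRESHOLDS)
        table, _ = run_contrasts(
            participants, events, classifications=cls,
            model_ids=[2, 4], endpoints=["total_cvd"], contrasts=("biomarker",),
        )
        t = table.set_index("model")
        assert t.loc[4, "log_hr_se"] >= t.loc[2, "log_hr_se"]
        assert t.loc[4, "n"] == t.loc[2, "n"]

    def test_model_nesting(self):
        names = {m: set(dict(MODEL_SPECS[m].covariates)) for m in (1, 2, 3)}
        assert names[1] < names[2] < names[3]
        assert set(dict(MODEL_SPECS[4].covariates)) == set(dict(MODEL_SPECS[2].covariates)) | {"randomization"}
        assert set(dict(MODEL_SPECS[5].covariates)) == set(dict(MODEL_SPECS[2].covariates)) | {"ahei"}

    def test_empty_contrast_cell_reported_not_estimable(self, small_cohort):
        _, participants, samples, _, events = small_cohort
        from flavatrial.calibration import ThresholdPair

        cls = classify_participants(participants, samples, ThresholdPair(1e9, 1e9))
        table, _ = run_contrasts(
            participants, events, classifications=cls,
            model_ids=[0], endpoints=["total_cvd"], contrasts=("biomarker",),
        )
        assert table["hr"].isna().all()
        assert table["note"].str.contains("not estimable").all()


class TestImputation:
    def fit_frame(self, small_cohort, frame):
        ds = SurvivalDataset("total_cvd", "itt", 2, frame)
        return fit_cox(ds)

    def test_no_missingness_reduces_to_single_fit(self, small_cohort):
        _, participants, _, _, events = small_cohort
        ds = build_survival_dataset(participants, events, "total_cvd", "itt", 2)
        completed = impute_missing(ds.frame, m=3, seed=1)
        assert len(completed) == 3
        for c in completed:
            pd.testing.assert_frame_equal(c, ds.frame)
        fits = [self.fit_frame(small_cohort, c) for c in completed]
        pooled = pool_cox_results(fits)
        single = fits[0]
        assert pooled.log_hr == pytest.approx(single.log_hr, abs=1e-12)
        assert pooled.log_hr_se == pytest.approx(single.log_hr_se, abs=1e-12)
        assert pooled.ci_low == pytest.approx(single.ci_low, abs=1e-9)

    def test_mcar_pooled_close_to_complete_data(self, small_cohort):
        _, participants, _, _, events = small_cohort
        ds = build_survival_dataset(participants, events, "total_cvd", "itt", 2)
        complete = self.fit_frame(small_cohort, ds.frame)
        holey = inject_mcar(ds.frame, ["bmi"], 0.10, seed=3)
        fits = [self.fit_frame(small_cohort, c) for c in impute_missing(holey, m=5, seed=5)]
        pooled = pool_cox_results(fits)
        assert pooled.n_imputations_pooled == 5
        assert abs(pooled.log_hr - complete.log_hr) < 3 * complete.log_hr_se

    def test_identical_fits_pool_with_zero_between_variance(self, small_cohort):
        _, participants, _, _, events = small_cohort
        ds = build_survival_dataset(participants, events, "total_cvd", "itt", 0)
        fit = fit_cox(ds)
        pooled = pool_cox_results([fit, fit, fit])
        assert pooled.log_hr_se == pytest.approx(fit.log_hr_se, abs=1e-14)

    def test_all_missing_column_is_error(self, small_cohort):
        _, participants, _, _, events = small_cohort
        ds = build_survival_dataset(participants, events, "total_cvd", "itt", 2)
        frame = ds.frame.assign(bmi=np.nan)
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(frame, m=2)


class TestCumulativeIncidence:
    def test_null_exponential_closed_form(self):
        rng = np.random.default_rng(4)
        lam, n = 0.08, 20000
        t = rng.exponential(1.0 / lam, n)
        frame = pd.DataFrame(
            {
                "exposure": rng.integers(0, 2, n).astype(float),
                "time": np.minimum(t, 10.0),
                "event": t <= 10.0,
            }
        )
        res = fit_cox(exposure_dataset(frame))
        curve = cumulative_incidence(res, group=0, model=0)
        grid = curve["time"].between(1.0, 8.0)
        expected = 1.0 - np.exp(-lam * curve.loc[grid, "time"])
        assert np.allclose(curve.loc[grid, "incidence"], expected, atol=0.02)
        assert (np.diff(curve["incidence"]) >= -1e-12).all()
        assert curve["incidence"].iloc[0] <= 1e-3

    def test_groups_differ_by_log_hr_on_cumhaz_scale(self, small_cohort):
        _, participants, _, _, events = small_cohort
        ds = build_survival_dataset(participants, events, "total_cvd", "itt", 0)
        res = fit_cox(ds)
        c1 = cumulative_incidence(res, group=1, model=0)
        c0 = cumulative_incidence(res, group=0, model=0)
        h1 = -np.log(1.0 - c1["incidence"].to_numpy())
        h0 = -np.log(1.0 - c0["incidence"].to_numpy())
        pos = h0 > 1e-10
        assert np.allclose(np.log(h1[pos]) - np.log(h0[pos]), res.log_hr, atol=1e-8)

    def test_matches_independent_breslow_computation(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(-0.5 * x)), n)
        frame = pd.DataFrame({"exposure": x, "time": np.minimum(t, 8.0), "event": t <= 8.0})
        res = fit_cox(exposure_dataset(frame))
        curve = cumulative_incidence(res, group=1, model=0)
        oracle_h0 = breslow_baseline_cumhaz(
            x, frame["time"], frame["event"], res.log_hr, curve["time"]
        )
        expected = 1.0 - np.exp(-oracle_h0 * np.exp(res.log_hr))
        assert np.allclose(curve["incidence"], expected, atol=1e-6)
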