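import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from jaderpv import (
    HazardClass,
    ReportDatabase,
    WeibullFit,
    WeibullOnsetModel,
    classify_hazard,
    compute_durations,
    fit_weibull,
    onset_histogram,
    summarize,
)
from jaderpv.time_to_onset import fit_exponential_scale

#: fixed 20-point duration sample used for oracle comparisons
TOY_SAMPLE = np.array([1, 2, 2, 3, 4, 5, 6, 7, 8, 9,
                       10, 12, 14, 15, 18, 21, 25, 30, 40, 55], dtype=float)


def _db(drug_rows, reac_rows):
    demo = pd.DataFrame(
        {
            "report_id": sorted({r[0] for r in drug_rows} | {r[0] for r in reac_rows}),
        }
    )
    demo["sex"] = "male"
    demo["age_band"] = "40s"
    demo["reporting_year"] = "2010"
    drug = pd.DataFrame(drug_rows,
                        columns=["report_id", "drug_name", "role_code", "start_date"])
    reac = pd.DataFrame(reac_rows, columns=["report_id", "pt_code", "onset_date"])
    hist = pd.DataFrame({"report_id": [], "primary_illness": []})
    return ReportDatabase(demo=demo, drug=drug, reac=reac, hist=hist)


class TestComputeDurations:
    def test_simple_calendar_arithmetic(self):
        db = _db(
            [("R1", "drugx", "suspected", "2010-03-01")],
            [("R1", "10042033", "2010-03-04")],
        )
        dur, excl = compute_durations(db, {"drugx"})
        assert dur["duration_days"].tolist() == [3.0]

    def test_earliest_start_date_wins(self):
        db = _db(
            [("R1", "drugx", "suspected", "2010-03-01"),
             ("R1", "drugx", "suspected", "2010-02-20")],
            [("R1", "10042033", "2010-03-01")],
        )
        dur, _ = compute_durations(db, {"drugx"})
        assert dur["duration_days"].tolist() == [9.0]

    def test_onset_before_start_excluded_and_counted(self):
        db = _db(
            [("R1", "drugx", "suspected", "2010-03-10")],
            [("R1", "10042033", "2010-03-01")],
        )
        dur, excl = compute_durations(db, {"drugx"})
        assert dur.empty and excl["negative_duration"] == 1

    def test_partial_precision_dates_excluded_and_counted(self):
        db = _db(
            [("R1", "drugx", "suspected", "2010-03"),
             ("R2", "drugx", "suspected", "2010-03-01")],
            [("R1", "10042033", "2010-03-20"),
             ("R2", "10042033", "2010-04")],
        )
        dur, excl = compute_durations(db, {"drugx"})
        assert dur.empty
        assert excl["incomplete_start_date"] == 1
        assert excl["incomplete_onset_date"] == 1

    def test_earliest_event_kept_when_multiple(self):
        db = _db(
            [("R1", "drugx", "suspected", "2010-03-01")],
            [("R1", "10042033", "2010-03-10"),
             ("R1", "10044223", "2010-03-05")],
        )
        dur, excl = compute_durations(db, {"drugx"})
        assert dur["duration_days"].tolist() == [4.0]
        assert excl["extra_events_collapsed"] == 1

    def test_non_suspected_roles_do_not_enter(self):
        db = _db(
            [("R1", "drugx", "concomitant", "2010-03-01")],
            [("R1", "10042033", "2010-03-04")],
        )
        dur, _ = compute_durations(db, {"drugx"})
        assert dur.empty

    def test_non_case_reports_do_not_enter(self):
        db = _db(
            [("R1", "drugx", "suspected", "2010-03-01")],
            [("R1", "PT900001", "2010-03-04")],
        )
        dur, _ = compute_durations(db, {"drugx"})
        assert dur.empty


class TestSummarize:
    def test_inclusive_quartiles(self):
        s = summarize([1, 2, 3, 8, 20])
        assert s.median == 3
        assert s.lower_quartile == pytest.approx(1.5)
        assert s.upper_quartile == pytest.approx(14.0)
        assert s.minimum == 1 and s.maximum == 20

    def test_single_value(self):
        s = summarize([7])
        assert (s.median, s.lower_quartile, s.upper_quartile,
                s.minimum, s.maximum) == (7, 7, 7, 7, 7)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize([])

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_ordering_invariant(self, values):
        s = summarize(values)
        assert (s.minimum <= s.lower_quartile <= s.median
                <= s.upper_quartile <= s.maximum)

    def test_matches_generating_quantiles_at_moderate_n(self):
        rng = np.random.default_rng(42)
        scale, shape, n = 9.44, 0.64, 340
        t = scale * rng.weibull(shape, n)
        s = summarize(t)
        med = scale * np.log(2) ** (1 / shape)
        # median of 340 draws: sampling error a few times f(median)^-1/sqrt(n)
        assert abs(s.median - med) < 1.5


class TestFitWeibull:
    def test_shape_fixed_at_one_scale_is_sample_mean(self):
        t = np.array([1.0, 3.0, 4.0, 10.0, 2.0])
        assert fit_exponential_scale(t) == pytest.approx(t.mean())

    def test_matches_scipy_and_lifelines(self):
        from scipy import stats as ss
        lifelines = pytest.importorskip("lifelines")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_weibull(TOY_SAMPLE)
        c, _, sc = ss.weibull_min.fit(TOY_SAMPLE, floc=0)
        assert fit.shape == pytest.approx(c, rel=1e-4)
        assert fit.scale == pytest.approx(sc, rel=1e-4)
        wf = lifelines.WeibullFitter().fit(TOY_SAMPLE)
        assert fit.scale == pytest.approx(wf.lambda_, rel=1e-4)
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-4)

    def test_loglik_dominates_surrounding_grid(self):
        from jaderpv.time_to_onset import _weibull_loglik
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_weibull(TOY_SAMPLE)
        scales = np.linspace(fit.scale * 0.5, fit.scale * 1.5, 200)
        shapes = np.linspace(fit.shape * 0.5, fit.shape * 1.5, 200)
        grid = np.array([[_weibull_loglik(TOY_SAMPLE, a, b) for a in scales]
                         for b in shapes])
        assert fit.loglik >= grid.max() - 1e-9

    def test_zero_durations_shifted_not_dropped(self):
        t = np.r_[np.zeros(5), np.linspace(1, 30, 45)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_weibull(t)
        assert fit.n == 50 and fit.converged

    def test_sample_floor_enforced_and_small_n_warns(self):
        with pytest.raises(ValueError):
            fit_weibull([1.0] * 5)
        with pytest.warns(UserWarning, match="cautiously"):
            fit_weibull(TOY_SAMPLE)

    def test_wald_ci_contains_estimate(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_weibull(TOY_SAMPLE)
        assert fit.scale_ci[0] < fit.scale < fit.scale_ci[1]
        assert fit.shape_ci[0] < fit.shape < fit.shape_ci[1]

    def test_profile_ci_close_to_wald_at_moderate_n(self):
        rng = np.random.default_rng(3)
        t = 10.0 * rng.weibull(0.8, 400)
        wald = fit_weibull(t, ci_method="wald")
        prof = fit_weibull(t, ci_method="profile")
        for w, p in zip(wald.shape_ci + wald.scale_ci,
                        prof.shape_ci + prof.scale_ci):
            assert p == pytest.approx(w, rel=0.15)

    @given(k=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, k):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = fit_weibull(TOY_SAMPLE)
            scaled = fit_weibull(TOY_SAMPLE * k)
        assert scaled.shape == pytest.approx(base.shape, rel=1e-6)
        assert scaled.scale == pytest.approx(base.scale * k, rel=1e-6)

    def test_degenerate_sample_is_error(self):
        with pytest.raises(ValueError):
            fit_weibull([3.0] * 20)

    def test_negative_durations_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull([-1.0] + [2.0] * 19)


class TestClassifyHazard:
    def _fit(self, shape, lo, hi):
        return WeibullFit(scale=10.0, shape=shape, scale_ci=(8.0, 12.0),
                          shape_ci=(lo, hi), n=100, loglik=-1.0, converged=True)

    @pytest.mark.parametrize(
        "shape,lo,hi,expected",
        [
            (0.64, 0.59, 0.69, HazardClass.DECREASING),
            (1.02, 0.94, 1.10, HazardClass.CONSTANT_COMPATIBLE),
            (1.17, 1.00, 1.35, HazardClass.CONSTANT_COMPATIBLE),  # bound touches 1
            (1.30, 1.05, 1.61, HazardClass.INCREASING),
            (0.81, 0.65, 1.00, HazardClass.CONSTANT_COMPATIBLE),
        ],
    )
    def test_rules(self, shape, lo, hi, expected):
        assert classify_hazard(self._fit(shape, lo, hi)) is expected

    def test_nonconverged_fit_rejected(self):
        fit = self._fit(0.6, 0.5, 0.7)
        fit.converged = False
        with pytest.raises(ValueError):
            classify_hazard(fit)

    def test_exponential_data_usually_constant_compatible(self):
        # CI calibration smoke check: shape=1 data should rarely be called
        # increasing or decreasing
        rng = np.random.default_rng(7)
        calls = []
        for _ in range(60):
            t = rng.exponential(15.0, 150)
            calls.append(classify_hazard(fit_weibull(t)))
        frac_const = np.mean([c is HazardClass.CONSTANT_COMPATIBLE for c in calls])
        assert frac_const > 0.85


class TestOnsetHistogram:
    def test_small_example(self):
        h = onset_histogram([0, 1, 1, 3]).set_index("day")["count"]
        assert h["0"] == 1 and h["1"] == 2 and h["3"] == 1
        assert h.sum() == 4

    def test_all_overflow(self):
        h = onset_histogram([60, 70, 100])
        assert h.iloc[-1]["count"] == 3
        assert h.iloc[:-1]["count"].sum() == 0

    def test_early_onset_mass_for_short_latency_drug(self):
        # acetaminophen-like latencies: more than half of onsets within 4 days
        rng = np.random.default_rng(11)
        t = np.rint(6.17 * rng.weibull(0.74, 310))
        h = onset_histogram(t).set_index("day")["count"]
        first5 = h[[str(d) for d in range(5)]].sum()  # days 0-4
        assert first5 / len(t) > 0.5


class TestEstimator:
    def test_fitted_attributes_and_classification(self):
        rng = np.random.default_rng(2)
        t = 9.44 * rng.weibull(0.64, 340)
        m = WeibullOnsetModel().fit(t)
        assert m.n_ == 340 and m.converged_
        assert m.shape_ci_[0] < m.shape_ < m.shape_ci_[1]
        assert m.hazard_class_ is HazardClass.DECREASING
        s = m.survival_function([0.0, m.scale_])
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(np.exp(-1.0))

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone
        m = WeibullOnsetModel(zero_shift=0.25)
        assert clone(m).get_params()["zero_shift"] == 0.25
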