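"""Kaplan-Meier, log-rank, Cox regression and the prognostic cutoff scan."""

import numpy as np
import pandas as pd
import pytest

from timascan.survival import (SurvivalError, cox_fit, km_estimate, logrank_test,
                               max_median_diff_cutoff, MaxMedianDiffCutoff,
                               SELECTION_WARNING)


class TestKaplanMeier:
    def test_product_limit_steps_without_censoring(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [1.0, 0.8, 0.6, 0.4, 0.2, 0.0])
        assert km.survival[0] == 1.0  # S(0) = 1
        assert km.median_survival == 3

    def test_no_censoring_reproduces_empirical_survival(self, rng):
        times = rng.exponential(5.0, 60)
        km = km_estimate(times, np.ones(60, bool))
        for grid_t, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(times > grid_t))

    def test_exponential_median_close_to_ln2_over_lambda(self, rng):
        medians = [km_estimate(rng.exponential(10.0, 500),
                               np.ones(500, bool)).median_survival
                   for _ in range(10)]
        assert np.mean(medians) == pytest.approx(np.log(2) * 10, rel=0.10)

    def test_all_censored_curve_has_undefined_median(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.median_survival is None
        assert (km.survival == 1.0).all()


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [1] * 10
        group = [True] * 5 + [False] * 5
        chi2, df, p = logrank_test(times, events, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_invariant_under_arm_relabeling(self, rng):
        times = rng.exponential(5, 80)
        events = rng.random(80) < 0.8
        group = rng.random(80) < 0.5
        a = logrank_test(times, events, group)
        b = logrank_test(times, events, ~group)
        assert a[0] == pytest.approx(b[0])

    def test_no_events_is_an_error(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [1, 1, 0, 0])

    def test_power_under_proportional_hazards(self, rng):
        hits, reps = 0, 40
        for _ in range(reps):
            t0 = rng.exponential(10, 150)
            t1 = rng.exponential(5, 150)  # HR 2
            times = np.r_[t0, t1]
            events = np.ones(300, bool)
            group = np.repeat([False, True], 150)
            hits += logrank_test(times, events, group)[2] < 0.05
        assert hits / reps >= 0.90 - 3 * np.sqrt(0.9 * 0.1 / reps)


def _ph_frame(rng, n=400, log_hr=np.log(2)):
    x = (rng.random(n) < 0.5).astype(float)
    u = rng.random(n)
    t = 10.0 * (-np.log(u) / np.exp(log_hr * x)) ** (1 / 1.5)
    c = rng.uniform(0, 30, n)
    return pd.DataFrame({"t": np.minimum(t, c), "e": t <= c, "x": x})


class TestCox:
    def test_recovers_log_hazard_ratio(self, rng):
        coefs = [cox_fit(_ph_frame(rng), "t", "e", ["x"]).coefficients[0]
                 for _ in range(10)]
        assert np.mean(coefs) == pytest.approx(np.log(2), abs=0.15)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        """Breslow == Efron without ties; lifelines is the independent check."""
        import lifelines
        df = _ph_frame(rng, n=150)
        fit = cox_fit(df, "t", "e", ["x"], ties="breslow")
        ll = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert fit.coefficients[0] == pytest.approx(ll.params_["x"], abs=1e-6)
        assert fit.standard_errors[0] == pytest.approx(
            ll.standard_errors_["x"], abs=1e-6)
        efron = cox_fit(df, "t", "e", ["x"], ties="efron")
        assert efron.coefficients[0] == pytest.approx(fit.coefficients[0],
                                                      abs=1e-9)

    def test_zero_variance_covariate_is_an_error(self, rng):
        df = _ph_frame(rng, n=50)
        df["const"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            cox_fit(df, "t", "e", ["const"])

    def test_coefficients_rescale_exactly_under_scaling(self, rng):
        df = _ph_frame(rng, n=200)
        df["x10"] = df["x"] * 10 + 3
        a = cox_fit(df, "t", "e", ["x"])
        b = cox_fit(df, "t", "e", ["x10"])
        assert b.coefficients[0] * 10 == pytest.approx(a.coefficients[0],
                                                       rel=1e-6)
        assert b.model_chi_square == pytest.approx(a.model_chi_square, rel=1e-9)

    def test_missing_rows_excluded_and_counted(self, rng):
        df = _ph_frame(rng, n=100)
        df.loc[:9, "x"] = np.nan
        fit = cox_fit(df, "t", "e", ["x"])
        assert fit.n == 90 and fit.n_excluded_missing == 10

    def test_ties_methods_differ_with_ties(self, rng):
        df = _ph_frame(rng, n=120)
        df["t"] = np.ceil(df["t"])  # force heavy ties
        br = cox_fit(df, "t", "e", ["x"], ties="breslow")
        ef = cox_fit(df, "t", "e", ["x"], ties="efron")
        assert br.coefficients[0] != pytest.approx(ef.coefficients[0], abs=1e-9)


def _km_median_oracle(times, events):
    """Independent product-limit median (direct loop, no lifelines)."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s, at_risk = 1.0, len(times)
    i = 0
    while i < len(times):
        j = i
        d = 0
        while j < len(times) and times[j] == times[i]:
            d += int(events[j])
            j += 1
        if d:
            s *= 1 - d / at_risk
            if s <= 0.5 + 1e-9:
                return float(times[i])
        at_risk -= j - i
        i = j
    return None


def _brute_force_scan(df, min_arm_fraction=0.10):
    values = df["m"].to_numpy(float)
    n = len(df)
    min_arm = max(int(np.ceil(min_arm_fraction * n)), 1)
    best = None
    for cut in np.unique(values):
        high = values >= cut
        if high.sum() < min_arm or (~high).sum() < min_arm:
            continue
        mh = _km_median_oracle(df["t"][high], df["e"][high])
        ml = _km_median_oracle(df["t"][~high], df["e"][~high])
        if mh is None or ml is None:
            continue
        key = (-abs(mh - ml), cut)
        if best is None or key < best[0]:
            best = (key, float(cut), mh, ml)
    return best


class TestCutoffScan:
    def _frame(self, rng, n=60):
        m = rng.choice([5.0, 10.0, 15.0, 20.0, 25.0, 30.0], size=n)
        lam = np.where(m >= 20.0, 6.0, 12.0)
        return pd.DataFrame({
            "m": m,
            "t": rng.exponential(lam),
            "e": rng.random(n) < 0.85,
        })

    def test_matches_exhaustive_scan(self, rng):
        agreements = 0
        total = 60
        for _ in range(total):
            df = self._frame(rng)
            oracle = _brute_force_scan(df)
            if oracle is None:
                continue
            try:
                res = max_median_diff_cutoff(df, "m", "t", "e", force=True)
            except SurvivalError:
                continue
            assert res.cutoff == oracle[1]
            assert res.median_high == pytest.approx(oracle[2])
            assert res.median_low == pytest.approx(oracle[3])
            agreements += 1
        assert agreements >= 40  # most random instances are admissible

    def test_screen_gatekeeping_refuses_null_marker(self, rng):
        df = self._frame(rng, n=80)
        # marker independent of survival, from its own stream
        df["null_m"] = np.random.default_rng(101).normal(size=80)
        with pytest.raises(SurvivalError, match="scan refused"):
            max_median_diff_cutoff(df, "null_m", "t", "e")
        res = max_median_diff_cutoff(df, "null_m", "t", "e", force=True)
        assert res.screen_p >= 0.05

    def test_result_carries_multiple_testing_warning(self, rng):
        res = max_median_diff_cutoff(self._frame(rng), "m", "t", "e",
                                     force=True)
        assert res.multiple_testing_warning == SELECTION_WARNING
        assert res.logrank_df == 1

    def test_no_admissible_cutoff_is_explicit(self, rng):
        df = self._frame(rng, n=30)
        df["e"] = False
        df.loc[0, "e"] = True  # one event: medians undefined everywhere
        with pytest.raises(SurvivalError, match="no admissible cutoff"):
            max_median_diff_cutoff(df, "m", "t", "e", force=True)

    def test_adjusted_cox_reports_arm_hazard_ratio(self, rng):
        df = self._frame(rng, n=120)
        df["age"] = rng.normal(60, 10, 120)
        res = max_median_diff_cutoff(df, "m", "t", "e", covariates=["age"],
                                     force=True)
        assert res.adjusted_cox is not None
        assert res.adjusted_cox.df == 2
        assert res.adjusted_cox.covariates[0] == "_high_arm"


def test_estimator_protocol(rng):
    from sklearn.base import clone
    est = MaxMedianDiffCutoff(force=True)
    clone(est)
    df = TestCutoffScan()._frame(rng, n=100)
    est.fit(df[["m"]].to_numpy(), np.c_[df["t"], df["e"].astype(float)])
    assert est.cutoff_ in np.unique(df["m"])
    preds = est.predict(df[["m"]].to_numpy())
    assert preds.dtype == bool
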