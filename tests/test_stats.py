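"""Wilson intervals, common-effect pooling, natural-spline logistic model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

from equamu.stats import (AgeSplineModel, SeparationError,
                          natural_spline_basis, pooled_prevalence, round_pct,
                          wilson_interval, yearly_trend)


class TestWilson:
    @pytest.mark.parametrize("k,n", [
        (0, 10), (1, 10), (10, 10), (7, 100), (70, 1000),
        (15709, 225622), (68, 300), (1, 2), (499, 500),
    ])
    def test_matches_statsmodels_wilson(self, k, n):
        est = wilson_interval(k, n)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert est.lower == pytest.approx(lo, abs=1e-12)
        assert est.upper == pytest.approx(hi, abs=1e-12)

    def test_zero_successes_lower_bound_is_exactly_zero(self):
        assert wilson_interval(0, 10).lower == 0.0

    def test_zero_successes_upper_matches_score_equation_root(self):
        # independent oracle: numeric root of the score equation
        # (p_hat - p)^2 = z^2 p (1 - p) / n at p_hat = 0
        n, z = 10, sps.norm.ppf(0.975)
        root = brentq(lambda p: p * p - z * z * p * (1 - p) / n, 1e-12, 0.9)
        assert wilson_interval(0, n).upper == pytest.approx(root, abs=1e-10)

    def test_interval_contains_point_estimate(self):
        for k, n in [(0, 5), (3, 9), (50, 51), (7, 100)]:
            est = wilson_interval(k, n)
            assert est.lower <= est.point <= est.upper

    def test_reflection_under_success_failure_swap(self):
        a = wilson_interval(3, 10)
        b = wilson_interval(7, 10)
        assert a.lower == pytest.approx(1 - b.upper, abs=1e-12)
        assert a.upper == pytest.approx(1 - b.lower, abs=1e-12)

    def test_empirical_coverage_matches_analytic_coverage(self):
        # one grid cell, checked against the exact (pmf-sum) coverage
        n, p, reps = 300, 0.5, 4000
        rng = np.random.default_rng(5)
        k = rng.binomial(n, p, reps)
        lo, hi = wilson_interval(k, np.full(reps, n))
        emp = np.mean((lo <= p) & (p <= hi))
        kk = np.arange(n + 1)
        alo, ahi = wilson_interval(kk, np.full(n + 1, n))
        exact = sps.binom.pmf(kk, n, p)[(alo <= p) & (p <= ahi)].sum()
        assert emp == pytest.approx(exact, abs=4 * np.sqrt(exact * (1 - exact) / reps))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 3)

    def test_percentage_rounding_is_half_up(self):
        assert round_pct(2.25, 1) == 2.3
        assert round_pct(2.249, 1) == 2.2


class TestPooledPrevalence:
    def test_single_practice_identity(self):
        m = pooled_prevalence([(70, 1000)])
        assert m.point == pytest.approx(0.07, abs=1e-9)

    def test_two_identical_practices_narrow_the_interval(self):
        one = pooled_prevalence([(50, 1000)])
        two = pooled_prevalence([(50, 1000), (50, 1000)])
        assert two.point == pytest.approx(0.05, abs=1e-9)
        assert (two.upper - two.lower) < (one.upper - one.lower)

    def test_identical_proportions_pool_to_that_proportion(self):
        m = pooled_prevalence([(5, 100), (50, 1000), (500, 10000)])
        assert m.point == pytest.approx(0.05, abs=1e-9)

    def test_raw_scale_matches_closed_form_inverse_variance_mean(self):
        counts = [(30, 1000), (50, 1000), (70, 1000)]
        m = pooled_prevalence(counts, transform="raw")
        p = np.array([k / n for k, n in counts])
        w = 1.0 / (p * (1 - p) / 1000)
        assert m.point == pytest.approx(np.sum(w * p) / np.sum(w), abs=1e-12)

    def test_equal_proportions_equal_sizes_give_unweighted_mean(self):
        # with identical within-practice variances the weights cancel
        m = pooled_prevalence([(50, 1000), (50, 1000), (50, 1000)],
                              transform="raw")
        assert m.point == pytest.approx(0.05, abs=1e-12)

    def test_pooled_point_within_practice_range(self):
        counts = [(2, 40), (30, 300), (70, 500), (0, 120)]
        m = pooled_prevalence(counts)
        ests = m.table["estimate"]
        corrected_lo = min(ests.min(), 0.5 / 121)
        assert corrected_lo <= m.point <= ests.max()

    def test_zero_cells_handled_by_continuity_correction(self):
        m = pooled_prevalence([(0, 100), (10, 100)])
        assert 0.0 < m.point < 0.10
        assert np.isfinite(m.table["theta"]).all()

    def test_interval_narrows_as_practices_accumulate(self):
        widths = []
        for reps in (2, 5, 20):
            m = pooled_prevalence([(35, 500)] * reps)
            widths.append(m.upper - m.lower)
        assert widths == sorted(widths, reverse=True)

    def test_weights_normalised(self):
        m = pooled_prevalence([(5, 100), (20, 500)])
        assert m.table["weight"].sum() == pytest.approx(1.0)

    def test_unknown_transform(self):
        with pytest.raises(ValueError):
            pooled_prevalence([(1, 10)], transform="arcsine")


class TestSplineBasis:
    def test_dimension_equals_df(self):
        x = np.linspace(0, 40, 500)
        for df in (2, 3, 5):
            B, knots = natural_spline_basis(x, df=df)
            assert B.shape == (500, df)
            assert len(knots) == df + 1

    def test_linear_beyond_boundary_knots(self):
        x = np.linspace(0, 40, 1001)
        B, _ = natural_spline_basis(x, knots=[15, 25],
                                    boundary_knots=[10, 30])
        coef = np.array([0.5, -1.2, 0.7])
        y = B @ coef
        for region in (x < 10, x > 30):
            second = np.diff(y[region], 2)
            assert np.max(np.abs(second)) < 1e-8

    def test_second_derivative_continuous_at_knots(self):
        B = lambda pts: natural_spline_basis(
            pts, knots=[15.0], boundary_knots=[5.0, 35.0])[0]
        coef = np.array([1.0, 2.0])
        h = 1e-4
        for knot in (5.0, 15.0, 35.0):
            pts = np.array([knot - 2 * h, knot - h, knot,
                            knot + h, knot + 2 * h])
            y = B(pts) @ coef
            left = (y[2] - 2 * y[1] + y[0]) / h ** 2
            right = (y[4] - 2 * y[3] + y[2]) / h ** 2
            assert left == pytest.approx(right, abs=1e-2)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            natural_spline_basis(np.linspace(0, 1, 10), knots=[0.5, 0.5],
                                 boundary_knots=[0, 1])


class TestAgeSplineModel:
    def test_constant_probability_recovered(self):
        rng = np.random.default_rng(21)
        n = 50_000
        ages = rng.uniform(0, 40, n)
        y = rng.random(n) < 0.07
        res = AgeSplineModel(ages, y, df=3).fit()
        inside = ((res.curve["lower"] <= 0.07)
                  & (0.07 <= res.curve["upper"])).mean()
        assert inside >= 0.9
        assert res.curve["probability"].between(0.06, 0.08).all()

    def test_no_spurious_curvature_on_linear_logit(self):
        rng = np.random.default_rng(22)
        n = 80_000
        ages = rng.uniform(0, 40, n)
        eta = -3.0 + 0.05 * ages
        y = rng.random(n) < expit(eta)
        res = AgeSplineModel(ages, y, df=3).fit()
        truth = expit(-3.0 + 0.05 * res.curve["age"].to_numpy())
        halfwidth = (res.curve["upper"] - res.curve["lower"]).to_numpy() / 2
        dev = np.abs(res.curve["probability"].to_numpy() - truth)
        assert (dev < 2 * halfwidth).mean() >= 0.95

    def test_u_shape_minimum_recovered(self):
        rng = np.random.default_rng(23)
        n = 100_000
        ages = rng.uniform(0, 40, n)
        eta = -3.0 + 0.01 * (ages - 12.0) ** 2
        y = rng.random(n) < expit(eta)
        res = AgeSplineModel(ages, y, df=3).fit()
        assert res.minimum_age == pytest.approx(12.0, abs=2.0)

    def test_probabilities_stay_in_unit_interval(self):
        rng = np.random.default_rng(24)
        ages = rng.uniform(0, 40, 2000)
        y = rng.random(2000) < 0.05
        res = AgeSplineModel(ages, y).fit()
        assert ((res.curve[["probability", "lower", "upper"]] > 0).all().all()
                and (res.curve[["probability", "lower", "upper"]] < 1)
                .all().all())

    def test_single_class_outcome_raises_separation_error(self):
        ages = np.linspace(0, 40, 200)
        with pytest.raises(SeparationError):
            AgeSplineModel(ages, np.ones(200)).fit()
        with pytest.raises(SeparationError):
            AgeSplineModel(ages, np.zeros(200)).fit()

    def test_summary_mentions_fit_size(self):
        rng = np.random.default_rng(25)
        ages = rng.uniform(0, 40, 3000)
        y = rng.random(3000) < 0.1
        res = AgeSplineModel(ages, y).fit()
        assert "3000" in res.summary().replace(",", "")


class TestYearlyTrend:
    def _cons(self, practice, years, rate, n=200, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for yr in years:
            for i in range(n):
                rows.append({"practice_id": practice, "horse_id": f"h{i}",
                             "date": f"{yr}-06-01",
                             "treated": bool(rng.random() < rate)})
        return pd.DataFrame(rows)

    def test_constant_rate_gives_flat_series(self):
        cons = self._cons("P1", range(2019, 2024), 0.05, n=2000)
        out = yearly_trend(cons)
        assert len(out) == 5
        assert out["pct"].between(3.5, 6.5).all()

    def test_incomplete_practice_excluded_when_restricted(self):
        a = self._cons("P1", [2019, 2020, 2021], 0.0)
        b = self._cons("P2", [2019, 2021], 1.0)  # missing 2020
        out = yearly_trend(pd.concat([a, b]))
        assert (out["pct"] == 0.0).all()  # only P1 retained

    def test_unrestricted_pools_everything(self):
        a = self._cons("P1", [2019, 2020, 2021], 0.0)
        b = self._cons("P2", [2019, 2021], 1.0)
        out = yearly_trend(pd.concat([a, b]),
                           restrict_to_practices_present_all_years=False)
        assert out.loc[out["year"] == 2019, "pct"].iloc[0] == 50.0
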