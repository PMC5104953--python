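"""EONR derivation, return-to-N scans, site-mean pooling, method comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nresponse import (
    EconConfig,
    OptimumEstimate,
    ResponseFit,
    SiteMeanResult,
    annual_optima,
    eonr_from_fit,
    fit_group,
    method_difference,
    predict_yield,
    rtn_optimum,
    site_mean,
)
from conftest import make_table

RATES = np.array([0.0, 67.0, 134.0, 201.0, 268.0])


def quad_fit(a=4000.0, b=50.0, c=-0.09):
    return ResponseFit(
        form="quadratic", a=a, b=b, c=c, x0=None,
        ss_res=0.0, r2=1.0, p_value=1e-9, converged=True, n_obs=20,
    )


def qp_fit(a=4000.0, b=50.0, x0=150.0):
    c = -b / (2 * x0)
    return ResponseFit(
        form="quadratic_plateau", a=a, b=b, c=c, x0=x0,
        ss_res=0.0, r2=1.0, p_value=1e-9, converged=True, n_obs=20,
    )


class TestEonrFromFit:
    def test_analytic_derivative_solution(self):
        est = eonr_from_fit(quad_fit(), EconConfig(), max_rate=268)
        assert est.eonr == pytest.approx((5.6 - 50) / (2 * -0.09), abs=0.01)
        assert est.yeonr == pytest.approx(10857.3, abs=0.5)
        assert est.boundary == "interior"

    def test_marginal_value_equal_to_cost_at_origin(self):
        est = eonr_from_fit(quad_fit(b=5.6), EconConfig(), max_rate=268)
        assert est.eonr == 0.0
        assert est.boundary == "at_zero"

    def test_plateau_cap_and_interior_root(self):
        # unconstrained root below the join point: interior
        f = qp_fit(b=50, x0=150)
        est = eonr_from_fit(f, EconConfig(), max_rate=268)
        expected = (5.6 - 50) / (2 * f.c)
        assert est.eonr == pytest.approx(expected, abs=0.01)
        assert expected < 150
        # a free ratio of zero drives the optimum to the join point
        est0 = eonr_from_fit(f, EconConfig(price_ratio=1e-12), max_rate=268)
        assert est0.eonr == pytest.approx(150, abs=0.01)
        # both reproduced by numeric profit maximization
        grid = np.linspace(0, 268, 100001)
        profit = predict_yield(f, grid) - 5.6 * grid
        assert grid[np.argmax(profit)] == pytest.approx(est.eonr, abs=0.01)

    def test_convex_fit_is_undefined(self):
        est = eonr_from_fit(quad_fit(c=0.01), EconConfig(), max_rate=268)
        assert est.boundary == "undefined"
        assert est.eonr is None and est.yeonr is None

    def test_censoring_at_max_rate(self):
        est = eonr_from_fit(quad_fit(b=80, c=-0.05), EconConfig(), max_rate=268)
        assert est.eonr == 268
        assert est.boundary == "at_max"

    @settings(deadline=None, max_examples=50)
    @given(
        b=st.floats(10, 90),
        c=st.floats(-0.2, -0.02),
        r1=st.floats(1, 8),
        r2=st.floats(1, 8),
    )
    def test_eonr_non_increasing_in_price_ratio(self, b, c, r1, r2):
        lo, hi = sorted([r1, r2])
        f = quad_fit(b=b, c=c)
        e_lo = eonr_from_fit(f, EconConfig(price_ratio=lo), max_rate=1000)
        e_hi = eonr_from_fit(f, EconConfig(price_ratio=hi), max_rate=1000)
        assert e_hi.eonr <= e_lo.eonr + 1e-9


class TestRtn:
    def grid_series(self, fit, step=5.0):
        grid = np.arange(0, 350 + step / 2, step)
        return pd.Series(predict_yield(fit, grid), index=grid)

    def test_flat_curve_optimum_at_zero(self):
        s = pd.Series(9000.0, index=np.arange(0, 355, 5.0))
        est = rtn_optimum(s)
        assert est.eonr == 0.0
        assert est.boundary == "at_zero"

    def test_quadratic_grid_within_one_step_of_analytic(self):
        est = rtn_optimum(self.grid_series(quad_fit()))
        assert est.eonr == 245.0  # analytic optimum 246.7, 5-kg grid
        assert est.details["rules_agree"]

    def test_rising_curve_censored_at_grid_end(self):
        est = rtn_optimum(self.grid_series(quad_fit(b=120, c=-0.01)))
        assert est.boundary == "at_max"
        assert est.eonr == 350.0

    def test_gapped_grid_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0], index=[0.0, 5.0, 15.0])
        with pytest.raises(ValueError):
            rtn_optimum(s)

    @settings(deadline=None, max_examples=50)
    @given(b=st.floats(10, 80), c=st.floats(-0.25, -0.03))
    def test_concave_curves_within_one_grid_step(self, b, c):
        f = quad_fit(b=b, c=c)
        analytic = eonr_from_fit(f, EconConfig(), max_rate=10000).eonr
        if not (0 < analytic < 345):
            return
        est = rtn_optimum(self.grid_series(f))
        assert abs(est.eonr - analytic) <= 5.0


class TestSiteMean:
    def estimates(self, values, rotation="CC"):
        return [
            OptimumEstimate(
                eonr=v, yeonr=8000.0, method="regression_eonr",
                rotation=rotation, year=2000 + i,
            )
            for i, v in enumerate(values)
        ]

    def test_two_point_mean_and_sd(self):
        res = site_mean(self.estimates([100, 200]), None, "across_years")
        assert res.mean_eonr == pytest.approx(150)
        assert res.sd_eonr == pytest.approx(70.71, abs=0.01)
        assert res.n_years == 2

    def test_identical_years_make_pooling_methods_agree(self):
        rows = []
        for year in (2001, 2002, 2003):
            for rate in RATES:
                mu = 4000 + 50 * rate - 0.09 * rate**2
                for rep in (1, 2, 3, 4):
                    rows.append([year, "CC", "corn", rate, rep, mu])
        table = make_table(rows)
        yearly = annual_optima(table)
        across = site_mean(yearly, table, "across_years", rotation="CC")
        pooled = site_mean(yearly, table, "pooled", rotation="CC")
        assert across.sd_eonr == pytest.approx(0, abs=1e-6)
        assert pooled.mean_eonr == pytest.approx(across.mean_eonr, abs=1e-4)

    def test_undefined_years_excluded_not_zeroed(self):
        ests = self.estimates([100, 200]) + [
            OptimumEstimate(
                eonr=None, yeonr=None, method="regression_eonr",
                rotation="CC", year=2003, boundary="undefined",
            )
        ]
        res = site_mean(ests, None, "across_years")
        assert res.mean_eonr == pytest.approx(150)
        assert res.n_years == 2

    def test_pooled_equals_hand_chained_mean_fit(self, experiment16):
        table = experiment16.trial
        pooled = site_mean(None, table, "pooled", rotation="CC")
        # independent step-by-step chain on the mean response
        sub = table.corn()
        sub = sub[sub.rotation == "CC"]
        mean_resp = sub.groupby("n_rate", as_index=False)["yield"].mean()
        best = fit_group(mean_resp, fit_level="mean")
        expected = eonr_from_fit(best, EconConfig(), mean_resp.n_rate.max())
        assert pooled.mean_eonr == pytest.approx(expected.eonr, abs=1e-9)
        assert pooled.sd_eonr is None

    def test_pooled_invariant_to_year_order(self, experiment16):
        table = experiment16.trial
        df = table.df.sort_values("year", ascending=False, kind="stable")
        from nresponse import TrialTable

        shuffled = TrialTable(df.reset_index(drop=True))
        a = site_mean(None, table, "pooled", rotation="SC")
        b = site_mean(None, shuffled, "pooled", rotation="SC")
        assert a.mean_eonr == pytest.approx(b.mean_eonr, abs=1e-9)


class TestMethodDifference:
    def site(self, eonr, method="pooled"):
        return SiteMeanResult(
            method=method, mean_eonr=eonr, sd_eonr=None,
            mean_yeonr=9000.0, n_years=16, rotation="CC",
        )

    def test_signed_difference(self):
        assert method_difference(self.site(187), self.site(226)) == -39

    def test_identity_is_zero(self):
        assert method_difference(self.site(150), self.site(150)) == 0

    def test_undefined_operand_gives_none(self):
        assert method_difference(self.site(None), self.site(150)) is None
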