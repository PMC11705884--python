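"""Morphology trend models, seasonal climate summaries, trend fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tempopgen import phenoclim
from tempopgen.phenoclim import (
    climate_trends,
    diversity_trend,
    filter_morphology_rows,
    fit_trait_model,
    fraction_increasing,
    period_contrast,
    relative_traits,
    seasonal_summary,
    trend_per_point,
)


def morpho_table(rng, n=400, slope=-0.03, sex_gap=0.0, interaction=0.0, noise=0.1):
    years = rng.integers(1980, 2016, n)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    male = (sex == "M").astype(float)
    bill = 10 + slope * (years - 1980) + sex_gap * male
    bill += interaction * male * (years - 1980) + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "id": [f"b{i}" for i in range(n)],
            "sex": sex,
            "year": years,
            "library": "005",
            "bill_mm": bill,
            "tarsus_mm": 30 + rng.normal(0, 1, n),
            "wing_mm": 89 + rng.normal(0, 2, n),
        }
    )


class TestRelativeTraits:
    def test_simple_division(self):
        df = pd.DataFrame({"bill_mm": [9.0], "tarsus_mm": [30.0], "wing_mm": [90.0]})
        out = relative_traits(df)
        assert out["relative_bill"].iloc[0] == pytest.approx(0.3)
        assert out["relative_wing"].iloc[0] == pytest.approx(3.0)

    def test_missing_tarsus_keeps_row(self):
        df = pd.DataFrame(
            {"bill_mm": [9.0, 8.0], "tarsus_mm": [np.nan, 0.0], "wing_mm": [90.0, 91.0]}
        )
        out = relative_traits(df)
        assert out["relative_bill"].isna().all()
        assert out["bill_mm"].notna().all()
        assert len(out) == 2

    def test_equal_tarsi_preserve_ranks(self, rng):
        df = pd.DataFrame(
            {"bill_mm": rng.normal(9, 1, 30), "tarsus_mm": 30.0, "wing_mm": 90.0}
        )
        out = relative_traits(df)
        rho = stats.spearmanr(out["bill_mm"], out["relative_bill"]).statistic
        assert rho == pytest.approx(1.0)


class TestFitTraitModel:
    def test_year_effect_recovered(self, rng):
        df = morpho_table(rng, slope=-0.03)
        res = fit_trait_model(df, "bill")
        assert "year" in res.terms
        year_coef = res.coefficients.set_index("term").loc["year", "estimate"]
        assert year_coef == pytest.approx(-0.03, abs=0.01)
        assert year_coef < 0

    def test_interaction_rarely_selected_under_noise(self, rng):
        picks = 0
        for _ in range(50):
            df = morpho_table(rng, n=80, slope=0.0, noise=1.0)
            res = fit_trait_model(df, "bill")
            picks += "year:sex" in res.terms
        assert picks < 25  # AIC penalty keeps the interaction a minority pick

    def test_constant_trait_selects_intercept_only(self, rng):
        df = morpho_table(rng, slope=0.0, noise=0.0)
        df["bill_mm"] = 9.9
        res = fit_trait_model(df, "bill")
        assert res.terms == ()

    def test_selected_model_minimises_aic(self, rng):
        df = morpho_table(rng, slope=-0.02, sex_gap=0.5)
        res = fit_trait_model(df, "bill")
        assert res.aic[res.formula] == min(res.aic.values())

    def test_interaction_model_equals_sexwise_fits(self, rng):
        # strong interaction: full model fitted values match two separate
        # per-sex regressions
        df = morpho_table(rng, slope=-0.05, sex_gap=2.0, interaction=0.06, noise=0.05)
        res = fit_trait_model(df, "bill")
        assert "year:sex" in res.terms
        import statsmodels.formula.api as smf

        full = smf.ols("bill_mm ~ year + C(sex) + year:C(sex)", data=df).fit()
        for sex in ("M", "F"):
            sub = df[df["sex"] == sex]
            sep = smf.ols("bill_mm ~ year", data=sub).fit()
            assert np.allclose(
                full.predict(sub), sep.predict(sub), atol=1e-10
            )


class TestPeriodContrast:
    def test_identical_periods(self, rng):
        df = morpho_table(rng, slope=0.0, noise=0.0)
        diff, pct = period_contrast(df, "bill", (1980, 1985), (2010, 2015))
        assert diff == pytest.approx(0.0, abs=1e-9)
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_constructed_means(self):
        df = pd.DataFrame(
            {
                "bill_mm": [9.3] * 10 + [8.4] * 10,
                "year": [1982] * 10 + [2012] * 10,
            }
        )
        diff, pct = period_contrast(df, "bill", (1980, 1985), (2010, 2015))
        assert diff == pytest.approx(-0.9)
        assert pct == pytest.approx(-9.677, abs=0.01)

    def test_empty_period_raises(self, rng):
        df = morpho_table(rng)
        with pytest.raises(ValueError, match="empty"):
            period_contrast(df, "bill", (1900, 1901), (2010, 2015))


class TestRowFilters:
    def test_report_counts(self):
        df = pd.DataFrame(
            {
                "sex": ["M", "F", "U", "M"],
                "month": [3, 4, 5, 9],
                "age": ["adult", "hatch_year", "adult", "adult"],
            }
        )
        out, report = filter_morphology_rows(df)
        assert report == {"month": 1, "hatch_year": 1, "missing_sex": 1}
        assert len(out) == 1


class TestSeasonalSummary:
    def _daily(self, values, year=2000, months=(6, 7)):
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        df = pd.DataFrame({"date": dates})
        df["tmax"] = np.nan
        df["tmin"] = np.nan
        df["prcp"] = 0.0
        sel = df["date"].dt.month.isin(months)
        df.loc[sel, "tmax"] = values[: sel.sum()]
        df.loc[sel, "tmin"] = values[: sel.sum()]
        df.loc[sel, "prcp"] = values[: sel.sum()]
        return df

    def test_constant_series(self):
        df = self._daily(np.full(61, 7.0))
        assert seasonal_summary(df, "tmax", "breeding") == pytest.approx(7.0)
        assert seasonal_summary(df, "tmin", "breeding") == pytest.approx(7.0)
        assert seasonal_summary(df, "prcp", "breeding") == pytest.approx(7.0 * 61)

    def test_type7_quantile_hand_value(self):
        # June-July has 61 days; tmax = 1..61 -> 95th type-7 quantile = 58
        df = self._daily(np.arange(1.0, 62.0))
        assert seasonal_summary(df, "tmax", "breeding") == pytest.approx(58.0)

    def test_zero_precip_total(self):
        df = self._daily(np.zeros(61))
        assert seasonal_summary(df, "prcp", "breeding") == 0.0

    def test_quantile_shift_equivariance(self, rng):
        vals = rng.normal(10, 3, 61)
        df1 = self._daily(vals)
        df2 = self._daily(vals + 2.5)
        assert seasonal_summary(df2, "tmax", "breeding") == pytest.approx(
            seasonal_summary(df1, "tmax", "breeding") + 2.5
        )

    def test_empty_season_raises(self):
        df = self._daily(np.full(61, 1.0))
        df.loc[df["date"].dt.month.isin([1, 2]), ["tmin", "tmax"]] = np.nan
        with pytest.raises(ValueError, match="season"):
            seasonal_summary(df[df["date"].dt.month > 2], "tmax", "winter")


class TestTrends:
    def test_monotone_series(self):
        up = trend_per_point(np.arange(10.0), np.arange(10) + 2000)
        dn = trend_per_point(-np.arange(10.0), np.arange(10) + 2000)
        assert up.rho == pytest.approx(1.0) and dn.rho == pytest.approx(-1.0)

    def test_ties_match_permutation_oracle(self):
        from test_effects import spearman_perm_oracle

        years = np.arange(2000, 2005, dtype=float)
        vals = np.array([1.0, 2.0, 2.0, 4.0, 3.0])
        fit = trend_per_point(vals, years)
        rho_o, p_o = spearman_perm_oracle(years, vals)
        assert fit.rho == pytest.approx(rho_o, abs=1e-12)
        assert fit.p == pytest.approx(p_o, abs=1e-12)

    def test_constant_series_flagged(self):
        fit = trend_per_point(np.full(6, 3.0), np.arange(6) + 2000)
        assert np.isnan(fit.rho) and fit.method == "undefined"

    def test_monotone_transform_invariance(self, rng):
        years = np.arange(2000, 2012, dtype=float)
        vals = rng.normal(size=12)
        a = trend_per_point(vals, years)
        b = trend_per_point(np.exp(vals), years)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_fraction_increasing_halves(self):
        trends = pd.DataFrame({"rho": [0.5, 0.9, -0.4, -0.8]})
        assert fraction_increasing(trends) == 50.0

    def test_fraction_increasing_all_positive(self):
        assert fraction_increasing(pd.DataFrame({"rho": [0.1, 0.2]})) == 100.0

    def test_fraction_undefined_trends_excluded(self):
        trends = pd.DataFrame({"rho": [0.5, np.nan, -0.2, np.nan]})
        assert fraction_increasing(trends) == 50.0


class TestDiversityTrend:
    def _table(self, years, values):
        return pd.DataFrame({"year": years, "thetaW": values, "low_data": False})

    def test_flat_series_zero_slope(self):
        tab = self._table([2000] * 5 + [2005] * 5, [0.004] * 10)
        fit, _ = diversity_trend(tab)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        years = np.repeat(np.arange(2000, 2010), 3)
        tab = self._table(years, 0.001 * (years - 2000))
        fit, per_year = diversity_trend(tab)
        assert fit.slope == pytest.approx(0.001, abs=1e-12)
        assert fit.p < 1e-10
        assert len(per_year) == 10

    def test_null_coverage(self, rng):
        covered = 0
        for _ in range(20):
            years = np.repeat(np.arange(2000, 2010), 4)
            vals = 0.005 + rng.normal(0, 0.0005, years.size)
            df = self._table(years, vals)
            res = stats.linregress(years.astype(float), vals)
            lo = res.slope - 1.96 * res.stderr
            hi = res.slope + 1.96 * res.stderr
            covered += lo <= 0 <= hi
        assert covered >= 18  # stationary truth: CI covers zero ~95% of the time

    def test_single_year_raises(self):
        with pytest.raises(ValueError):
            diversity_trend(self._table([2000] * 4, [0.001] * 4))
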