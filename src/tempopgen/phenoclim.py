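"""Morphological trend models, seasonal climate summaries, and trend fits.

Morphology: each trait is regressed on collection year, sex, and their
interaction; the reported model is chosen by sequentially dropping terms
(interaction first, then main effects, never keeping an interaction without
its mains) and comparing AIC = n log(RSS/n) + 2k with k counting coefficients
plus the residual variance.  Relative traits divide bill and wing by tarsus,
the standard avian body-size proxy.

Climate: per grid point and year, the breeding season (June-July) and winter
(January-February) are summarised by the 5th quantile of daily minima, the
95th quantile of daily maxima (robust stand-ins for the seasonal extremes)
and total precipitation; the temporal trend at a point is the Spearman rank
correlation of the yearly summary with year, and a range-wide warming figure
is the percentage of points with a positive trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from ._stats import spearman_test
from .simulate import trait_column

__all__ = [
    "MorphModelResult",
    "TrendFit",
    "relative_traits",
    "filter_morphology_rows",
    "fit_trait_model",
    "period_contrast",
    "seasonal_summary",
    "seasonal_summaries",
    "trend_per_point",
    "climate_trends",
    "fraction_increasing",
    "diversity_trend",
]

SEASONS = {"breeding": (6, 7), "winter": (1, 2)}
SPRING_MONTHS = (3, 4, 5)

# candidate models visited by the sequential dropping scheme, respecting
# marginality (no interaction without both main effects)
_MODEL_TERMS = [
    ("year", "sex", "year:sex"),
    ("year", "sex"),
    ("year",),
    ("sex",),
    (),
]


@dataclass
class MorphModelResult:
    trait: str
    formula: str
    terms: tuple[str, ...]
    coefficients: pd.DataFrame  # term, estimate, p
    aic: dict[str, float]  # per candidate formula
    n: int


@dataclass
class TrendFit:
    slope: float = np.nan
    intercept: float = np.nan
    rho: float = np.nan
    p: float = np.nan
    n: int = 0
    method: str = ""


def relative_traits(samples: pd.DataFrame) -> pd.DataFrame:
    """Add relative_bill and relative_wing columns (trait / tarsus).

    Rows with missing or non-positive tarsus keep their absolute traits but
    get missing relative values.
    """
    out = samples.copy()
    tarsus = out[trait_column("tarsus")].astype(float)
    ok = tarsus > 0
    for trait, rel in (("bill", "relative_bill"), ("wing", "relative_wing")):
        col = out[trait_column(trait)].astype(float)
        out[rel] = np.where(ok & col.notna(), col / tarsus, np.nan)
    return out


def filter_morphology_rows(
    samples: pd.DataFrame,
    months: tuple[int, ...] = SPRING_MONTHS,
    drop_hatch_year: bool = True,
    require_sex: bool = True,
):
    """Declarative row filters for the morphology analysis, with a drop report.

    Applies, in order: spring-migration months (if a month column exists),
    discarding hatch-year birds (if an age column exists), and requiring sex.
    Returns (filtered table, dict of rows dropped per rule).
    """
    out = samples.copy()
    report = {"month": 0, "hatch_year": 0, "missing_sex": 0}
    if "month" in out.columns and months:
        keep = out["month"].isin(months)
        report["month"] = int((~keep).sum())
        out = out[keep]
    if drop_hatch_year and "age" in out.columns:
        keep = out["age"].astype(str).str.lower() != "hatch_year"
        report["hatch_year"] = int((~keep).sum())
        out = out[keep]
    if require_sex:
        keep = out["sex"].isin(["M", "F"])
        report["missing_sex"] = int((~keep).sum())
        out = out[keep]
    return out.reset_index(drop=True), report


def _aic(fit, n: int) -> float:
    rss = float(np.sum(fit.resid**2))
    k = len(fit.params) + 1  # coefficients + residual variance
    if rss <= 0:
        rss = 1e-300
    return n * np.log(rss / n) + 2 * k


def _formula(col: str, terms: tuple[str, ...]) -> str:
    rhs = " + ".join(t.replace("sex", "C(sex)") for t in terms) if terms else "1"
    return f"{col} ~ {rhs}"


def fit_trait_model(samples: pd.DataFrame, trait: str) -> MorphModelResult:
    """OLS year/sex/interaction model for one trait with AIC term selection."""
    col = trait_column(trait)
    df = samples[[col, "year", "sex"]].dropna().reset_index(drop=True)
    df = df.rename(columns={col: "trait_value"})
    n = len(df)
    if n < 10:
        raise ValueError(f"need >= 10 observations, got {n}")
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes required")
    aics: dict[str, float] = {}
    fits = {}
    for terms in _MODEL_TERMS:
        f = _formula("trait_value", terms)
        fit = smf.ols(f, data=df).fit()
        aics[f] = _aic(fit, n)
        fits[f] = (terms, fit)
    best = min(aics, key=aics.get)
    terms, fit = fits[best]
    coef = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return MorphModelResult(
        trait=trait,
        formula=best.replace("trait_value", trait),
        terms=terms,
        coefficients=coef,
        aic={k.replace("trait_value", trait): v for k, v in aics.items()},
        n=n,
    )


def period_contrast(
    samples: pd.DataFrame,
    trait: str,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
):
    """Difference of period means (b - a) and percent change relative to period a."""
    col = trait_column(trait)
    vals = samples[[col, "year"]].dropna()
    in_a = vals[(vals["year"] >= period_a[0]) & (vals["year"] <= period_a[1])][col]
    in_b = vals[(vals["year"] >= period_b[0]) & (vals["year"] <= period_b[1])][col]
    if len(in_a) == 0 or len(in_b) == 0:
        raise ValueError("empty period")
    mean_a, mean_b = float(in_a.mean()), float(in_b.mean())
    diff = mean_b - mean_a
    return diff, 100.0 * diff / mean_a


# ---------------------------------------------------------------------------
# Climate


def seasonal_summary(daily: pd.DataFrame, variable: str, season: str) -> float:
    """One point-year seasonal value.

    tmax -> 95th quantile of daily maxima; tmin -> 5th quantile of daily
    minima; prcp -> seasonal total.  Quantiles use linear interpolation
    between order statistics (type 7).
    """
    months = SEASONS[season]
    dates = pd.to_datetime(daily["date"])
    sel = daily.loc[dates.dt.month.isin(months), variable].dropna()
    if len(sel) == 0:
        raise ValueError(f"no daily values in season {season!r}")
    x = sel.to_numpy(dtype=float)
    if variable == "tmax":
        return float(np.quantile(x, 0.95))
    if variable == "tmin":
        return float(np.quantile(x, 0.05))
    if variable == "prcp":
        return float(x.sum())
    raise ValueError(f"unknown variable {variable!r}")


def seasonal_summaries(daily: pd.DataFrame, variable: str, season: str) -> pd.DataFrame:
    """Yearly seasonal summaries for every grid point: point_id, lat, lon, year, value."""
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    months = SEASONS[season]
    df = df[df["date"].dt.month.isin(months)]
    df["year"] = df["date"].dt.year
    if variable == "tmax":
        agg = lambda x: np.quantile(x, 0.95)
    elif variable == "tmin":
        agg = lambda x: np.quantile(x, 0.05)
    elif variable == "prcp":
        agg = np.sum
    else:
        raise ValueError(f"unknown variable {variable!r}")
    out = (
        df.groupby(["point_id", "lat", "lon", "year"])[variable]
        .apply(lambda x: float(agg(x.to_numpy(dtype=float))))
        .rename("value")
        .reset_index()
    )
    return out


def trend_per_point(values, years) -> TrendFit:
    """Spearman trend of one point's yearly summaries against year."""
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    if values.size < 3:
        raise ValueError("need >= 3 years")
    if np.all(values == values[0]):
        return TrendFit(rho=np.nan, p=np.nan, n=values.size, method="undefined")
    rho, p, method = spearman_test(years, values)
    return TrendFit(rho=rho, p=p, n=values.size, method=method)


def climate_trends(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-point Spearman trend table from seasonal_summaries output."""
    rows = []
    for (pid, lat, lon), grp in summaries.groupby(["point_id", "lat", "lon"]):
        fit = trend_per_point(grp["value"].to_numpy(), grp["year"].to_numpy())
        rows.append(
            {"point_id": pid, "lat": lat, "lon": lon, "rho": fit.rho, "p": fit.p, "n": fit.n}
        )
    return pd.DataFrame(rows)


def fraction_increasing(trends: pd.DataFrame) -> float:
    """Percentage of grid points with rho > 0 among points with a defined trend."""
    rho = trends["rho"].to_numpy(dtype=float)
    defined = ~np.isnan(rho)
    if not defined.any():
        raise ValueError("no point has a defined trend")
    return 100.0 * float((rho[defined] > 0).sum()) / float(defined.sum())


def diversity_trend(window_table: pd.DataFrame, metric: str = "thetaW"):
    """OLS trend of per-window diversity on year.

    Windows flagged low_data are excluded.  Returns (TrendFit, per-year means).
    """
    df = window_table
    if "low_data" in df.columns:
        df = df[~df["low_data"].astype(bool)]
    df = df[["year", metric]].dropna()
    years = df["year"].unique()
    if len(years) < 2:
        raise ValueError("need at least 2 year groups")
    res = stats.linregress(df["year"].to_numpy(dtype=float), df[metric].to_numpy(dtype=float))
    per_year = df.groupby("year")[metric].mean().rename("mean").reset_index()
    fit = TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rho=np.nan,
        p=float(res.pvalue),
        n=len(df),
        method="ols",
    )
    return fit, per_year
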