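"""Explaining year-to-year variability in optimum N with precipitation.

Single-factor ordinary least squares regressions of yearly EONR on
candidate precipitation windows (and other drivers), ranked by R^2;
plus the negative-control check that soybean yields in the rotation are
unrelated to the N rate applied to the prior corn crop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Default candidate precipitation windows screened against EONR.
DEFAULT_WINDOWS = (
    ("Apr-Jun", "04-01", "06-30"),
    ("May-Jun", "05-01", "06-30"),
    ("Jun", "06-01", "06-30"),
    ("Jul silking +/-15d", "07-01", "07-31"),
    ("full year", "01-01", "12-31"),
)


@dataclass(frozen=True)
class WindowSpec:
    """A within-year date window, both endpoints inclusive (``MM-DD``)."""

    label: str
    start: str
    end: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start must not be after end")


@dataclass(frozen=True)
class RegressionResult:
    """A simple OLS line: slope, intercept, R^2, slope-test p, point count."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    label: str | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def window_sum(daily_precip: pd.Series, window: WindowSpec) -> float:
    """Sum daily precipitation (mm) over a month-day window, ends inclusive.

    ``daily_precip`` is indexed by date (anything ``pd.DatetimeIndex``
    accepts).  The series must cover the window's span.
    """
    s = daily_precip.copy()
    s.index = pd.DatetimeIndex(s.index)
    year = s.index[0].year
    start = pd.Timestamp(f"{year}-{window.start}")
    end = pd.Timestamp(f"{year}-{window.end}")
    covered = (s.index.min() <= start) and (s.index.max() >= end)
    if not covered:
        raise ValueError(
            f"daily series does not cover window {window.label!r} "
            f"({start.date()}..{end.date()})"
        )
    mask = (s.index >= start) & (s.index <= end)
    return float(s[mask].sum())


def simple_regression(x, y, label: str | None = None) -> RegressionResult:
    """OLS line of y on x with the slope t-test and squared Pearson R.

    Pairs with a missing value in either series are dropped; at least three
    complete pairs and non-zero predictor variance are required (zero
    variance returns an undefined, NaN-filled result rather than raising).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >=3 complete pairs for regression")
    if np.ptp(x) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, len(x), label)
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        p_value=p,
        n=len(x),
        label=label,
    )


def screen_windows(
    daily_precip_by_year: dict[int, pd.Series],
    eonr_by_year: pd.Series,
    candidates: tuple[WindowSpec, ...] | None = None,
    alpha: float = 0.05,
) -> list[RegressionResult]:
    """Regress yearly EONR on each candidate window's precipitation sum.

    Years with an undefined EONR are dropped pairwise.  Results are ranked
    by R^2 descending; significance at ``alpha`` is readable off each
    result's p-value.
    """
    if candidates is None:
        candidates = tuple(WindowSpec(*w) for w in DEFAULT_WINDOWS)
    if not candidates:
        raise ValueError("need at least one candidate window")
    years = sorted(set(daily_precip_by_year) & set(eonr_by_year.index))
    if len(years) < 3:
        raise ValueError("need >=3 years")
    eonr = eonr_by_year.loc[years].to_numpy(float)
    results = []
    for w in candidates:
        sums = np.array([window_sum(daily_precip_by_year[y], w) for y in years])
        results.append(simple_regression(sums, eonr, label=w.label))
    return sorted(results, key=lambda r: (np.nan_to_num(r.r2, nan=-1.0)), reverse=True)


def rank_precip_predictors(
    weather: pd.DataFrame,
    eonr_by_year: pd.Series,
    columns: tuple[str, ...] = ("spring_precip", "silking_precip", "annual_precip"),
) -> list[RegressionResult]:
    """Rank pre-summed precipitation columns of a weather table as EONR
    predictors — the seasonal-summary counterpart of :func:`screen_windows`."""
    merged = weather.set_index("year").join(eonr_by_year.rename("eonr"), how="inner")
    results = [
        simple_regression(merged[col], merged["eonr"], label=col) for col in columns
    ]
    return sorted(results, key=lambda r: (np.nan_to_num(r.r2, nan=-1.0)), reverse=True)


def carryover_check(soybean_yields, prior_corn_n, label="soybean~prior_corn_N"):
    """Regress soybean yield on the prior-year corn N rate.

    The contract is the report itself: on data where the rotation carries no
    N benefit forward, the slope should be indistinguishable from zero.
    """
    return simple_regression(prior_corn_n, soybean_yields, label=label)


def multi_factor_regression(
    frame: pd.DataFrame, response: str, predictors: tuple[str, ...]
) -> pd.DataFrame:
    """Descriptive multiple OLS of a response on several drivers.

    Reported for completeness only — no selection decisions are made from
    it.  Returns the coefficient table (coef, p) plus the model R^2 in the
    ``r_squared`` attribute-row.
    """
    sub = frame[[response, *predictors]].dropna()
    X = sm.add_constant(sub[list(predictors)])
    model = sm.OLS(sub[response], X).fit()
    out = pd.DataFrame({"coef": model.params, "p_value": model.pvalues})
    out.attrs["r_squared"] = float(model.rsquared)
    return out


def regressions_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window": r.label,
            "slope": r.slope,
            "intercept": r.intercept,
            "r2": r.r2,
            "p_value": r.p_value,
            "n": r.n,
        }
        for r in results
    )
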