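"""Economic optimum N rate (EONR) derivation, return-to-N scans, site means.

Two techniques are implemented:

* regression EONR — set the first derivative of a fitted response curve
  equal to the N:grain price ratio and solve; the yield at that rate is the
  YEONR.
* return to N (RTN) — scan a finely incremented N-rate grid of yields and
  find the rate where the marginal net return (yield gain minus grain-mass
  cost of the added N) reaches zero, the grid analogue of the MRTN
  recommendation framework.

Yearly optima are pooled into site means two ways: averaging yearly
estimates (with an SD), or averaging yields per rate across years first and
deriving a single optimum from the mean response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import AnalysisConfig, EconConfig, TrialTable
from .response_fitting import ResponseFit, fit_group, predict_yield

logger = logging.getLogger(__name__)

#: Boundary flags for an optimum estimate.
INTERIOR, AT_ZERO, AT_MAX, UNDEFINED = "interior", "at_zero", "at_max", "undefined"


@dataclass(frozen=True)
class OptimumEstimate:
    """EONR (kg N ha^-1) and YEONR (kg ha^-1) for one year/rotation/method.

    ``boundary`` records whether the optimum is interior to the tested range,
    clamped at zero or at the maximum rate, or undefined (no concave,
    converged response).  Undefined estimates carry ``eonr is None``.
    """

    eonr: float | None
    yeonr: float | None
    method: str  # "regression_eonr" | "rtn"
    rotation: str | None = None
    year: int | None = None
    boundary: str = INTERIOR
    details: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.boundary != UNDEFINED and self.eonr is not None


@dataclass(frozen=True)
class SiteMeanResult:
    """Site-level EONR summary: across-years average (with SD) or pooled fit."""

    method: str  # "across_years" | "pooled"
    mean_eonr: float | None
    sd_eonr: float | None
    mean_yeonr: float | None
    n_years: int
    rotation: str | None = None

    @property
    def defined(self) -> bool:
        return self.mean_eonr is not None


def _undefined(method: str, rotation=None, year=None, **details) -> OptimumEstimate:
    return OptimumEstimate(
        eonr=None,
        yeonr=None,
        method=method,
        rotation=rotation,
        year=year,
        boundary=UNDEFINED,
        details=details,
    )


def eonr_from_fit(
    fit: ResponseFit | None,
    econ: EconConfig | None = None,
    max_rate: float = 268.0,
    rotation: str | None = None,
    year: int | None = None,
) -> OptimumEstimate:
    """Derive the EONR from a fitted response curve.

    Solves b + 2 c x = price_ratio.  For the plateau form the root is capped
    at the join point (the slope is zero, below any positive price ratio,
    beyond it).  The result is clamped to [0, max_rate] with a boundary flag;
    clamping at the top mirrors censoring at the largest tested rate rather
    than extrapolating beyond the data.  A non-converged fit or one with
    c >= 0 (profit has no interior maximum) gives an undefined estimate.
    """
    econ = econ or EconConfig()
    if fit is None or not fit.converged:
        return _undefined("regression_eonr", rotation, year, reason="no converged fit")
    if fit.c >= 0:
        return _undefined("regression_eonr", rotation, year, reason="non-concave fit")
    x = (econ.price_ratio - fit.b) / (2.0 * fit.c)
    if fit.form == "quadratic_plateau" and fit.x0 is not None:
        x = min(x, fit.x0)
    boundary = INTERIOR
    if x <= 0:
        x, boundary = 0.0, AT_ZERO
    elif x >= max_rate:
        x, boundary = float(max_rate), AT_MAX
    return OptimumEstimate(
        eonr=float(x),
        yeonr=float(predict_yield(fit, x)),
        method="regression_eonr",
        rotation=rotation,
        year=year,
        boundary=boundary,
    )


def rtn_optimum(
    yield_curve,
    econ: EconConfig | None = None,
    rotation: str | None = None,
    year: int | None = None,
) -> OptimumEstimate:
    """Return-to-N optimum from yields on an evenly spaced N-rate grid.

    ``yield_curve`` maps N rate to yield (dict or pandas Series, kg units).
    Two equivalent-for-concave-curves rules are evaluated: the first rate at
    which the marginal net return (yield gain per step minus price_ratio x
    step) turns negative, and the grid maximizer of cumulative net return
    Y(N) - price_ratio * N.  The cumulative maximizer is returned; any
    disagreement (possible on noisy, non-concave curves) is flagged in
    ``details`` and logged.
    """
    econ = econ or EconConfig()
    if isinstance(yield_curve, dict):
        s = pd.Series(yield_curve).sort_index()
    else:
        s = pd.Series(yield_curve)
    rates = s.index.to_numpy(float)
    yields = s.to_numpy(float)
    if len(rates) < 2:
        raise ValueError("need at least two grid rates")
    steps = np.diff(rates)
    if np.any(steps <= 0):
        raise ValueError("N-rate grid must be strictly increasing")
    if not np.allclose(steps, steps[0]):
        raise ValueError("N-rate grid must be evenly spaced (no gaps)")

    net = yields - econ.price_ratio * rates
    i_max = int(np.argmax(net))  # first maximizer on ties -> lowest rate

    marginal = np.diff(yields) - econ.price_ratio * steps
    neg = np.nonzero(marginal < 0)[0]
    i_cross = int(neg[0]) if len(neg) else len(rates) - 1

    if i_cross != i_max:
        logger.info(
            "RTN rules disagree: first zero-crossing at %.0f, cumulative max at %.0f",
            rates[i_cross],
            rates[i_max],
        )
    boundary = INTERIOR
    if i_max == 0:
        boundary = AT_ZERO
    elif i_max == len(rates) - 1:
        boundary = AT_MAX
    return OptimumEstimate(
        eonr=float(rates[i_max]),
        yeonr=float(yields[i_max]),
        method="rtn",
        rotation=rotation,
        year=year,
        boundary=boundary,
        details={
            "zero_crossing_rate": float(rates[i_cross]),
            "rules_agree": i_cross == i_max,
        },
    )


def rtn_from_fit(
    fit: ResponseFit,
    econ: EconConfig | None = None,
    cfg: AnalysisConfig | None = None,
    rotation: str | None = None,
    year: int | None = None,
) -> OptimumEstimate:
    """RTN scan over predicted yields of a fitted curve on the configured grid."""
    cfg = cfg or AnalysisConfig()
    start, stop, step = cfg.rtn_grid
    grid = np.arange(start, stop + step / 2, step)
    yields = predict_yield(fit, grid)
    return rtn_optimum(
        pd.Series(yields, index=grid), econ, rotation=rotation, year=year
    )


def annual_optima(
    table: TrialTable,
    econ: EconConfig | None = None,
    cfg: AnalysisConfig | None = None,
    fit_level: str = "replicate",
    method: str = "regression_eonr",
) -> list[OptimumEstimate]:
    """Fit every (year, rotation) corn group and derive its optimum."""
    econ = econ or EconConfig()
    cfg = cfg or AnalysisConfig()
    out = []
    for (yr, rot), grp in table.groups("corn"):
        if fit_level == "mean":
            grp = grp.groupby("n_rate", as_index=False)["yield"].mean()
        max_rate = float(grp["n_rate"].max())
        best = fit_group(grp, alpha=cfg.alpha, fit_level=fit_level)
        if method == "rtn":
            if best is None:
                out.append(_undefined("rtn", rot, yr, reason="no converged fit"))
            else:
                out.append(rtn_from_fit(best, econ, cfg, rotation=rot, year=yr))
        else:
            out.append(eonr_from_fit(best, econ, max_rate, rotation=rot, year=yr))
    return out


def site_mean(
    estimates: list[OptimumEstimate] | None,
    table: TrialTable | None,
    method: str,
    econ: EconConfig | None = None,
    cfg: AnalysisConfig | None = None,
    rotation: str | None = None,
    optimum_method: str = "regression_eonr",
    fit_level: str = "replicate",
) -> SiteMeanResult:
    """Pool yearly optima into one site-level figure.

    ``method="across_years"`` averages the defined yearly EONR/YEONR values
    and reports their SD; undefined years propagate as missing, never as
    zero.  ``method="pooled"`` averages yields per N rate across years first
    and runs the full fit -> select -> optimum chain once on that mean
    response (no SD is defined for the pooled route).
    """
    econ = econ or EconConfig()
    cfg = cfg or AnalysisConfig()
    if method == "across_years":
        if not estimates:
            raise ValueError("across_years pooling needs yearly estimates")
        defined = [e for e in estimates if e.defined]
        if len(defined) < 2:
            return SiteMeanResult(method, None, None, None, len(defined), rotation)
        eonrs = np.array([e.eonr for e in defined])
        yeonrs = np.array([e.yeonr for e in defined])
        return SiteMeanResult(
            method="across_years",
            mean_eonr=float(eonrs.mean()),
            sd_eonr=float(eonrs.std(ddof=1)),
            mean_yeonr=float(yeonrs.mean()),
            n_years=len(defined),
            rotation=rotation,
        )
    if method != "pooled":
        raise ValueError(f"unknown pooling method {method!r}")
    if table is None:
        raise ValueError("pooled pooling needs the trial table")
    sub = table.corn()
    if rotation is not None:
        sub = sub[sub["rotation"] == rotation]
    n_years = sub["year"].nunique()
    if n_years < 2:
        raise ValueError("pooled pooling needs >=2 years")
    mean_resp = sub.groupby("n_rate", as_index=False)["yield"].mean()
    best = fit_group(mean_resp, alpha=cfg.alpha, fit_level="mean")
    if optimum_method == "rtn":
        if best is None:
            est = _undefined("rtn", rotation)
        else:
            est = rtn_from_fit(best, econ, cfg, rotation=rotation)
    else:
        est = eonr_from_fit(
            best, econ, float(mean_resp["n_rate"].max()), rotation=rotation
        )
    return SiteMeanResult(
        method="pooled",
        mean_eonr=est.eonr,
        sd_eonr=None,
        mean_yeonr=est.yeonr,
        n_years=n_years,
        rotation=rotation,
    )


def method_difference(reference, candidate) -> float | None:
    """Signed EONR difference, reference minus candidate (kg N ha^-1).

    Both operands may be SiteMeanResult or OptimumEstimate; an undefined
    operand gives ``None``.  The exact difference is returned — display
    rounding is left to the caller.
    """
    ref = reference.mean_eonr if isinstance(reference, SiteMeanResult) else reference.eonr
    cand = candidate.mean_eonr if isinstance(candidate, SiteMeanResult) else candidate.eonr
    if ref is None or cand is None:
        return None
    return float(ref - cand)


def optima_to_frame(estimates: list[OptimumEstimate]) -> pd.DataFrame:
    """Tabulate estimates, one row per year x rotation x method."""
    return pd.DataFrame(
        {
            "year": e.year,
            "rotation": e.rotation,
            "method": e.method,
            "eonr": e.eonr,
            "yeonr": e.yeonr,
            "boundary": e.boundary,
        }
        for e in estimates
    )
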