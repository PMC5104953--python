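"""Yield-response curve fitting: quadratic and smooth quadratic-plus-plateau.

Each (year, rotation) group of yield/N-rate observations is fit with two
candidate forms:

* quadratic            y = a + b x + c x^2
* quadratic-plateau    y = a + b x + c x^2 for x < x0, constant for x >= x0,
  with the smoothness constraint x0 = -b / (2 c) so the response has a
  well-defined slope everywhere (the plateau joins the parabola at its
  vertex).

The plateau form is fit by profiling the join point over a deterministic
dense grid and refining the best candidate with a bounded scalar
minimizer — no random initialization, so results are seed-independent.
Model choice keeps the significant, converged candidate with the smaller
residual sum of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats


class UnfittableGroupError(ValueError):
    """Raised when a group has too few distinct N rates to fit a curve."""


@dataclass(frozen=True)
class ResponseFit:
    """One fitted yield-N response curve.

    ``a`` is the intercept (kg ha^-1), ``b`` the linear coefficient (kg yield
    per kg N), ``c`` the quadratic coefficient, ``x0`` the join point
    (kg N ha^-1, plateau form only).  ``p_value`` is from the overall F-test
    of the model against the intercept-only model.  ``fit_level`` records
    whether replicate observations or treatment means were fit.
    """

    form: str  # "quadratic" | "quadratic_plateau"
    a: float
    b: float
    c: float
    x0: float | None
    ss_res: float
    r2: float
    p_value: float
    converged: bool
    n_obs: int
    fit_level: str = "replicate"


def _as_xy(group) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(group, pd.DataFrame):
        x = group["n_rate"].to_numpy(float)
        y = group["yield"].to_numpy(float)
    else:
        x, y = group
        x = np.asarray(x, float)
        y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expected paired 1-d N-rate and yield arrays")
    return x, y


def _check_fittable(x: np.ndarray) -> None:
    if len(np.unique(x)) < 3:
        raise UnfittableGroupError(
            f"need >=3 distinct N rates to fit a response, got {len(np.unique(x))}"
        )
    if len(x) < 4:
        raise UnfittableGroupError("need >=4 observations to fit a response")


def _overall_f_pvalue(ss_res: float, ss_tot: float, n: int, df_model: int) -> float:
    """p of the F-test of the fitted model against the intercept-only model."""
    df_resid = n - df_model - 1
    if df_resid <= 0 or ss_tot <= 0:
        return 1.0
    if ss_res <= 0:
        return 0.0
    f = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, df_model, df_resid))


def fit_quadratic(group, fit_level: str = "replicate") -> ResponseFit:
    """Ordinary least squares fit of y = a + b x + c x^2.

    ``group`` is a DataFrame with ``n_rate``/``yield`` columns or an (x, y)
    pair of arrays.  Requires >=3 distinct rates and >=4 points.
    """
    x, y = _as_xy(group)
    _check_fittable(x)
    X = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    p = _overall_f_pvalue(ss_res, ss_tot, len(y), df_model=2)
    a, b, c = (float(v) for v in coef)
    return ResponseFit(
        form="quadratic",
        a=a,
        b=b,
        c=c,
        x0=None,
        ss_res=ss_res,
        r2=max(0.0, min(1.0, r2)),
        p_value=p,
        converged=True,
        n_obs=len(y),
        fit_level=fit_level,
    )


def _qp_basis(x: np.ndarray, x0: float) -> np.ndarray:
    """Regressor of the profiled plateau model: y = a + c * g(x; x0).

    With the smoothness constraint b = -2 c x0 the curve below the join is
    a + c (x^2 - 2 x0 x) and the plateau value is a - c x0^2.
    """
    below = x < x0
    g = np.where(below, x * x - 2.0 * x0 * x, -x0 * x0)
    return g


def _qp_profile_ss(x: np.ndarray, y: np.ndarray, x0s: np.ndarray) -> np.ndarray:
    """Residual SS of the best (a, c) for each candidate join point, vectorized."""
    n = len(x)
    below = x[None, :] < x0s[:, None]
    g = np.where(below, x[None, :] ** 2 - 2.0 * x0s[:, None] * x[None, :], -x0s[:, None] ** 2)
    gbar = g.mean(axis=1)
    ybar = y.mean()
    gc = g - gbar[:, None]
    yc = y - ybar
    var_g = np.einsum("ij,ij->i", gc, gc)
    cov_gy = gc @ yc
    ss_tot = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(var_g > 0, cov_gy / var_g, 0.0)
    ss = ss_tot - c * cov_gy * np.where(var_g > 0, 1.0, 0.0)
    return np.maximum(ss, 0.0)


def _qp_solve_at(x: np.ndarray, y: np.ndarray, x0: float) -> tuple[float, float, float]:
    """(a, c, ss_res) of the plateau model at a fixed join point."""
    g = _qp_basis(x, x0)
    gbar, ybar = g.mean(), y.mean()
    var_g = float(np.sum((g - gbar) ** 2))
    if var_g <= 0:
        c = 0.0
    else:
        c = float(np.sum((g - gbar) * (y - ybar)) / var_g)
    a = float(ybar - c * gbar)
    resid = y - (a + c * g)
    return a, c, float(resid @ resid)


def fit_quadratic_plateau(
    group,
    fit_level: str = "replicate",
    profile_step: float = 1.0,
    profile_span: float = 1.5,
) -> ResponseFit:
    """Fit the smooth quadratic-plateau by join-point profiling.

    The join point x0 is profiled over a dense grid at ``profile_step`` kg N
    resolution; the conditional (a, c) solve at each x0 is linear.  The best
    grid point is refined with a bounded scalar minimizer.  The profile runs
    from just above the second-smallest distinct rate (so at least two
    distinct rates pin the quadratic segment — below that the join point is
    not identifiable and the model degenerates to a step) to ``profile_span``
    times the largest rate.  The fit reports ``converged=False`` (rather
    than raising) when the best solution has c >= 0 or its join point sits
    at a profile boundary — degenerate or non-plateauing data.
    """
    x, y = _as_xy(group)
    _check_fittable(x)
    lo = float(np.unique(x)[1])
    hi = float(profile_span * x.max())
    if hi <= lo:
        hi = lo + 1.0
    x0s = np.arange(lo + profile_step, hi + profile_step / 2, profile_step)
    ss = _qp_profile_ss(x, y, x0s)
    i = int(np.argmin(ss))
    # bounded local refinement around the best grid candidate
    left = x0s[max(i - 1, 0)]
    right = x0s[min(i + 1, len(x0s) - 1)]
    if right > left:
        res = optimize.minimize_scalar(
            lambda t: _qp_solve_at(x, y, t)[2],
            bounds=(left, right),
            method="bounded",
            options={"xatol": 1e-6},
        )
        x0 = float(res.x)
        if _qp_solve_at(x, y, x0)[2] > ss[i]:
            x0 = float(x0s[i])
    else:
        x0 = float(x0s[i])
    a, c, ss_res = _qp_solve_at(x, y, x0)
    b = -2.0 * c * x0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    p = _overall_f_pvalue(ss_res, ss_tot, len(y), df_model=2)
    edge_tol = 1.5 * profile_step
    converged = c < 0 and (lo + edge_tol) < x0 < (hi - edge_tol)
    return ResponseFit(
        form="quadratic_plateau",
        a=a,
        b=b,
        c=c,
        x0=x0,
        ss_res=ss_res,
        r2=max(0.0, min(1.0, r2)),
        p_value=p,
        converged=converged,
        n_obs=len(y),
        fit_level=fit_level,
    )


def select_model(
    fq: ResponseFit | None, fqp: ResponseFit | None, alpha: float = 0.05
) -> ResponseFit | None:
    """Choose between the two candidate fits of one group.

    Non-converged and non-significant (p >= alpha) candidates are discarded;
    among survivors the smaller residual SS wins (equivalently the larger R^2
    on the same data).  Exact SS ties prefer the plateau form, a biologically
    bounded response.  Returns ``None`` when nothing survives — the group is
    flagged non-responsive / unfitted.
    """
    survivors = [
        f
        for f in (fq, fqp)
        if f is not None and f.converged and f.p_value < alpha
    ]
    if not survivors:
        return None
    if len(survivors) == 1:
        return survivors[0]
    fq_s, fqp_s = survivors if survivors[0].form == "quadratic" else survivors[::-1]
    if fqp_s.ss_res <= fq_s.ss_res:
        return fqp_s
    return fq_s


def fit_group(
    group, alpha: float = 0.05, fit_level: str = "replicate"
) -> ResponseFit | None:
    """Convenience: fit both forms and select, as used throughout the pipeline."""
    fq = fit_quadratic(group, fit_level=fit_level)
    fqp = fit_quadratic_plateau(group, fit_level=fit_level)
    return select_model(fq, fqp, alpha=alpha)


def predict_yield(fit: ResponseFit, x) -> np.ndarray | float:
    """Evaluate a converged fit at N rate(s) ``x`` (kg N ha^-1, >= 0)."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    arr = np.asarray(x, float)
    if np.any(arr < 0):
        raise ValueError("N rate must be non-negative")
    if fit.form == "quadratic_plateau":
        assert fit.x0 is not None
        xe = np.minimum(arr, fit.x0)
    else:
        xe = arr
    out = fit.a + fit.b * xe + fit.c * xe * xe
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def fit_all_groups(
    table, alpha: float = 0.05, fit_level: str = "replicate"
) -> pd.DataFrame:
    """Fit every (year, rotation) corn group of a TrialTable.

    Returns one row per group with both candidate fits' diagnostics and the
    selected form (or ``none`` for non-responsive groups).  ``fit_level``
    ``"mean"`` averages replicates per treatment before fitting.
    """
    rows = []
    for (year, rot), grp in table.groups("corn"):
        if fit_level == "mean":
            grp = grp.groupby("n_rate", as_index=False)["yield"].mean()
        try:
            fq = fit_quadratic(grp, fit_level=fit_level)
            fqp = fit_quadratic_plateau(grp, fit_level=fit_level)
        except UnfittableGroupError:
            rows.append({"year": year, "rotation": rot, "selected": "unfittable"})
            continue
        best = select_model(fq, fqp, alpha=alpha)
        row = {
            "year": year,
            "rotation": rot,
            "selected": best.form if best else "none",
        }
        if best is not None:
            row.update(
                a=best.a,
                b=best.b,
                c=best.c,
                x0=best.x0,
                ss_res=best.ss_res,
                r2=best.r2,
                p_value=best.p_value,
            )
        rows.append(row)
    return pd.DataFrame(rows)
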