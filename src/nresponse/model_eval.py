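"""Agreement statistics between simulated and observed series.

RMSE and its observed-mean-relative form (RRMSE, %) quantify how well a
model reproduces observations; RRMSE <= 15% counts as good agreement,
15-30% moderate, >= 30% poor.  ``evaluation_report`` lays the statistics out
per N rate and rotation with a pooled "Mean" row computed over all pairs —
never as an average of the per-rate rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import AnalysisConfig, TrialTable

GOOD, MODERATE, POOR = "good", "moderate", "poor"


@dataclass(frozen=True)
class EvalReport:
    """Agreement statistics for one simulated-vs-observed grouping."""

    grouping: tuple
    n: int
    rmse: float
    rrmse: float | None
    agreement: str | None
    obs_mean: float


def rmse(observed, simulated) -> float:
    """Root mean square error, sqrt(mean((S_i - O_i)^2)), in input units."""
    o = np.asarray(observed, float)
    s = np.asarray(simulated, float)
    if o.shape != s.shape or o.ndim != 1:
        raise ValueError("observed and simulated must be paired 1-d series")
    if len(o) == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((s - o) ** 2)))


def rrmse(observed, simulated) -> float | None:
    """Relative RMSE: 100 * RMSE / mean(observed), in percent.

    Returns ``None`` (undefined) when the observed mean is not positive.
    """
    o = np.asarray(observed, float)
    obar = o.mean() if len(o) else 0.0
    value = rmse(observed, simulated)
    if obar <= 0:
        return None
    return float(100.0 * value / obar)


def classify_agreement(
    rrmse_pct: float | None, bands: tuple[float, float] = (15.0, 30.0)
) -> str | None:
    """Good / moderate / poor agreement class for an RRMSE percentage.

    Boundary convention: exactly good_max classifies as good, exactly
    moderate_max as poor; the middle band is the open interval between them.
    """
    if rrmse_pct is None:
        return None
    if rrmse_pct < 0:
        raise ValueError("RRMSE cannot be negative")
    good_max, moderate_max = bands
    if rrmse_pct <= good_max:
        return GOOD
    if rrmse_pct < moderate_max:
        return MODERATE
    return POOR


def cv_percent(series) -> float | None:
    """Coefficient of variation, 100 * sample SD / mean, in percent."""
    y = np.asarray(series, float)
    if len(y) < 2:
        raise ValueError("CV needs at least two values")
    mean = y.mean()
    if mean <= 0:
        return None
    return float(100.0 * y.std(ddof=1) / mean)


def _pair_tables(
    obs: TrialTable, sim: TrialTable, pair: str = "mean"
) -> pd.DataFrame:
    """Align two trial tables on (year, rotation, crop, n_rate).

    Simulators produce one value per treatment, so the default pairs the
    simulated treatment value against the observed treatment mean; ``pair=
    "replicate"`` instead repeats the simulated value against each observed
    replicate, a sensitivity variant.
    """
    key = ["year", "rotation", "crop", "n_rate"]
    sim_means = sim.treatment_means("corn")
    sim_means = pd.concat([sim_means, sim.treatment_means("soybean")])
    sim_means = sim_means.rename(columns={"yield": "sim"})
    if pair == "mean":
        obs_side = pd.concat(
            [obs.treatment_means("corn"), obs.treatment_means("soybean")]
        ).rename(columns={"yield": "obs"})
    elif pair == "replicate":
        obs_side = obs.df.rename(columns={"yield": "obs"})[key + ["obs"]]
    else:
        raise ValueError(f"unknown pairing {pair!r}")
    merged = obs_side.merge(sim_means, on=key, how="inner")
    if merged.empty:
        raise ValueError("tables share no (year, rotation, crop, n_rate) keys")
    return merged


def _report_for(pairs: pd.DataFrame, grouping: tuple, bands) -> EvalReport:
    o = pairs["obs"].to_numpy(float)
    s = pairs["sim"].to_numpy(float)
    r = rmse(o, s)
    rr = rrmse(o, s)
    return EvalReport(
        grouping=grouping,
        n=len(pairs),
        rmse=r,
        rrmse=rr,
        agreement=classify_agreement(rr, bands),
        obs_mean=float(o.mean()),
    )


def evaluation_report(
    obs: TrialTable,
    sim: TrialTable,
    group_by: tuple[str, ...] = ("rotation", "n_rate"),
    cfg: AnalysisConfig | None = None,
    pair: str = "mean",
) -> list[EvalReport]:
    """Per-group and pooled agreement statistics for two trial tables.

    One report per combination of ``group_by`` values, plus for each value
    of the leading group keys a pooled ``"Mean"`` row computed over that
    slice's concatenated pairs (and a grand pooled row when more than one
    key is grouped on).
    """
    cfg = cfg or AnalysisConfig()
    bands = cfg.agreement_bands
    pairs = _pair_tables(obs, sim, pair=pair)
    reports = [
        _report_for(grp, tuple(key) if isinstance(key, tuple) else (key,), bands)
        for key, grp in pairs.groupby(list(group_by), sort=True)
    ]
    # pooled Mean rows over the leading keys (e.g. one per rotation)
    if len(group_by) > 1:
        lead = list(group_by[:-1])
        for key, grp in pairs.groupby(lead, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            reports.append(_report_for(grp, tuple(key) + ("Mean",), bands))
    reports.append(_report_for(pairs, ("Mean",), bands))
    return reports


def report_to_frame(reports: list[EvalReport]) -> pd.DataFrame:
    """Tabulate evaluation reports for CSV output."""
    return pd.DataFrame(
        {
            "group": " / ".join(str(g) for g in r.grouping),
            "n": r.n,
            "rmse": r.rmse,
            "rrmse_pct": r.rrmse,
            "agreement": r.agreement,
            "obs_mean": r.obs_mean,
        }
        for r in reports
    )
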