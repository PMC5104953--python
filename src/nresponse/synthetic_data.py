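"""Synthetic multi-year, two-rotation N-rate trial generator with known truth.

The generator composes a minimal soil-N / weather / yield process whose
statistical structure matches what the analysis pipeline assumes about a
rainfed Midwest corn experiment:

* rotation-dependent soil N supply — soybean-corn (SC) plots mineralize
  more N than continuous corn (CC), by a configurable factor (default 50%
  higher);
* spring-precipitation-driven fertilizer N loss — the fraction of applied
  N lost to denitrification and leaching grows exponentially with the
  April-June precipitation sum, and the soil supply declines mildly with it;
* a smooth quadratic-plateau yield response to plant-available N,
  multiplied by a year effect and replicate noise;
* atmospheric N deposition proportional to precipitation, folded into the
  supply term;
* soybean yields in the SC rotation drawn independently of the N rate
  applied to the prior corn crop.

Because every piece is analytic, the economically optimal N rate of each
simulated year is available in closed form, enabling parameter-recovery
tests of the whole fit -> select -> optimum chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import EconConfig, TrialTable
from .optimum_n import AT_MAX, AT_ZERO, INTERIOR

#: The five fertilizer treatments of the emulated experiment (kg N ha^-1).
DEFAULT_N_RATES = (0.0, 67.0, 134.0, 201.0, 268.0)
DEFAULT_N_REPS = 4


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of the synthetic weather-N-yield process.

    Yield response operates on plant-available N, A = S + (1 - L) * N_rate,
    where S is the soil supply (mineralization plus deposition, kg N ha^-1)
    and L the precipitation-dependent loss fraction of applied fertilizer.
    Expected yield is ``year_factor * (y0 + b_av * A + c_av * A^2)`` up to
    the vertex A0 = -b_av / (2 c_av), constant beyond — a smooth
    quadratic-plateau in available N, hence also in applied N.

    Defaults place the closed-form true optima near 205 (CC) and 155 (SC)
    kg N ha^-1 at reference precipitation, with CC mean yields spanning
    roughly 4-12 Mg ha^-1 from the zero-N to the top rate.
    """

    y0: float = 2000.0  # base yield intercept, kg ha^-1
    b_av: float = 85.0  # kg yield per kg available N
    c_av: float = -0.16  # curvature, kg yield per (kg N)^2
    s0_cc: float = 80.0  # mean CC soil N supply at reference precip, kg N ha^-1
    sc_supply_factor: float = 1.5  # SC supply multiplier
    supply_precip_slope: float = -0.0005  # fractional supply change per mm
    supply_floor_frac: float = 0.5  # supply never drops below this fraction
    loss_base: float = 0.08  # fertilizer-loss fraction at reference precip
    loss_exp_rate: float = 0.004  # per mm of spring precip
    loss_cap: float = 0.8
    precip_ref: float = 400.0  # reference spring precipitation, mm
    year_effect_cv: float = 0.13  # multiplicative year factor CV
    year_factor_floor: float = 0.4
    rep_cv: float = 0.08  # replicate noise CV
    deposition_coeff: float = 0.01  # kg N ha^-1 per mm precipitation
    soybean_yield_mean: float = 3400.0  # kg ha^-1
    soybean_yield_sd: float = 660.0
    price_ratio: float = 5.6
    n_rates: tuple[float, ...] = DEFAULT_N_RATES
    n_reps: int = DEFAULT_N_REPS
    # weather process (annual / spring / silking-window precipitation, mm)
    annual_precip_mean: float = 900.0
    annual_precip_sd: float = 180.0
    annual_precip_bounds: tuple[float, float] = (550.0, 1300.0)
    spring_precip_mean: float = 400.0
    spring_precip_sd: float = 90.0
    spring_precip_bounds: tuple[float, float] = (150.0, 700.0)
    silking_precip_mean: float = 110.0
    silking_precip_sd: float = 45.0

    def __post_init__(self) -> None:
        if self.c_av >= 0:
            raise ValueError("c_av must be negative (concave response)")
        if not (0 <= self.loss_base < 1 and 0 < self.loss_cap < 1):
            raise ValueError("loss fractions must lie in [0, 1)")
        for cv in (self.year_effect_cv, self.rep_cv):
            if cv < 0:
                raise ValueError("CVs must be non-negative")

    @property
    def available_n_vertex(self) -> float:
        """A0, the available-N rate at which the response plateaus."""
        return -self.b_av / (2.0 * self.c_av)


@dataclass(frozen=True)
class SyntheticExperiment:
    """A generated trial plus its weather and per-year ground truth.

    ``truth`` has one row per corn year x rotation with the closed-form
    optimum (true_eonr, true_yeonr), the supply and loss that produced it,
    and the year factor.
    """

    trial: TrialTable
    weather: pd.DataFrame
    truth: pd.DataFrame
    params: GeneratorParams


def simulate_weather(
    n_years: int, params: GeneratorParams | None = None, seed: int | None = 0
) -> pd.DataFrame:
    """Draw yearly precipitation summaries (annual, spring, silking-window).

    Annual totals are normal around 900 mm (sd 180) clipped to [550, 1300];
    the April-June spring sum is normal around 400 mm (sd 90) clipped to
    [150, min(700, annual)]; the July silking-window sum is normal around
    110 mm (sd 45) clipped at zero.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    annual = np.clip(
        rng.normal(p.annual_precip_mean, p.annual_precip_sd, n_years),
        *p.annual_precip_bounds,
    )
    spring = np.clip(
        rng.normal(p.spring_precip_mean, p.spring_precip_sd, n_years),
        p.spring_precip_bounds[0],
        np.minimum(p.spring_precip_bounds[1], annual),
    )
    silking = np.clip(
        rng.normal(p.silking_precip_mean, p.silking_precip_sd, n_years), 0.0, None
    )
    return pd.DataFrame(
        {
            "year": np.arange(2000, 2000 + n_years),
            "annual_precip": annual,
            "spring_precip": spring,
            "silking_precip": silking,
        }
    )


def n_deposition(precip_mm, coeff: float = 0.01):
    """Atmospheric N deposition, kg N ha^-1, proportional to precipitation.

    Linear in precipitation, so summing daily deposition equals applying the
    coefficient to the annual total.
    """
    arr = np.asarray(precip_mm, float)
    if np.any(arr < 0):
        raise ValueError("precipitation must be non-negative")
    out = coeff * arr
    return float(out) if np.isscalar(precip_mm) else out


def loss_fraction(spring_precip: float, params: GeneratorParams | None = None) -> float:
    """Fraction of applied fertilizer N lost, exponential in spring precip.

    ``loss_base`` at the reference precipitation, growing by ``loss_exp_rate``
    per mm above it and capped at ``loss_cap``.
    """
    if spring_precip < 0:
        raise ValueError("precipitation must be non-negative")
    p = params or GeneratorParams()
    raw = p.loss_base * math.exp(p.loss_exp_rate * (spring_precip - p.precip_ref))
    return min(p.loss_cap, raw)


def supply(
    spring_precip: float, rotation: str, params: GeneratorParams | None = None
) -> float:
    """Soil N supply (kg N ha^-1) for one rotation at a spring precipitation.

    The CC baseline declines linearly with precipitation above the reference
    (wet springs mineralize into a leaky profile), floored at half the
    baseline; SC supply is the same shape scaled by ``sc_supply_factor``.
    """
    if spring_precip < 0:
        raise ValueError("precipitation must be non-negative")
    p = params or GeneratorParams()
    factor = p.sc_supply_factor if rotation in ("SC", "SC_val") else 1.0
    wet = max(
        p.supply_floor_frac,
        1.0 + p.supply_precip_slope * (spring_precip - p.precip_ref),
    )
    return p.s0_cc * factor * wet


def _qp_available(a_n: np.ndarray, p: GeneratorParams) -> np.ndarray:
    a0 = p.available_n_vertex
    ae = np.minimum(a_n, a0)
    return p.y0 + p.b_av * ae + p.c_av * ae * ae


def true_yield(
    n_rate,
    supply_n: float,
    loss: float,
    year_factor: float = 1.0,
    params: GeneratorParams | None = None,
):
    """Expected yield (kg ha^-1) at an applied N rate, given supply and loss."""
    p = params or GeneratorParams()
    n = np.asarray(n_rate, float)
    available = supply_n + (1.0 - loss) * n
    out = np.maximum(0.0, year_factor * _qp_available(available, p))
    return float(out) if np.isscalar(n_rate) else out


def true_eonr(
    supply_n: float,
    loss: float,
    year_factor: float = 1.0,
    params: GeneratorParams | None = None,
    econ: EconConfig | None = None,
) -> tuple[float, float, str]:
    """Closed-form economically optimal applied N rate and its yield.

    Marginal yield per kg applied N is ``year_factor * (b_av + 2 c_av A) *
    (1 - L)``; setting it equal to the price ratio gives
    ``A* = (ratio / ((1 - L) * year_factor) - b_av) / (2 c_av)`` and
    ``N* = (A* - S) / (1 - L)``, clamped at zero when the soil already
    supplies more than the economic optimum.  Returns (eonr, yeonr,
    boundary flag).
    """
    p = params or GeneratorParams()
    ratio = (econ or EconConfig(price_ratio=p.price_ratio)).price_ratio
    if loss >= 1.0:
        return 0.0, true_yield(0.0, supply_n, loss, year_factor, p), AT_ZERO
    a_star = (ratio / ((1.0 - loss) * year_factor) - p.b_av) / (2.0 * p.c_av)
    n_star = (a_star - supply_n) / (1.0 - loss)
    boundary = INTERIOR
    if n_star <= 0:
        n_star, boundary = 0.0, AT_ZERO
    y_star = true_yield(n_star, supply_n, loss, year_factor, p)
    return float(n_star), float(y_star), boundary


def generate_experiment(
    n_years: int, params: GeneratorParams | None = None, seed: int | None = 0
) -> SyntheticExperiment:
    """Generate a replicated two-rotation trial with per-year ground truth.

    Per year: weather is drawn; a multiplicative year factor ~ Normal(1,
    year_effect_cv) truncated at ``year_factor_floor``; per rotation the
    supply (mineralization plus annual deposition) and loss fraction are
    computed and expected yields at the treatment rates perturbed by
    replicate noise ``(1 + Normal(0, rep_cv))``.  SC soybean rows (the
    rotation's other phase) are drawn independently of prior corn N.  All
    randomness flows from the single ``seed``.
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    weather = simulate_weather(n_years, p, seed=rng.integers(2**31))
    records = []
    truth_rows = []
    for row in weather.itertuples(index=False):
        year = int(row.year)
        year_factor = max(
            p.year_factor_floor, float(rng.normal(1.0, p.year_effect_cv))
        )
        loss = loss_fraction(row.spring_precip, p)
        deposition = n_deposition(row.annual_precip, p.deposition_coeff)
        for rotation in ("CC", "SC"):
            s = supply(row.spring_precip, rotation, p) + deposition
            expected = true_yield(np.asarray(p.n_rates), s, loss, year_factor, p)
            noise = rng.normal(0.0, p.rep_cv, size=(p.n_reps, len(p.n_rates)))
            yields = np.maximum(0.0, expected[None, :] * (1.0 + noise))
            for rep in range(p.n_reps):
                for j, rate in enumerate(p.n_rates):
                    records.append(
                        {
                            "year": year,
                            "rotation": rotation,
                            "crop": "corn",
                            "n_rate": rate,
                            "rep": rep + 1,
                            "yield": yields[rep, j],
                        }
                    )
            eonr, yeonr, boundary = true_eonr(s, loss, year_factor, p)
            truth_rows.append(
                {
                    "year": year,
                    "rotation": rotation,
                    "true_eonr": eonr,
                    "true_yeonr": yeonr,
                    "boundary": boundary,
                    "supply": s,
                    "loss_fraction": loss,
                    "year_factor": year_factor,
                }
            )
        # soybean phase of the SC rotation: independent of prior corn N
        soy = rng.normal(
            p.soybean_yield_mean, p.soybean_yield_sd, size=(p.n_reps, len(p.n_rates))
        )
        for rep in range(p.n_reps):
            for j, rate in enumerate(p.n_rates):
                records.append(
                    {
                        "year": year,
                        "rotation": "SC",
                        "crop": "soybean",
                        "n_rate": rate,
                        "rep": rep + 1,
                        "yield": max(0.0, soy[rep, j]),
                    }
                )
    trial = TrialTable(pd.DataFrame(records))
    return SyntheticExperiment(
        trial=trial, weather=weather, truth=pd.DataFrame(truth_rows), params=p
    )
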