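"""Data model, validation, file I/O and configuration for N-rate trial analysis.

The central container is :class:`TrialTable`, a thin wrapper around a pandas
DataFrame holding replicate-level grain yields from a multi-year nitrogen
rate experiment.  Yields are always stored internally in kg ha^-1 and
fertilizer N in kg N ha^-1; unit conversion happens once, at load time.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Valid rotation labels.  ``CC`` = continuous corn, ``SC`` = soybean-corn
#: rotation (corn receiving the N treatments), ``SC_val`` = an even-start
#: validation subset kept as a distinct group but treated identically by
#: all computations.
ROTATIONS = ("CC", "SC", "SC_val")

#: Valid crop labels.
CROPS = ("corn", "soybean")

#: Canonical column order for trial CSV files.
TRIAL_COLUMNS = ("year", "rotation", "crop", "n_rate", "rep", "yield")

#: Factors converting a declared yield unit to the internal kg ha^-1.
UNIT_SCALES = {"kg_ha": 1.0, "mg_ha": 1000.0}


class TrialFormatError(ValueError):
    """A trial file does not conform to the expected CSV layout."""


class TrialValidationError(ValueError):
    """Trial records violate a hard invariant (negative rates, duplicates...)."""


@dataclass(frozen=True)
class EconConfig:
    """Economic assumptions for optimum-N computations.

    Parameters
    ----------
    price_ratio:
        Cost of 1 kg fertilizer N expressed as kg of corn grain (the
        break-even marginal slope), dimensionless mass ratio.  The default
        of 5.6 reflects the long-run N:grain price ratio used for Midwest
        corn.
    yield_unit_scale:
        Factor converting the declared yield unit to kg ha^-1.
    """

    price_ratio: float = 5.6
    yield_unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.price_ratio <= 0:
            raise ValueError("price_ratio must be positive")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings shared across the pipeline.

    ``rtn_grid`` is the (start, stop, step) N-rate grid in kg N ha^-1 used by
    the return-to-N scan; ``agreement_bands`` are the (good_max, moderate_max)
    RRMSE percentages separating good / moderate / poor model agreement.
    """

    rtn_grid: tuple[float, float, float] = (0.0, 350.0, 5.0)
    alpha: float = 0.05
    agreement_bands: tuple[float, float] = (15.0, 30.0)
    outlier_iqr_multiplier: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        start, stop, step = self.rtn_grid
        if step <= 0 or stop <= start:
            raise ValueError("rtn_grid must satisfy step > 0 and stop > start")
        good, moderate = self.agreement_bands
        if not (0 < good < moderate):
            raise ValueError("agreement_bands must satisfy 0 < good_max < moderate_max")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class Finding:
    """One validation finding (report-only; never blocks loading)."""

    kind: str
    group: tuple
    message: str


class TrialTable:
    """Replicate-level yield observations indexed by year x rotation x N rate.

    Wraps a DataFrame with columns ``year, rotation, crop, n_rate, rep,
    yield`` where yield is in kg ha^-1 regardless of the unit the source
    file declared.  Row order of the source is preserved.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise TrialFormatError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(TRIAL_COLUMNS)].reset_index(drop=True)
        self._check_invariants(df)
        self._df = df

    @staticmethod
    def _check_invariants(df: pd.DataFrame) -> None:
        bad_rot = set(df["rotation"]) - set(ROTATIONS)
        if bad_rot:
            raise TrialValidationError(f"unknown rotation label(s): {sorted(bad_rot)}")
        bad_crop = set(df["crop"]) - set(CROPS)
        if bad_crop:
            raise TrialValidationError(f"unknown crop label(s): {sorted(bad_crop)}")
        for col, label in (("n_rate", "n_rate"), ("yield", "yield")):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals < 0)
            if bad.any():
                row = int(bad.idxmax())
                raise TrialValidationError(
                    f"non-numeric or negative {label} at data row {row + 1}"
                )
        key = ["year", "rotation", "crop", "n_rate", "rep"]
        dup = df.duplicated(subset=key)
        if dup.any():
            row = int(dup.idxmax())
            raise TrialValidationError(
                f"duplicate (year, rotation, crop, n_rate, rep) key at data row {row + 1}"
            )

    @property
    def df(self) -> pd.DataFrame:
        """The underlying records (yield in kg ha^-1). Copy — never a view."""
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self._df.equals(other._df)

    def corn(self) -> pd.DataFrame:
        return self._df[self._df["crop"] == "corn"].copy()

    def groups(self, crop: str = "corn") -> Iterable[tuple[tuple[int, str], pd.DataFrame]]:
        """Iterate (year, rotation) groups of one crop, in first-seen order."""
        sub = self._df[self._df["crop"] == crop]
        for key, grp in sub.groupby(["year", "rotation"], sort=False):
            yield (int(key[0]), str(key[1])), grp.copy()

    def mean_yield_by_rate(
        self, rotation: str | None = None, crop: str = "corn"
    ) -> pd.Series:
        """Treatment-mean yield (kg ha^-1) per N rate, across years and reps."""
        sub = self._df[self._df["crop"] == crop]
        if rotation is not None:
            sub = sub[sub["rotation"] == rotation]
        return sub.groupby("n_rate")["yield"].mean()

    def treatment_means(self, crop: str = "corn") -> pd.DataFrame:
        """Per-(year, rotation, n_rate) mean yields, replicates averaged out."""
        sub = self._df[self._df["crop"] == crop]
        out = (
            sub.groupby(["year", "rotation", "crop", "n_rate"], sort=False, as_index=False)[
                "yield"
            ]
            .mean()
        )
        return out

    def to_csv(self, path: str | Path, units: str = "kg_ha") -> None:
        """Write the table with yields expressed in ``units``."""
        scale = _unit_scale(units)
        out = self._df.copy()
        out["yield"] = out["yield"] / scale
        out.to_csv(path, index=False)


def _unit_scale(units: str) -> float:
    try:
        return UNIT_SCALES[units]
    except KeyError:
        raise TrialFormatError(
            f"unknown yield unit {units!r}; expected one of {sorted(UNIT_SCALES)}"
        ) from None


def load_trial_table(path: str | Path, units: str = "kg_ha") -> TrialTable:
    """Read a trial CSV, validate it, and normalize yields to kg ha^-1.

    The file must carry the header ``year,rotation,crop,n_rate,rep,yield``;
    ``units`` declares the unit of the yield column (``kg_ha`` or ``mg_ha``).
    Row order is preserved.  A malformed header raises
    :class:`TrialFormatError`; bad rows raise :class:`TrialValidationError`
    naming the offending data row.
    """
    scale = _unit_scale(units)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing column(s): {', '.join(missing)}")
    df["yield"] = pd.to_numeric(df["yield"], errors="coerce") * scale
    df["n_rate"] = pd.to_numeric(df["n_rate"], errors="coerce")
    return TrialTable(df)


def validate_trial(
    table: TrialTable, cfg: AnalysisConfig | None = None
) -> list[Finding]:
    """Report soft data-quality problems without mutating anything.

    Findings cover (a) (year, rotation) corn groups with fewer than 3 distinct
    N rates, which cannot support a curvature fit; (b) unbalanced replicate
    counts across treatments of a group; (c) yields further than
    ``outlier_iqr_multiplier`` interquartile ranges from their treatment-group
    median.
    """
    cfg = cfg or AnalysisConfig()
    findings: list[Finding] = []
    for (year, rot), grp in table.groups("corn"):
        n_rates = grp["n_rate"].nunique()
        if n_rates < 3:
            findings.append(
                Finding(
                    "unfittable_group",
                    (year, rot),
                    f"only {n_rates} distinct N rate(s); need >=3 to fit a response",
                )
            )
        reps = grp.groupby("n_rate")["rep"].count()
        if reps.nunique() > 1:
            findings.append(
                Finding(
                    "unbalanced_replicates",
                    (year, rot),
                    f"replicate counts per rate vary: {dict(reps)}",
                )
            )
    key = ["year", "rotation", "crop", "n_rate"]
    k = cfg.outlier_iqr_multiplier
    for name, grp in table.df.groupby(key, sort=False):
        y = grp["yield"].to_numpy(float)
        if len(y) < 3:
            continue
        q1, med, q3 = np.percentile(y, [25, 50, 75])
        iqr = q3 - q1
        if iqr == 0:
            continue
        mask = np.abs(y - med) > k * iqr
        for idx in grp.index[mask]:
            findings.append(
                Finding(
                    "yield_outlier",
                    tuple(name),
                    f"yield {grp.loc[idx, 'yield']:.1f} deviates more than "
                    f"{k} x IQR ({iqr:.1f}) from group median {med:.1f}",
                )
            )
    return findings


def load_config(path: str | Path) -> tuple[EconConfig, AnalysisConfig]:
    """Read a YAML key-value file overriding EconConfig/AnalysisConfig defaults.

    Unknown keys raise ``KeyError`` so typos do not pass silently.  Keys are
    flat; tuple-valued settings (``rtn_grid``, ``agreement_bands``) may be
    given as YAML lists.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    econ_fields = {f.name for f in dataclasses.fields(EconConfig)}
    ana_fields = {f.name for f in dataclasses.fields(AnalysisConfig)}
    econ_kwargs, ana_kwargs = {}, {}
    for key, value in raw.items():
        if key in econ_fields:
            econ_kwargs[key] = value
        elif key in ana_fields:
            if isinstance(value, list):
                value = tuple(value)
            ana_kwargs[key] = value
        else:
            raise KeyError(f"unknown config key {key!r}")
    return EconConfig(**econ_kwargs), AnalysisConfig(**ana_kwargs)


def trial_table_from_records(
    records: Sequence[dict] | pd.DataFrame, units: str = "kg_ha"
) -> TrialTable:
    """Build a TrialTable from in-memory records (yield in ``units``)."""
    df = pd.DataFrame(records)
    df["yield"] = pd.to_numeric(df["yield"], errors="coerce") * _unit_scale(units)
    return TrialTable(df)
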