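"""Allometric pollen and seed production and pollen-season statistics.

Pollen grains and seed counts scale as power laws of mature stand biomass.
Seed set is additionally discounted by how far seed maturation progressed
before the season ended: the fraction of the thermal-time maturity
requirement accumulated since flowering, with a floor below which no seed
ripens at all (the mechanism that sets the species' cold northern limit).
Coefficients are order-of-magnitude placeholders and configuration-first:
only ratios of pollen between scenarios are scale-free.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "AllometryParams",
    "SeasonResult",
    "pollen_production",
    "seed_production",
    "maturation_fraction",
    "pollen_season_stats",
]


@dataclass(frozen=True)
class AllometryParams:
    """Power-law coefficients linking mature biomass to pollen and seed."""

    pollen_coeff: float = 1.0e6
    pollen_exp: float = 1.0
    seed_coeff: float = 300.0
    seed_exp: float = 1.0
    min_maturation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.pollen_coeff < 0 or self.seed_coeff < 0:
            raise ConfigurationError("allometric coefficients must be >= 0")
        if self.pollen_exp <= 0 or self.seed_exp <= 0:
            raise ConfigurationError("allometric exponents must be > 0")
        if not 0.0 <= self.min_maturation_fraction <= 1.0:
            raise ConfigurationError("min_maturation_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SeasonResult:
    """Pollen-season summary of one simulated year.

    Dates are absent (None) when the plant died before flowering or never
    emerged, in which case pollen and seed are exactly zero.
    """

    season_start: Optional[dt.date]
    season_end: Optional[dt.date]
    termination_reason: Optional[str]
    pollen: float
    matured_seed: float
    maturation_fraction: float


def pollen_production(mature_biomass: float,
                      params: AllometryParams = AllometryParams()) -> float:
    """Pollen grains m⁻² from mature stand biomass: coeff × biomass^exp."""
    if mature_biomass < 0:
        raise InputError("biomass must be >= 0")
    return params.pollen_coeff * mature_biomass ** params.pollen_exp


def seed_production(mature_biomass: float, maturation: float,
                    params: AllometryParams = AllometryParams()) -> float:
    """Seeds m⁻² from mature biomass, discounted by maturation progress.

    The discount is the maturation fraction itself, except below the floor
    ``min_maturation_fraction`` where no seed ripens at all.
    """
    if mature_biomass < 0:
        raise InputError("biomass must be >= 0")
    if not 0.0 <= maturation <= 1.0:
        raise InputError("maturation fraction must be in [0, 1]")
    effective = 0.0 if maturation < params.min_maturation_fraction else maturation
    return params.seed_coeff * mature_biomass ** params.seed_exp * effective


def maturation_fraction(tt_since_flowering: float, maturity_tt: float) -> float:
    """Fraction of the seed-maturation thermal-time requirement achieved."""
    if maturity_tt <= 0:
        raise ConfigurationError("maturity_tt must be > 0")
    if tt_since_flowering < 0:
        raise InputError("tt_since_flowering must be >= 0")
    return min(1.0, tt_since_flowering / maturity_tt)


def pollen_season_stats(daily_trace: pd.DataFrame, maturity_tt: float,
                        params: AllometryParams = AllometryParams()) -> SeasonResult:
    """Recompute the pollen-season summary from a recorded daily trace.

    The trace is one simulated year with columns ``date, stage,
    tt_since_flowering, total_biomass, termination_reason, death_cause``
    (as written by the annual simulation with tracing enabled).  Season
    start is the first flowering day, season end the day the season
    terminated; pollen is computed from the biomass on that day.
    """
    required = {"date", "stage", "tt_since_flowering", "total_biomass",
                "termination_reason", "death_cause"}
    missing = required - set(daily_trace.columns)
    if missing:
        raise InputError(f"trace missing columns: {sorted(missing)}")

    flowering = daily_trace[daily_trace["stage"] == "flowering"]
    if flowering.empty:
        return SeasonResult(season_start=None, season_end=None,
                            termination_reason=None, pollen=0.0,
                            matured_seed=0.0, maturation_fraction=0.0)

    start = pd.Timestamp(flowering["date"].iloc[0]).date()
    terminated = daily_trace[daily_trace["termination_reason"].notna()
                             | daily_trace["death_cause"].notna()]
    if terminated.empty:  # season ran to the end of the record
        last = daily_trace.iloc[-1]
        reason = "year_end"
    else:
        last = terminated.iloc[0]
        reason = last["termination_reason"] if pd.notna(last["termination_reason"]) \
            else last["death_cause"]
    end = pd.Timestamp(last["date"]).date()
    biomass = float(last["total_biomass"])
    frac = maturation_fraction(float(last["tt_since_flowering"]), maturity_tt)
    return SeasonResult(season_start=start, season_end=end,
                        termination_reason=reason,
                        pollen=pollen_production(biomass, params),
                        matured_seed=seed_production(biomass, frac, params),
                        maturation_fraction=frac)
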