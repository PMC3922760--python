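"""Daily plant development, biomass growth, mortality and flowering rules.

Phenology runs on thermal time with a triangular temperature response
(base 0.9 °C, optimum 31.7 °C, and an assumed ceiling of 40 °C that makes
the optimum a unique maximum).  Flowering starts on a fixed calendar date
(1 August) — ragweed populations synchronise flowering regionally rather
than following a latitude/photoperiod gradient — and ends at the first of
four rules:

1. accumulated thermal time since flowering reaches the maturity
   requirement;
2. frost: daily minimum temperature below 0 °C;
3. cold spell: 5-day mean daily minimum temperature below 7 °C;
4. severe drought: 10-day mean actual/potential transpiration below 0.1.

Independently, from germination onwards the plant is *killed* by frost
(daily minimum ≤ 0 °C, inclusive) or by the same 10-day drought rule;
death before flowering means zero pollen and seed for the year.

Stand biomass accrues by radiation-use efficiency on light intercepted
through a Beer's-law canopy, modulated by the thermal-time temperature
factor and the transpiration ratio, and is split between organs by a
stage-dependent allocation table.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConfigurationError, SimulationStateError

__all__ = [
    "PhenologyParams",
    "GrowthParams",
    "PlantState",
    "STAGES",
    "thermal_time_increment",
    "daily_growth",
    "check_flowering_onset",
    "check_end_of_flowering",
    "check_mortality",
]

STAGES = ("pre-emergent", "vegetative", "flowering", "terminated", "dead")
ORGANS = ("root", "stem", "leaf", "reproductive")

#: End-of-flowering rule priority when several fire on the same day.
RULE_PRIORITY = ("thermal_time", "frost", "cold_spell", "drought")


@dataclass(frozen=True)
class PhenologyParams:
    """Thermal-time response, flowering calendar and termination thresholds.

    ``flowering_onset`` is a (month, day) calendar date, not a Julian day,
    so it falls on the same date in leap years.  The senescence frost rule
    is strict (< 0 °C) while the kill rule is inclusive (≤ 0 °C); both are
    implemented exactly as stated even though the asymmetry looks odd.
    """

    t_base: float = 0.9
    t_opt: float = 31.7
    t_ceil: float = 40.0
    flowering_onset: tuple[int, int] = (8, 1)
    maturity_tt: float = 1200.0
    frost_kill_tmin: float = 0.0
    senescence_tmin: float = 0.0
    senescence_5day_tmin_mean: float = 7.0
    senescence_window: int = 5
    drought_ratio_threshold: float = 0.1
    drought_window: int = 10

    def __post_init__(self) -> None:
        if not self.t_base < self.t_opt < self.t_ceil:
            raise ConfigurationError("require t_base < t_opt < t_ceil")
        if self.maturity_tt <= 0:
            raise ConfigurationError("maturity_tt must be > 0")
        if self.drought_window < 1 or self.senescence_window < 1:
            raise ConfigurationError("rule windows must be >= 1 day")
        m, d = self.flowering_onset
        dt.date(2001, m, d)  # validates the calendar date


def _default_allocation() -> dict[str, dict[str, float]]:
    return {
        "vegetative": {"root": 0.25, "stem": 0.20, "leaf": 0.55, "reproductive": 0.0},
        "flowering": {"root": 0.05, "stem": 0.10, "leaf": 0.05, "reproductive": 0.80},
    }


@dataclass(frozen=True)
class GrowthParams:
    """Radiation-use growth and allocation parameters.

    rue
        radiation-use efficiency, g dry matter per MJ intercepted.
    k_ext
        Beer's-law canopy extinction coefficient.
    sla
        specific leaf area, m² leaf per g leaf.
    allocation_table
        per-stage fractions over organs, each stage summing to 1.
    initial_seedling_mass
        per-plant mass at emergence, g; bootstraps interception so the
        Beer's-law term is non-zero on day one.
    density_cap
        self-thinning ceiling on established plants, plants m⁻².
    """

    rue: float = 1.5
    k_ext: float = 0.6
    sla: float = 0.02
    allocation_table: dict[str, dict[str, float]] = field(default_factory=_default_allocation)
    initial_seedling_mass: float = 0.01
    density_cap: float = 200.0

    def __post_init__(self) -> None:
        if self.rue <= 0 or self.k_ext <= 0 or self.sla <= 0:
            raise ConfigurationError("rue, k_ext and sla must be > 0")
        if self.initial_seedling_mass <= 0 or self.density_cap <= 0:
            raise ConfigurationError("initial_seedling_mass and density_cap must be > 0")
        for stage, fractions in self.allocation_table.items():
            if set(fractions) != set(ORGANS):
                raise ConfigurationError(f"allocation for stage {stage!r} must cover {ORGANS}")
            if any(not 0.0 <= f <= 1.0 for f in fractions.values()):
                raise ConfigurationError(f"allocation fractions for {stage!r} outside [0, 1]")
            if abs(sum(fractions.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"allocation fractions for {stage!r} must sum to 1")


@dataclass
class PlantState:
    """Stand-level plant state (biomass pools in g m⁻²)."""

    stage: str = "pre-emergent"
    tt_since_emergence: float = 0.0
    tt_since_flowering: float = 0.0
    biomass: dict[str, float] = field(default_factory=lambda: {o: 0.0 for o in ORGANS})
    lai: float = 0.0
    termination_reason: Optional[str] = None
    death_cause: Optional[str] = None

    @property
    def total_biomass(self) -> float:
        return sum(self.biomass.values())

    @property
    def alive(self) -> bool:
        return self.stage in ("vegetative", "flowering")


def thermal_time_increment(tmean: float, params: PhenologyParams = PhenologyParams()) -> float:
    """Daily thermal-time increment (°Cd): triangular in temperature.

    Zero at/below the base, rising as (tmean − t_base) to the unique
    maximum (t_opt − t_base) at the optimum, declining linearly to zero at
    the ceiling, zero beyond.
    """
    if tmean <= params.t_base or tmean >= params.t_ceil:
        return 0.0
    if tmean <= params.t_opt:
        return tmean - params.t_base
    peak = params.t_opt - params.t_base
    return peak * (params.t_ceil - tmean) / (params.t_ceil - params.t_opt)


def daily_growth(state: PlantState, radiation: float, transp_ratio: float,
                 tmean: float, params: GrowthParams = GrowthParams(),
                 phen: PhenologyParams = PhenologyParams()) -> PlantState:
    """Advance an alive plant by one day of growth.

    Biomass increment = rue × radiation × (1 − exp(−k_ext·LAI)) × f_temp ×
    transp_ratio, with f_temp the thermal-time increment normalised by its
    maximum; the increment is split across organs by the stage's
    allocation fractions (conserved exactly) and LAI follows leaf biomass.
    Thermal-time counters advance by the same increment.
    """
    if not state.alive:
        raise SimulationStateError(f"daily_growth called on {state.stage} plant")
    tt = thermal_time_increment(tmean, phen)
    f_temp = tt / (phen.t_opt - phen.t_base)
    intercepted = radiation * (1.0 - math.exp(-params.k_ext * state.lai))
    increment = params.rue * intercepted * f_temp * transp_ratio
    alloc = params.allocation_table[state.stage]
    for organ in ORGANS:
        state.biomass[organ] += increment * alloc[organ]
    state.lai = state.biomass["leaf"] * params.sla
    state.tt_since_emergence += tt
    if state.stage == "flowering":
        state.tt_since_flowering += tt
    return state


def check_flowering_onset(date: dt.date, params: PhenologyParams = PhenologyParams()) -> bool:
    """True on and after the fixed flowering-onset calendar date of that year."""
    m, d = params.flowering_onset
    return date >= dt.date(date.year, m, d)


def _mean_tail(values: Sequence[float], n: int) -> float:
    tail = values[-n:]
    return sum(tail) / len(tail)


def check_end_of_flowering(tmin_history: Sequence[float], tt_since_flowering: float,
                           transp_history: Sequence[float],
                           params: PhenologyParams = PhenologyParams()) -> Optional[str]:
    """First end-of-flowering rule triggered today, or None.

    ``tmin_history`` / ``transp_history`` are the daily minima and
    transpiration ratios up to and including today; windowed rules are
    evaluated only once enough history exists.  Same-day collisions are
    resolved in the fixed priority order thermal_time, frost, cold_spell,
    drought.
    """
    if tt_since_flowering >= params.maturity_tt:
        return "thermal_time"
    if len(tmin_history) >= 1 and tmin_history[-1] < params.senescence_tmin:
        return "frost"
    if (len(tmin_history) >= params.senescence_window
            and _mean_tail(tmin_history, params.senescence_window)
            < params.senescence_5day_tmin_mean):
        return "cold_spell"
    if (len(transp_history) >= params.drought_window
            and _mean_tail(transp_history, params.drought_window)
            < params.drought_ratio_threshold):
        return "drought"
    return None


def check_mortality(daily_tmin: float, transp_history: Sequence[float], stage: str,
                    params: PhenologyParams = PhenologyParams()) -> Optional[str]:
    """Death cause for an emerged plant today, or None.

    Frost kills at daily minimum ≤ 0 °C (inclusive); drought kills when
    the 10-day mean transpiration ratio is below 0.1.  Callers must treat
    death before flowering as a zero-seed, zero-pollen year.
    """
    if stage not in ("vegetative", "flowering"):
        return None
    if daily_tmin <= params.frost_kill_tmin:
        return "frost"
    if (len(transp_history) >= params.drought_window
            and _mean_tail(transp_history, params.drought_window)
            < params.drought_ratio_threshold):
        return "drought"
    return None
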