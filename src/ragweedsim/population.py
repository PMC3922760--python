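"""Annual population projection, ensemble growth rate and suitability.

Each replicate simulates one full year of the annual-plant life cycle on
one weather year drawn from a generated pool, starting from a fixed
reference seedbank: winter chilling breaks dormancy, hydrothermal time
drives germination, a stochastic fraction of the germinable pool emerges
as a stand, the stand grows, flowers from 1 August and ends its season by
the termination rules, and seed returns to the bank after predation while
the residual bank decays exponentially.  The finite growth rate of the
year is λ = seed_out / seed_in; the asymptotic growth rate Λ is the mean
of log λ over the replicate ensemble, and a six-class ordered suitability
index (U.0 … E.1) is assigned from Λ.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .germination import (DormancyParams, GerminationParams, PredationDraw,
                          SeedBankState, SeedFateParams, clamp_dormancy_level,
                          cumulative_germination, dormancy_release_rate,
                          draw_emergence_fraction, draw_predation_loss,
                          hydrothermal_increment, seedbank_annual_survival)
from .growth import (GrowthParams, ORGANS, PhenologyParams, PlantState,
                     check_end_of_flowering, check_flowering_onset,
                     check_mortality, daily_growth, thermal_time_increment)
from .reproduction import (AllometryParams, SeasonResult, maturation_fraction,
                           pollen_production, seed_production)
from .soil import SOIL_PRESETS, SoilParams, SoilState, update_water_balance
from .weather import ScenarioDelta, SiteClimate, apply_scenario, generate_weather

__all__ = [
    "SimulationParams",
    "AnnualOutcome",
    "SiteResult",
    "SuitabilityScale",
    "DEFAULT_SCALE",
    "simulate_year",
    "run_site",
    "asymptotic_growth_rate",
    "classify_suitability",
    "pollen_change",
    "POLLEN_CHANGE_SENTINEL",
]


@dataclass(frozen=True)
class SimulationParams:
    """Bundle of all sub-model parameters for one simulation.

    ``reference_seedbank`` is the standardised bank every replicate starts
    from (seeds m⁻²); ``emergence_trigger_fraction`` is the share of the
    maximum germination at which the cohort is taken to emerge (its median
    germination day).
    """

    dormancy: DormancyParams = field(default_factory=DormancyParams)
    germination: GerminationParams = field(default_factory=GerminationParams)
    seed_fate: SeedFateParams = field(default_factory=SeedFateParams)
    soil: SoilParams = field(default_factory=SoilParams)
    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    reference_seedbank: float = 10000.0
    emergence_trigger_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.reference_seedbank <= 0:
            raise ConfigurationError("reference_seedbank must be > 0")
        if not 0.0 < self.emergence_trigger_fraction < 1.0:
            raise ConfigurationError("emergence_trigger_fraction must be in (0, 1)")

    def for_site(self, site: SiteClimate) -> "SimulationParams":
        """Swap in the soil preset referenced by the site, if known."""
        preset = SOIL_PRESETS.get(site.soil_profile_ref)
        if preset is None:
            return self
        return replace(self, soil=preset)


@dataclass(frozen=True)
class AnnualOutcome:
    """One simulated year: seedbank ratio λ and the season summary.

    ``death_cause`` is set when the plant was killed outright (frost or
    drought), whether before or during flowering.
    """

    lam: float
    season: SeasonResult
    seed_in: float
    seed_out: float
    death_cause: Optional[str] = None
    emerged: bool = False


@dataclass(frozen=True)
class SuitabilityScale:
    """Ordered cut points on Λ separating the six suitability classes."""

    cuts: tuple[float, float, float, float, float] = (-2.0, -1.0, -0.5, 0.0, 0.5)
    categories: tuple[str, ...] = ("U.0", "U.1", "C.0", "C.1", "E.0", "E.1")

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.cuts) + 1:
            raise ConfigurationError("need exactly one more category than cut points")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ConfigurationError("cut points must be strictly increasing")


DEFAULT_SCALE = SuitabilityScale()

#: Capped sentinel reported where baseline pollen is (near) zero but the
#: future scenario produces pollen — newly colonised sites.
POLLEN_CHANGE_SENTINEL = 0.85


@dataclass(frozen=True)
class SiteResult:
    """Ensemble summary for one site × scenario."""

    site_id: str
    scenario: str
    capital_lambda: float
    category: str
    mean_pollen: float
    mean_season_end_doy: Optional[float]
    n_replicates: int
    termination_reasons: dict[str, int] = field(default_factory=dict)
    death_causes: dict[str, int] = field(default_factory=dict)
    mean_maturation: float = 0.0


class _YearArrays:
    """Per-year weather unpacked to numpy arrays for the daily loop."""

    __slots__ = ("dates", "tmin", "tmean", "precip", "ref_et", "radiation",
                 "doy_oct1", "n")

    def __init__(self, df: pd.DataFrame):
        if len(df) == 0:
            raise InputError("empty weather year")
        self.dates = [ts.date() for ts in pd.DatetimeIndex(df["date"])]
        self.tmin = df["tmin"].to_numpy()
        self.tmean = df["tmean"].to_numpy()
        self.precip = df["precip"].to_numpy()
        self.ref_et = df["ref_et"].to_numpy()
        self.radiation = df["radiation"].to_numpy()
        self.n = len(self.dates)
        year = self.dates[0].year
        self.doy_oct1 = (dt.date(year, 10, 1) - dt.date(year, 1, 1)).days


def _prepare_year(weather_year) -> _YearArrays:
    if isinstance(weather_year, _YearArrays):
        return weather_year
    return _YearArrays(weather_year)


def simulate_year(weather_year, seedbank: SeedBankState, rng: np.random.Generator,
                  params: SimulationParams = SimulationParams(),
                  record_trace: bool = False
                  ) -> tuple[AnnualOutcome, SeedBankState] | tuple[AnnualOutcome, SeedBankState, pd.DataFrame]:
    """Simulate one annual cycle on one weather year.

    The replicate's seeds were shed the previous autumn, so dormancy
    release is first integrated over October–December of the same weather
    year (autumn spin-up) before the daily loop runs January–December.
    Two stochastic draws are consumed per call — the emergence fraction
    and the predation loss — in that order, regardless of outcome, so
    replicate streams stay aligned across scenarios.

    Returns the annual outcome (λ = seed_out/seed_in) and next seedbank;
    with ``record_trace=True`` also a daily trace DataFrame.
    """
    w = _prepare_year(weather_year)
    seed_in = seedbank.old_seed + seedbank.fresh_seed
    if seed_in <= 0:
        raise InputError("seedbank must hold seed (seed_in > 0)")

    emergence_frac = draw_emergence_fraction(rng, params.seed_fate)
    predation: PredationDraw = draw_predation_loss(rng, params.seed_fate)

    dorm = params.dormancy
    germ = params.germination
    phen = params.phenology
    gro = params.growth
    allo = params.allometry

    # Autumn spin-up: chilling accumulated Oct-Dec before the simulated year.
    dormancy_level = seedbank.dormancy_level
    for tm in w.tmean[w.doy_oct1:]:
        dormancy_level += dormancy_release_rate(tm, dorm)
    dormancy_level = clamp_dormancy_level(dormancy_level)

    theta = seedbank.theta_ht
    soil_state = SoilState(water=params.soil.pawc)  # winter-wet profile on Jan 1
    trigger_y = params.emergence_trigger_fraction * germ.M
    onset_month, onset_day = phen.flowering_onset
    onset_date = dt.date(w.dates[0].year, onset_month, onset_day)

    plant: Optional[PlantState] = None
    emerged = False
    transp_hist: list[float] = []
    flowering_tmin_hist: list[float] = []
    season_start: Optional[dt.date] = None
    season_end: Optional[dt.date] = None
    termination_reason: Optional[str] = None
    death_cause: Optional[str] = None
    final_biomass = 0.0
    final_tt_flowering = 0.0
    trace_rows: list[dict] = [] if record_trace else None

    for i in range(w.n):
        date = w.dates[i]
        tmean = w.tmean[i]
        tmin = w.tmin[i]

        if dormancy_level < 1.0:
            dormancy_level = clamp_dormancy_level(
                dormancy_level + dormancy_release_rate(tmean, dorm))

        cover = 1.0 - math.exp(-gro.k_ext * plant.lai) if plant is not None and plant.alive else 0.0
        soil_state, status = update_water_balance(
            soil_state, w.precip[i], w.ref_et[i], cover, params.soil)

        if dormancy_level >= 1.0:
            theta += hydrothermal_increment(tmean, status.psi, germ)
            if not emerged and plant is None and date < onset_date:
                y = cumulative_germination(theta, germ)
                if y >= trigger_y:
                    density = min(gro.density_cap,
                                  seed_in * (y / 100.0) * emergence_frac)
                    if density > 0:
                        plant = PlantState(stage="vegetative")
                        mass0 = gro.initial_seedling_mass * density
                        alloc = gro.allocation_table["vegetative"]
                        for organ in ORGANS:
                            plant.biomass[organ] = mass0 * alloc[organ]
                        plant.lai = plant.biomass["leaf"] * gro.sla
                        emerged = True

        if plant is not None and plant.alive:
            transp_hist.append(status.transp_ratio)
            cause = check_mortality(tmin, transp_hist, plant.stage, phen)
            if cause is not None:
                death_cause = cause
                if plant.stage == "flowering":
                    # death during flowering terminates the season with the
                    # biomass and maturation accrued so far
                    termination_reason = cause
                    season_end = date
                    final_biomass = plant.total_biomass
                    final_tt_flowering = plant.tt_since_flowering
                plant.stage = "dead"
                plant.death_cause = cause
            else:
                plant = daily_growth(plant, w.radiation[i], status.transp_ratio,
                                     tmean, gro, phen)
                if plant.stage == "vegetative" and check_flowering_onset(date, phen):
                    plant.stage = "flowering"
                    season_start = date
                    flowering_tmin_hist = []
                if plant.stage == "flowering":
                    flowering_tmin_hist.append(tmin)
                    reason = check_end_of_flowering(
                        flowering_tmin_hist, plant.tt_since_flowering,
                        transp_hist, phen)
                    if reason is not None:
                        termination_reason = reason
                        season_end = date
                        final_biomass = plant.total_biomass
                        final_tt_flowering = plant.tt_since_flowering
                        plant.stage = "terminated"
                        plant.termination_reason = reason

        if record_trace:
            died_today = (plant is not None and plant.stage == "dead"
                          and len([r for r in trace_rows if r["death_cause"]]) == 0)
            trace_rows.append({
                "date": date,
                "stage": plant.stage if plant is not None else "pre-emergent",
                "tt_since_flowering": plant.tt_since_flowering if plant is not None else 0.0,
                "total_biomass": plant.total_biomass if plant is not None else 0.0,
                "transp_ratio": status.transp_ratio,
                "psi": status.psi,
                "dormancy_level": dormancy_level,
                "theta_ht": theta,
                "termination_reason": termination_reason if season_end == date else None,
                "death_cause": death_cause if died_today else None,
            })

    # Season still open at year end (frost-free climates only).
    if plant is not None and plant.stage == "flowering":
        termination_reason = "year_end"
        season_end = w.dates[-1]
        final_biomass = plant.total_biomass
        final_tt_flowering = plant.tt_since_flowering
        plant.stage = "terminated"
        plant.termination_reason = termination_reason

    if season_start is not None and season_end is not None:
        frac = maturation_fraction(final_tt_flowering, phen.maturity_tt)
        pollen = pollen_production(final_biomass, allo)
        matured_seed = seed_production(final_biomass, frac, allo)
        season = SeasonResult(season_start=season_start, season_end=season_end,
                              termination_reason=termination_reason,
                              pollen=pollen, matured_seed=matured_seed,
                              maturation_fraction=frac)
    else:
        # never emerged, or died before flowering: exactly zero output
        season = SeasonResult(season_start=None, season_end=None,
                              termination_reason=None, pollen=0.0,
                              matured_seed=0.0, maturation_fraction=0.0)

    # Seedbank update: germinated seed leaves the bank (fatal germination for
    # the non-emerged share), the residual bank decays, and matured seed
    # returns after predation.
    y_final = cumulative_germination(theta, germ) if dormancy_level >= 1.0 else 0.0
    removed = seed_in * y_final / 100.0
    survival = seedbank_annual_survival(params.seed_fate.seedbank_half_life)
    seed_out = (seed_in - removed) * survival + season.matured_seed * (1.0 - predation.clamped)
    lam = seed_out / seed_in

    outcome = AnnualOutcome(lam=lam, season=season, seed_in=seed_in,
                            seed_out=seed_out, death_cause=death_cause,
                            emerged=emerged)
    new_bank = SeedBankState(old_seed=seed_out, fresh_seed=0.0,
                             dormancy_level=0.0, theta_ht=0.0)
    if record_trace:
        return outcome, new_bank, pd.DataFrame(trace_rows)
    return outcome, new_bank


def asymptotic_growth_rate(outcomes: Sequence[AnnualOutcome] | Sequence[float]) -> float:
    """Λ: arithmetic mean of the natural log of λ over the ensemble."""
    lams = [o.lam if isinstance(o, AnnualOutcome) else float(o) for o in outcomes]
    if not lams:
        raise InputError("need at least one outcome")
    if any(l <= 0 for l in lams):
        raise InputError("all lambda values must be > 0")
    return float(np.mean(np.log(lams)))


def classify_suitability(capital_lambda: float,
                         scale: SuitabilityScale = DEFAULT_SCALE) -> str:
    """Assign the six-class suitability category (lower-inclusive intervals)."""
    idx = int(np.searchsorted(np.asarray(scale.cuts), capital_lambda, side="right"))
    return scale.categories[idx]


def pollen_change(p_future: float, p_baseline: float,
                  baseline_floor: float = 1.0,
                  sentinel: float = POLLEN_CHANGE_SENTINEL) -> float:
    """log10 of the future/baseline seasonal pollen ratio.

    Newly colonised sites (baseline pollen at/below the floor but future
    pollen above it) are reported as the capped sentinel (> 0.8); if both
    are at the floor the change is undefined and NaN is returned.  Future
    pollen collapsing to zero is clamped at the floor.
    """
    if p_baseline < 0 or p_future < 0:
        raise InputError("pollen amounts must be >= 0")
    if p_baseline <= baseline_floor:
        return float("nan") if p_future <= baseline_floor else sentinel
    return math.log10(max(p_future, baseline_floor) / p_baseline)


def run_site(site: SiteClimate, scenario: Optional[ScenarioDelta] = None,
             n_sim: int = 1000, seed: int = 0,
             scale: SuitabilityScale = DEFAULT_SCALE,
             params: Optional[SimulationParams] = None,
             pool_years: int = 100, start_year: int = 2001,
             return_outcomes: bool = False):
    """Ensemble simulation of one site under one scenario.

    Generates a ``pool_years`` synthetic weather pool for the (perturbed)
    site, then runs ``n_sim`` independent one-year replicates, each on a
    weather year drawn uniformly from the pool with fresh emergence and
    predation draws, all starting from the standardised reference
    seedbank.  Aggregates Λ, the suitability category, mean seasonal
    pollen (zeros included) and the mean season-end day of year.

    The same ``seed`` yields bit-identical results, and runs differing
    only in the scenario are seed-paired through the weather generator.
    """
    if n_sim < 1:
        raise ConfigurationError("n_sim must be >= 1")
    scenario = scenario if scenario is not None else ScenarioDelta.baseline()
    params = (params if params is not None else SimulationParams()).for_site(site)
    perturbed = apply_scenario(site, scenario)

    ss = np.random.SeedSequence(int(seed))
    weather_ss, rep_ss = ss.spawn(2)
    pool_df = generate_weather(perturbed, pool_years, weather_ss, start_year=start_year)
    years = [_YearArrays(g) for _, g in pool_df.groupby(pool_df["date"].dt.year, sort=True)]

    rng = np.random.default_rng(rep_ss)
    year_idx = rng.integers(0, len(years), size=n_sim)

    outcomes: list[AnnualOutcome] = []
    for i in year_idx:
        bank = SeedBankState(old_seed=params.reference_seedbank)
        outcome, _ = simulate_year(years[i], bank, rng, params)
        outcomes.append(outcome)

    lam_mean = asymptotic_growth_rate(outcomes)
    category = classify_suitability(lam_mean, scale)
    mean_pollen = float(np.mean([o.season.pollen for o in outcomes]))
    end_doys = [o.season.season_end.timetuple().tm_yday
                for o in outcomes if o.season.season_end is not None]
    mean_end = float(np.mean(end_doys)) if end_doys else None
    reasons = Counter(o.season.termination_reason for o in outcomes
                      if o.season.termination_reason is not None)
    deaths = Counter(o.death_cause for o in outcomes if o.death_cause is not None)
    mean_mat = float(np.mean([o.season.maturation_fraction for o in outcomes]))

    result = SiteResult(site_id=site.site_id, scenario=scenario.label,
                        capital_lambda=lam_mean, category=category,
                        mean_pollen=mean_pollen, mean_season_end_doy=mean_end,
                        n_replicates=n_sim, termination_reasons=dict(reasons),
                        death_causes=dict(deaths), mean_maturation=mean_mat)
    if return_outcomes:
        return result, outcomes
    return result
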