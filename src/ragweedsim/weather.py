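"""Synthetic daily weather generation and climate-scenario perturbation.

Site climates are described by monthly statistics (mean daily minimum and
maximum temperature, wet-day probability and mean wet-day rainfall) plus a
latitude used for solar geometry.  From these the generator produces
seeded, reproducible daily series of tmin, tmax, tmean, precipitation,
shortwave radiation and reference evapotranspiration.

The generator structure is deliberately minimal:

* temperature: an AR(1) residual around the monthly-interpolated seasonal
  cycle, the same residual added to tmin and tmax so their ordering and
  the diurnal range are preserved;
* precipitation: a first-order two-state (wet/dry) Markov occurrence chain
  whose stationary wet fraction equals the configured monthly wet-day
  probability, with gamma-distributed wet-day amounts;
* radiation: a clear-sky seasonal curve from latitude, scaled by a fixed
  cloud factor on dry vs wet days;
* reference evapotranspiration: the Hargreaves temperature-and-radiation
  formula, clamped at zero.

Random streams are drawn in a fixed order that does not depend on the
parameter values, so two sites differing only by a scenario perturbation
and generated from the same seed are *seed-paired*: an additive +dT offset
shifts every daily temperature by exactly dT, and a rainfall multiplier
scales every wet-day amount exactly.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, UnsupportedLatitudeError

__all__ = [
    "SiteClimate",
    "ScenarioDelta",
    "generate_weather",
    "apply_scenario",
    "daylength",
    "reference_et",
    "extraterrestrial_radiation",
    "validate_weather",
    "WEATHER_COLUMNS",
]

WEATHER_COLUMNS = ("date", "tmin", "tmax", "tmean", "precip", "radiation", "ref_et")

#: Fraction of extraterrestrial radiation reaching the ground under a clear sky.
CLEAR_SKY_TRANSMITTANCE = 0.75
#: Fraction of clear-sky radiation on dry / wet days (fixed cloud factor).
DRY_DAY_FRACTION = 0.75
WET_DAY_FRACTION = 0.45

_MAX_LATITUDE = 66.0  # beyond this, polar day/night would need special casing


def _tuple12(name: str, values: Sequence[float], *, lo: float | None = None,
             hi: float | None = None) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    if len(vals) != 12:
        raise ConfigurationError(f"{name} must have 12 monthly entries, got {len(vals)}")
    for v in vals:
        if not math.isfinite(v):
            raise ConfigurationError(f"{name} contains a non-finite value")
        if lo is not None and v < lo:
            raise ConfigurationError(f"{name} entry {v} below minimum {lo}")
        if hi is not None and v > hi:
            raise ConfigurationError(f"{name} entry {v} above maximum {hi}")
    return vals


@dataclass(frozen=True)
class SiteClimate:
    """Monthly climate descriptors for one site.

    The twelve-element vectors are January..December.  ``wet_persistence``
    is the lag-1 correlation of the wet/dry occurrence chain (0 gives
    independent wet days); ``rain_shape`` the gamma shape of wet-day
    amounts.  ``soil_profile_ref`` keys into the soil parameter presets.
    """

    site_id: str
    latitude: float
    monthly_tmin_mean: tuple[float, ...]
    monthly_tmax_mean: tuple[float, ...]
    monthly_wet_day_prob: tuple[float, ...]
    monthly_wet_day_mean_rain: tuple[float, ...]
    temp_residual_sd: float = 2.0
    temp_residual_autocorr: float = 0.6
    wet_persistence: float = 0.3
    rain_shape: float = 0.8
    soil_profile_ref: str = "loam"
    longitude: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ConfigurationError(f"latitude {self.latitude} outside [-90, 90]")
        object.__setattr__(self, "monthly_tmin_mean",
                           _tuple12("monthly_tmin_mean", self.monthly_tmin_mean))
        object.__setattr__(self, "monthly_tmax_mean",
                           _tuple12("monthly_tmax_mean", self.monthly_tmax_mean))
        object.__setattr__(self, "monthly_wet_day_prob",
                           _tuple12("monthly_wet_day_prob", self.monthly_wet_day_prob,
                                    lo=0.0, hi=1.0))
        object.__setattr__(self, "monthly_wet_day_mean_rain",
                           _tuple12("monthly_wet_day_mean_rain",
                                    self.monthly_wet_day_mean_rain, lo=0.0))
        for lo, hi in zip(self.monthly_tmin_mean, self.monthly_tmax_mean):
            if hi < lo:
                raise ConfigurationError(
                    f"monthly tmax mean {hi} below tmin mean {lo} for site {self.site_id}")
        if self.temp_residual_sd < 0:
            raise ConfigurationError("temp_residual_sd must be >= 0")
        if not 0.0 <= self.temp_residual_autocorr < 1.0:
            raise ConfigurationError("temp_residual_autocorr must be in [0, 1)")
        if not 0.0 <= self.wet_persistence < 1.0:
            raise ConfigurationError("wet_persistence must be in [0, 1)")
        if self.rain_shape <= 0:
            raise ConfigurationError("rain_shape must be > 0")


@dataclass(frozen=True)
class ScenarioDelta:
    """Parametric climate-scenario perturbation.

    Monthly additive temperature offsets (°C) and multiplicative rainfall
    factors, standing in for downscaled GCM output.  The baseline scenario
    is all-zero offsets and all-one multipliers.
    """

    label: str = "baseline"
    temp_offset_monthly: tuple[float, ...] = (0.0,) * 12
    precip_multiplier_monthly: tuple[float, ...] = (1.0,) * 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "temp_offset_monthly",
                           _tuple12("temp_offset_monthly", self.temp_offset_monthly))
        object.__setattr__(self, "precip_multiplier_monthly",
                           _tuple12("precip_multiplier_monthly",
                                    self.precip_multiplier_monthly, lo=0.0))

    @classmethod
    def baseline(cls) -> "ScenarioDelta":
        return cls(label="baseline")

    @classmethod
    def uniform(cls, label: str, temp_offset: float = 0.0,
                precip_multiplier: float = 1.0) -> "ScenarioDelta":
        """Scenario with the same offset/multiplier in every month."""
        return cls(label=label,
                   temp_offset_monthly=(float(temp_offset),) * 12,
                   precip_multiplier_monthly=(float(precip_multiplier),) * 12)

    @property
    def is_baseline(self) -> bool:
        return (all(o == 0.0 for o in self.temp_offset_monthly)
                and all(m == 1.0 for m in self.precip_multiplier_monthly))


def apply_scenario(site: SiteClimate, delta: ScenarioDelta) -> SiteClimate:
    """Shift monthly temperature means additively and scale wet-day rain.

    All SiteClimate invariants are preserved (the same offset is applied to
    tmin and tmax in each month, so their ordering cannot flip).
    """
    tmin = tuple(t + o for t, o in zip(site.monthly_tmin_mean, delta.temp_offset_monthly))
    tmax = tuple(t + o for t, o in zip(site.monthly_tmax_mean, delta.temp_offset_monthly))
    rain = tuple(r * m for r, m in zip(site.monthly_wet_day_mean_rain,
                                       delta.precip_multiplier_monthly))
    return replace(site, monthly_tmin_mean=tmin, monthly_tmax_mean=tmax,
                   monthly_wet_day_mean_rain=rain)


# ---------------------------------------------------------------------------
# Solar geometry and reference evapotranspiration
# ---------------------------------------------------------------------------

def _solar_declination(day_of_year):
    return 0.409 * np.sin(2.0 * np.pi * np.asarray(day_of_year, dtype=float) / 365.0 - 1.39)


def daylength(latitude: float, day_of_year) -> float:
    """Astronomical day length in hours (no atmospheric refraction correction).

    Uses the standard solar-declination formula; at the equator this yields
    exactly 12 h year-round.  Latitudes beyond ±66° would require polar
    day/night handling and raise :class:`UnsupportedLatitudeError`.
    """
    if abs(latitude) > _MAX_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} beyond ±{_MAX_LATITUDE}° is not supported")
    decl = _solar_declination(day_of_year)
    phi = math.radians(latitude)
    x = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(x)
    return float(hours) if np.ndim(hours) == 0 else hours


def extraterrestrial_radiation(latitude: float, day_of_year):
    """Daily extraterrestrial shortwave radiation (MJ m⁻² d⁻¹), FAO-56 form."""
    if abs(latitude) > _MAX_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} beyond ±{_MAX_LATITUDE}° is not supported")
    doy = np.asarray(day_of_year, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = _solar_declination(doy)
    phi = math.radians(latitude)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws))
    ra = np.maximum(ra, 0.0)
    return float(ra) if np.ndim(ra) == 0 else ra


def reference_et(tmin, tmax, latitude: float, day_of_year):
    """Hargreaves reference evapotranspiration (mm d⁻¹), clamped at zero.

    ET0 = 0.0023 · (Ra/λ) · (Tmean + 17.8) · sqrt(Tmax − Tmin), with Ra the
    extraterrestrial radiation and λ = 2.45 MJ kg⁻¹ the latent heat of
    vaporisation.  Strictly increasing in tmax at fixed tmin (both through
    the mean temperature and the diurnal range).
    """
    tmin_a = np.asarray(tmin, dtype=float)
    tmax_a = np.asarray(tmax, dtype=float)
    if np.any(tmax_a < tmin_a):
        raise InputError("tmax must be >= tmin")
    ra = extraterrestrial_radiation(latitude, day_of_year)
    tmean = 0.5 * (tmin_a + tmax_a)
    et = 0.0023 * (ra / 2.45) * (tmean + 17.8) * np.sqrt(tmax_a - tmin_a)
    et = np.maximum(et, 0.0)
    return float(et) if np.ndim(et) == 0 else et


# ---------------------------------------------------------------------------
# Daily series generation
# ---------------------------------------------------------------------------

def _month_of_day(year: int) -> np.ndarray:
    """Month index (0-based) for each day of the calendar year."""
    lengths = [calendar.monthrange(year, m)[1] for m in range(1, 13)]
    return np.repeat(np.arange(12), lengths)


def _interp_anchors(anchors: np.ndarray, year: int) -> np.ndarray:
    """Periodic linear interpolation of mid-month anchor values to days."""
    lengths = np.array([calendar.monthrange(year, m)[1] for m in range(1, 13)], dtype=float)
    ndays = int(lengths.sum())
    mids = np.cumsum(lengths) - lengths / 2.0 + 0.5  # mid-month day-of-year
    xs = np.concatenate(([mids[-1] - ndays], mids, [mids[0] + ndays]))
    ys = np.concatenate(([anchors[-1]], anchors, [anchors[0]]))
    doy = np.arange(1, ndays + 1, dtype=float)
    return np.interp(doy, xs, ys)


_ANCHOR_SOLVER_CACHE: dict[bool, np.ndarray] = {}


def _anchor_solver(year: int) -> np.ndarray:
    """Inverse of the anchors → monthly-means map of the interpolation.

    Plain interpolation through mid-month values does not reproduce the
    monthly means (each month is pulled toward its neighbours), so anchor
    values are solved such that the monthly averages of the interpolated
    daily curve equal the configured means exactly.  The 12×12 map is
    linear and depends only on whether the year is leap.
    """
    leap = calendar.isleap(year)
    if leap not in _ANCHOR_SOLVER_CACHE:
        month = _month_of_day(year)
        m = np.zeros((12, 12))
        for j in range(12):
            basis = np.zeros(12)
            basis[j] = 1.0
            daily = _interp_anchors(basis, year)
            for k in range(12):
                m[k, j] = daily[month == k].mean()
        _ANCHOR_SOLVER_CACHE[leap] = np.linalg.inv(m)
    return _ANCHOR_SOLVER_CACHE[leap]


def _seasonal_cycle(monthly: Sequence[float], year: int) -> np.ndarray:
    """Daily seasonal cycle whose monthly means equal ``monthly`` exactly."""
    anchors = _anchor_solver(year) @ np.asarray(monthly, dtype=float)
    return _interp_anchors(anchors, year)


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def generate_weather(site: SiteClimate, n_years: int, seed,
                     start_year: int = 2001) -> pd.DataFrame:
    """Generate ``n_years`` of contiguous daily weather for a site.

    Returns a DataFrame with columns ``date, tmin, tmax, tmean, precip,
    radiation, ref_et`` (Gregorian calendar with leap years).  Identical
    ``(site, n_years, seed, start_year)`` yield bit-identical output.

    ``seed`` may be an integer master seed or a ``numpy.random.SeedSequence``;
    per-year streams are derived from it deterministically.
    """
    if n_years < 1:
        raise ConfigurationError("n_years must be >= 1")
    ss = _as_seed_sequence(seed)
    year_seeds = ss.spawn(n_years)

    sd = site.temp_residual_sd
    rho = site.temp_residual_autocorr
    innov = sd * math.sqrt(max(0.0, 1.0 - rho * rho))
    shape = site.rain_shape
    r = site.wet_persistence
    p_wet = np.asarray(site.monthly_wet_day_prob)
    scale_wet = np.asarray(site.monthly_wet_day_mean_rain) / shape

    frames = []
    for k, year in enumerate(range(start_year, start_year + n_years)):
        t_ss, p_ss = year_seeds[k].spawn(2)
        month = _month_of_day(year)
        ndays = month.size
        doy = np.arange(1, ndays + 1)

        cyc_tmin = _seasonal_cycle(site.monthly_tmin_mean, year)
        # safety clamp: mean-preserving anchors could in principle cross for
        # wildly varying diurnal ranges; smooth climates never trigger it
        cyc_tmax = np.maximum(_seasonal_cycle(site.monthly_tmax_mean, year), cyc_tmin)

        rng_t = np.random.default_rng(t_ss)
        z = rng_t.standard_normal(ndays)
        resid = np.empty(ndays)
        e = sd * z[0]
        resid[0] = e
        for i in range(1, ndays):
            e = rho * e + innov * z[i]
            resid[i] = e

        tmin = cyc_tmin + resid
        tmax = cyc_tmax + resid
        tmean = 0.5 * (tmin + tmax)

        # Occurrence and amount streams are drawn for every day regardless of
        # the wet/dry outcome, keeping scenario runs seed-paired.
        rng_p = np.random.default_rng(p_ss)
        u0 = rng_p.random()
        u = rng_p.random(ndays)
        g = rng_p.standard_gamma(shape, ndays)

        p_day = p_wet[month]
        wet = np.empty(ndays, dtype=bool)
        prev_wet = u0 < p_day[0]
        for i in range(ndays):
            p = p_day[i]
            p_cond = p + r * (1.0 - p) if prev_wet else p * (1.0 - r)
            prev_wet = u[i] < p_cond
            wet[i] = prev_wet
        precip = np.where(wet, g * scale_wet[month], 0.0)

        clear_sky = CLEAR_SKY_TRANSMITTANCE * extraterrestrial_radiation(site.latitude, doy)
        radiation = np.where(wet, WET_DAY_FRACTION, DRY_DAY_FRACTION) * clear_sky
        ref_et_v = reference_et(tmin, tmax, site.latitude, doy)

        frames.append(pd.DataFrame({
            "date": pd.date_range(f"{year}-01-01", periods=ndays, freq="D"),
            "tmin": tmin, "tmax": tmax, "tmean": tmean,
            "precip": precip, "radiation": radiation, "ref_et": ref_et_v,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out


def validate_weather(df: pd.DataFrame) -> None:
    """Raise :class:`InputError` if a weather series violates its invariants."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"weather series missing columns: {missing}")
    if len(df) == 0:
        raise InputError("weather series is empty")
    if not (df["tmin"] <= df["tmean"]).all() or not (df["tmean"] <= df["tmax"]).all():
        raise InputError("tmin <= tmean <= tmax violated")
    for col in ("precip", "radiation", "ref_et"):
        if (df[col] < 0).any():
            raise InputError(f"negative values in {col}")
    deltas = pd.Series(df["date"]).diff().dropna()
    if not (deltas == pd.Timedelta(days=1)).all():
        raise InputError("dates are not contiguous daily")
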