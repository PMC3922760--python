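"""Seed dormancy release, hydrothermal-time germination, and seed fates.

Common ragweed is a summer annual whose fresh seed is shed dormant and
needs a period of winter chilling before it can germinate.  Dormancy
release is modelled as a temperature-dependent daily rate integrating to 1
(fully released), with its optimum at 4 °C where 12 weeks of exposure are
required.  Once dormancy is broken, cumulative germination follows a
Weibull curve on hydrothermal time — the accumulated product of
supra-base temperature (base 3.6 °C) and supra-base soil water potential
(base −0.8 MPa).

Seed fates around germination are stochastic: the fraction of the
germinable pool that emerges is drawn from a skewed distribution with
median 26%, fresh-seed predation losses from a normal distribution
(mean 0.9, sd 0.1, clamped to [0, 1] downstream), and the old seedbank
decays exponentially with a 17-year half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DormancyParams",
    "GerminationParams",
    "SeedBankState",
    "SeedFateParams",
    "PredationDraw",
    "dormancy_release_rate",
    "update_dormancy",
    "hydrothermal_increment",
    "cumulative_germination",
    "draw_emergence_fraction",
    "draw_predation_loss",
    "seedbank_annual_survival",
]


@dataclass(frozen=True)
class DormancyParams:
    """Triangular temperature response of the daily dormancy-release rate.

    The rate peaks at ``t_opt`` where full release takes
    ``release_weeks_at_opt`` weeks, and falls linearly to zero at the two
    zero-rate bounds (chilling is ineffective both in deep frost and in
    warmth).
    """

    t_opt: float = 4.0
    release_weeks_at_opt: float = 12.0
    lower_zero_rate_temp: float = -5.0
    upper_zero_rate_temp: float = 20.0

    def __post_init__(self) -> None:
        if not self.lower_zero_rate_temp < self.t_opt < self.upper_zero_rate_temp:
            raise ConfigurationError("require lower bound < t_opt < upper bound")
        if self.release_weeks_at_opt <= 0:
            raise ConfigurationError("release_weeks_at_opt must be > 0")

    @property
    def peak_rate(self) -> float:
        """Daily release rate at the optimum: 1 / (7 × weeks)."""
        return 1.0 / (7.0 * self.release_weeks_at_opt)


@dataclass(frozen=True)
class GerminationParams:
    """Weibull cumulative-germination curve on hydrothermal time.

    Y(θ) = M · (1 − exp(−k·(θ−a)^c)) for θ > a, else 0, with M the maximum
    germination (%), k the rate of increase, a the lag phase (hydrothermal
    units) and c the shape.  θ accumulates as (T − t_base)(ψ − psi_base)
    per day when both factors are positive.
    """

    M: float = 95.0
    k: float = 0.002
    a: float = 120.0
    c: float = 2.0
    t_base: float = 3.6
    psi_base: float = -0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.M <= 100.0:
            raise ConfigurationError("M must be in (0, 100]")
        if self.k <= 0 or self.c <= 0 or self.a < 0:
            raise ConfigurationError("require k > 0, c > 0, a >= 0")


@dataclass
class SeedBankState:
    """Densities and germination bookkeeping for one site-year.

    ``dormancy_level`` integrates the daily release rate (1 = fully
    released); ``theta_ht`` is the accumulated hydrothermal time of the
    released cohort.
    """

    old_seed: float = 0.0
    fresh_seed: float = 0.0
    dormancy_level: float = 0.0
    theta_ht: float = 0.0

    def __post_init__(self) -> None:
        if self.old_seed < 0 or self.fresh_seed < 0 or self.theta_ht < 0:
            raise ConfigurationError("seedbank fields must be >= 0")
        if not 0.0 <= self.dormancy_level <= 1.0:
            raise ConfigurationError("dormancy_level must be in [0, 1]")


@dataclass(frozen=True)
class SeedFateParams:
    """Stochastic seed-fate parameters.

    Emergence is logit-normal with location logit(``emergence_median``) —
    so its median is exact by construction — and spread on the logit
    scale.  Predation is normal (raw draws exposed; clamping to [0, 1]
    happens in the annual pipeline).  The old bank decays with the given
    half-life.
    """

    emergence_median: float = 0.26
    emergence_spread: float = 0.75
    predation_mean: float = 0.9
    predation_sd: float = 0.1
    seedbank_half_life: float = 17.0

    def __post_init__(self) -> None:
        if not 0.0 < self.emergence_median < 1.0:
            raise ConfigurationError("emergence_median must be in (0, 1)")
        if self.emergence_spread < 0:
            raise ConfigurationError("emergence_spread must be >= 0")
        if self.predation_sd <= 0:
            raise ConfigurationError("predation_sd must be > 0")
        if self.seedbank_half_life <= 0:
            raise ConfigurationError("seedbank_half_life must be > 0")


def dormancy_release_rate(t: float, params: DormancyParams = DormancyParams()) -> float:
    """Daily dormancy-release rate (d⁻¹) at temperature ``t``.

    Triangular: zero at/beyond the zero-rate bounds, rising linearly to
    the peak rate 1/(7·weeks) at the optimum.
    """
    if t <= params.lower_zero_rate_temp or t >= params.upper_zero_rate_temp:
        return 0.0
    peak = params.peak_rate
    if t <= params.t_opt:
        return peak * (t - params.lower_zero_rate_temp) / (params.t_opt - params.lower_zero_rate_temp)
    return peak * (params.upper_zero_rate_temp - t) / (params.upper_zero_rate_temp - params.t_opt)


#: Absorbs float round-off when daily rates integrate to exactly 1 (e.g. 84
#: additions of 1/84); anything within this of full release counts as released.
RELEASE_TOLERANCE = 1e-9


def clamp_dormancy_level(level: float) -> float:
    """Clamp an integrated dormancy level to [0, 1] with release tolerance."""
    if level >= 1.0 - RELEASE_TOLERANCE:
        return 1.0
    return max(0.0, level)


def update_dormancy(state: SeedBankState, daily_tmean: float,
                    params: DormancyParams = DormancyParams()) -> SeedBankState:
    """Advance the dormancy level by one day of exposure at ``daily_tmean``."""
    level = clamp_dormancy_level(
        state.dormancy_level + dormancy_release_rate(daily_tmean, params))
    return SeedBankState(old_seed=state.old_seed, fresh_seed=state.fresh_seed,
                         dormancy_level=level, theta_ht=state.theta_ht)


def hydrothermal_increment(tmean: float, psi: float,
                           params: GerminationParams = GerminationParams()) -> float:
    """Daily hydrothermal-time increment (MPa·°C·d).

    The product (T − t_base)(ψ − psi_base) when both factors are positive,
    else zero: θ does not accumulate below the base temperature or below
    the base water potential.
    """
    dt = tmean - params.t_base
    dp = psi - params.psi_base
    if dt <= 0.0 or dp <= 0.0:
        return 0.0
    return dt * dp


def cumulative_germination(theta_ht: float,
                           params: GerminationParams = GerminationParams()) -> float:
    """Cumulative germination Y (%) at hydrothermal time ``theta_ht``."""
    if theta_ht < 0:
        raise ConfigurationError("theta_ht must be >= 0")
    if theta_ht <= params.a:
        return 0.0
    return params.M * (1.0 - math.exp(-params.k * (theta_ht - params.a) ** params.c))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def draw_emergence_fraction(rng: np.random.Generator,
                            params: SeedFateParams = SeedFateParams()) -> float:
    """Draw the fraction of the germinable pool that emerges this year.

    Logit-normal with median exactly ``emergence_median`` for any spread;
    support strictly inside (0, 1); degenerate at the median when the
    spread is zero.
    """
    x = _logit(params.emergence_median) + params.emergence_spread * rng.standard_normal()
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class PredationDraw:
    """Raw normal predation draw and its [0, 1]-clamped value.

    The raw value is exposed because clamping shifts the moments; the
    annual pipeline applies the clamped value.
    """

    raw: float
    clamped: float


def draw_predation_loss(rng: np.random.Generator,
                        params: SeedFateParams = SeedFateParams()) -> PredationDraw:
    """Draw the fresh-seed predation loss fraction."""
    raw = params.predation_mean + params.predation_sd * rng.standard_normal()
    return PredationDraw(raw=raw, clamped=min(1.0, max(0.0, raw)))


def seedbank_annual_survival(half_life: float) -> float:
    """Annual survival of the old seedbank: 2^(−1/half_life).

    Applying it ``half_life`` times halves the bank exactly.
    """
    if half_life <= 0:
        raise ConfigurationError("half_life must be > 0")
    return 2.0 ** (-1.0 / half_life)
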