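"""Single-layer soil water bucket.

Supplies two quantities to the biology: the soil water potential ψ (MPa)
consumed by hydrothermal-time germination, and the actual-to-potential
transpiration ratio that drives the drought senescence and mortality
rules.  One bucket with overflow drainage is sufficient to express the two
thresholds the biology needs (the base water potential for germination and
the 0.1 transpiration-ratio drought rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, InputError

__all__ = [
    "SoilParams",
    "SoilState",
    "WaterStatus",
    "soil_water_potential",
    "transpiration_supply_factor",
    "update_water_balance",
    "SOIL_PRESETS",
]


@dataclass(frozen=True)
class SoilParams:
    """Bucket parameters.

    pawc
        plant-available water capacity of the rooted profile, mm.
    psi_fc, psi_wilt
        water potential at field capacity (full bucket) and wilting point
        (empty bucket), MPa; both negative.
    evap_fraction
        bare-soil evaporation as a share of reference ET, applied to the
        canopy-free fraction of the ground.
    critical_fill
        relative content above which transpiration is unrestricted; supply
        declines linearly to zero below it.
    """

    pawc: float = 100.0
    psi_fc: float = -0.01
    psi_wilt: float = -1.5
    evap_fraction: float = 0.3
    critical_fill: float = 0.5

    def __post_init__(self) -> None:
        if self.pawc <= 0:
            raise ConfigurationError("pawc must be > 0")
        if not (self.psi_wilt < self.psi_fc < 0):
            raise ConfigurationError("require psi_wilt < psi_fc < 0")
        if not 0.0 <= self.evap_fraction <= 1.0:
            raise ConfigurationError("evap_fraction must be in [0, 1]")
        if not 0.0 < self.critical_fill <= 1.0:
            raise ConfigurationError("critical_fill must be in (0, 1]")


@dataclass
class SoilState:
    """Plant-available water currently stored, mm in [0, pawc]."""

    water: float


@dataclass(frozen=True)
class WaterStatus:
    """Daily water diagnostics.

    ``transp_ratio`` is actual/potential transpiration, defined as 1 when
    there is no demand.  ``evaporation``, ``transpiration`` and
    ``drainage`` close the bucket's daily water budget exactly.
    """

    psi: float
    transp_ratio: float
    evaporation: float = 0.0
    transpiration: float = 0.0
    drainage: float = 0.0


def soil_water_potential(relative_content: float, params: SoilParams = SoilParams()) -> float:
    """Map relative bucket fill (0..1) to soil water potential (MPa).

    Log-linear in the magnitude of ψ between the wilting point (empty) and
    field capacity (full); monotone increasing in content.
    """
    if not 0.0 <= relative_content <= 1.0:
        raise InputError(f"relative content {relative_content} outside [0, 1]")
    log_lo = math.log10(-params.psi_wilt)
    log_hi = math.log10(-params.psi_fc)
    return -10.0 ** (log_lo + relative_content * (log_hi - log_lo))


def transpiration_supply_factor(relative_content: float, critical_fill: float = 0.5) -> float:
    """Soil supply limitation on transpiration: 1 above the critical fill,
    declining linearly to 0 at an empty bucket."""
    if not 0.0 <= relative_content <= 1.0:
        raise InputError(f"relative content {relative_content} outside [0, 1]")
    if relative_content >= critical_fill:
        return 1.0
    return relative_content / critical_fill


def update_water_balance(state: SoilState, precip: float, ref_et: float,
                         cover: float, params: SoilParams = SoilParams()
                         ) -> tuple[SoilState, WaterStatus]:
    """Advance the bucket by one day.

    Rain is added first (excess above capacity drains), then bare-soil
    evaporation from the canopy-free fraction and canopy transpiration
    (potential = cover × ref_et) are withdrawn, both limited by the same
    supply factor.  The returned status closes the budget exactly:
    ``water' − water = precip − drainage − evaporation − transpiration``.
    """
    if precip < 0 or ref_et < 0:
        raise InputError("precip and ref_et must be >= 0")
    if not 0.0 <= cover <= 1.0:
        raise InputError("cover must be in [0, 1]")

    w = state.water + precip
    drainage = max(0.0, w - params.pawc)
    w -= drainage
    rel = w / params.pawc
    supply = transpiration_supply_factor(rel, params.critical_fill)

    pot_transp = cover * ref_et
    transp = pot_transp * supply
    evap = params.evap_fraction * (1.0 - cover) * ref_et * supply
    total = transp + evap
    if total > w:  # cannot extract more than is stored
        scale = w / total if total > 0 else 0.0
        transp *= scale
        evap *= scale
    w -= transp + evap

    ratio = transp / pot_transp if pot_transp > 0 else 1.0
    psi = soil_water_potential(min(1.0, max(0.0, w / params.pawc)), params)
    return SoilState(water=w), WaterStatus(psi=psi, transp_ratio=ratio,
                                           evaporation=evap, transpiration=transp,
                                           drainage=drainage)


#: Soil presets keyed by ``SiteClimate.soil_profile_ref``.
SOIL_PRESETS: dict[str, SoilParams] = {
    "loam": SoilParams(pawc=100.0),
    "deep_loam": SoilParams(pawc=150.0),
    "shallow_soil": SoilParams(pawc=80.0),
}
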