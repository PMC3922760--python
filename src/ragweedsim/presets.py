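"""Archetype site climates spanning the species' European niche limits.

Three presets built once from climate normals:

``temperate_favourable``
    Po valley / southern France analogue — the core of the species'
    established European range: mild winters for chilling, warm moist
    summers, long frost-free autumns.
``mediterranean_dry``
    interior southern Iberia analogue — beyond the dry southern limit:
    ample warmth but near-rainless summers on a shallow soil.
``boreal_cold``
    northern Fennoscandia analogue — beyond the cold northern limit:
    chilling completes only in early summer, the season is short and the
    first autumn frosts arrive long before seed can mature.

Monthly vectors are January..December; temperatures °C, rain mm per wet
day.
"""

from __future__ import annotations

from .weather import SiteClimate

__all__ = ["SITE_PRESETS", "get_preset"]


SITE_PRESETS: dict[str, SiteClimate] = {
    "temperate_favourable": SiteClimate(
        site_id="temperate_favourable",
        latitude=45.0,
        longitude=8.0,
        monthly_tmin_mean=(-2.0, -1.0, 2.0, 5.0, 10.0, 14.0, 16.0, 16.0, 12.0, 7.0, 2.0, -1.0),
        monthly_tmax_mean=(6.0, 8.0, 13.0, 17.0, 22.0, 27.0, 30.0, 29.0, 24.0, 17.0, 10.0, 6.0),
        monthly_wet_day_prob=(0.35, 0.33, 0.35, 0.38, 0.38, 0.32, 0.30, 0.30, 0.32, 0.36, 0.38, 0.36),
        monthly_wet_day_mean_rain=(6.0, 6.0, 7.0, 8.0, 9.0, 10.0, 9.0, 10.0, 9.0, 9.0, 8.0, 7.0),
        temp_residual_sd=2.0,
        temp_residual_autocorr=0.6,
        soil_profile_ref="deep_loam",
    ),
    "mediterranean_dry": SiteClimate(
        site_id="mediterranean_dry",
        latitude=38.0,
        longitude=-4.0,
        monthly_tmin_mean=(3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 19.0, 19.0, 16.0, 11.0, 7.0, 5.0),
        monthly_tmax_mean=(12.0, 14.0, 17.0, 20.0, 25.0, 31.0, 35.0, 34.0, 29.0, 22.0, 16.0, 13.0),
        monthly_wet_day_prob=(0.25, 0.24, 0.22, 0.22, 0.15, 0.07, 0.02, 0.03, 0.10, 0.20, 0.25, 0.26),
        monthly_wet_day_mean_rain=(7.0, 7.0, 6.0, 7.0, 6.0, 5.0, 4.0, 4.0, 6.0, 8.0, 8.0, 7.0),
        temp_residual_sd=2.2,
        temp_residual_autocorr=0.6,
        soil_profile_ref="shallow_soil",
    ),
    "boreal_cold": SiteClimate(
        site_id="boreal_cold",
        latitude=65.0,
        longitude=26.0,
        monthly_tmin_mean=(-18.0, -16.0, -11.0, -5.0, 0.0, 5.0, 8.0, 7.0, 2.0, -3.0, -10.0, -15.0),
        monthly_tmax_mean=(-10.0, -8.0, -3.0, 3.0, 9.0, 14.0, 17.0, 15.0, 9.0, 2.0, -4.0, -11.0),
        monthly_wet_day_prob=(0.40, 0.38, 0.35, 0.33, 0.33, 0.36, 0.38, 0.40, 0.42, 0.42, 0.42, 0.40),
        monthly_wet_day_mean_rain=(3.0, 3.0, 3.0, 4.0, 4.0, 5.0, 6.0, 6.0, 5.0, 5.0, 4.0, 3.0),
        temp_residual_sd=2.0,
        temp_residual_autocorr=0.6,
        soil_profile_ref="loam",
    ),
}


def get_preset(name: str) -> SiteClimate:
    """Return an archetype site climate by name."""
    try:
        return SITE_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown site preset {name!r}; "
                       f"available: {sorted(SITE_PRESETS)}") from None
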