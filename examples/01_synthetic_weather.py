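"""Generate synthetic daily weather for an archetype site and check its
statistics against the configured climate.

The generator is the stand-in for a stochastic weather generator trained
on station data: monthly climate normals in, reproducible daily series
out.
"""

import numpy as np

import ragweedsim as r

site = r.get_preset("temperate_favourable")
weather = r.generate_weather(site, n_years=30, seed=42)

july = weather[weather["date"].dt.month == 7]
configured_july = 0.5 * (site.monthly_tmin_mean[6] + site.monthly_tmax_mean[6])

print(f"{len(weather)} days generated for {site.site_id!r} (lat {site.latitude}°N)")
print(f"July mean temperature: {july['tmean'].mean():.2f} °C "
      f"(configured {configured_july:.2f} °C)")
print(f"July wet-day frequency: {(july['precip'] > 0).mean():.3f} "
      f"(configured {site.monthly_wet_day_prob[6]:.3f})")
print(f"Annual precipitation:  {weather['precip'].sum() / 30:.0f} mm/yr")
print(f"Midsummer reference ET: {weather['ref_et'].max():.1f} mm/d at most")
# The sample statistics should sit close to the configured normals; the
# residual differences are sampling noise that shrinks with more years.
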