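"""One annual life cycle, day by day.

Runs a single simulated year at the favourable archetype with the daily
trace enabled, then prints the key phenological dates and the seed/pollen
budget that turns into the year's population growth rate λ.
"""

import numpy as np

import ragweedsim as r

site = r.get_preset("temperate_favourable")
weather = r.generate_weather(site, n_years=1, seed=3)
params = r.SimulationParams().for_site(site)
bank = r.SeedBankState(old_seed=params.reference_seedbank)

outcome, next_bank, trace = r.simulate_year(weather, bank, np.random.default_rng(0),
                                            params, record_trace=True)

emerged = trace[trace["stage"] == "vegetative"]
print(f"emergence date:    {emerged['date'].iloc[0] if len(emerged) else 'never'}")
print(f"flowering starts:  {outcome.season.season_start}")
print(f"season ends:       {outcome.season.season_end} "
      f"({outcome.season.termination_reason})")
print(f"final biomass:     {trace['total_biomass'].max():.0f} g/m2")
print(f"maturation:        {outcome.season.maturation_fraction:.2f} "
      f"of the thermal-time requirement")
print(f"seasonal pollen:   {outcome.season.pollen:.3g} grains/m2")
print(f"matured seed:      {outcome.season.matured_seed:.0f} seeds/m2")
print(f"seedbank: {outcome.seed_in:.0f} -> {outcome.seed_out:.0f} seeds/m2, "
      f"lambda = {outcome.lam:.2f}")
# lambda > 1 means the seedbank grew over the year: germinated seed left the
# bank, the residual bank decayed (17-year half-life), and new seed returned
# after ~90% predation.
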