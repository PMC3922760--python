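"""Climate-scenario response: suitability shift and relative pollen change.

Applies a uniform +2 °C warming (seed-paired with the baseline, so the
weather noise is identical and only the climate signal differs) to the
cold-margin and favourable archetypes, and reports the change in Λ and
the log10 pollen ratio log10(Pfuture/Pbaseline).
"""

import ragweedsim as r

scenario = r.ScenarioDelta.uniform("plus2C", temp_offset=2.0)

for name in ("boreal_cold", "temperate_favourable"):
    site = r.get_preset(name)
    base = r.run_site(site, n_sim=300, seed=42)
    warm = r.run_site(site, scenario, n_sim=300, seed=42)
    change = r.pollen_change(warm.mean_pollen, base.mean_pollen)
    print(f"{name:22s} Lambda {base.capital_lambda:7.3f} ({base.category}) "
          f"-> {warm.capital_lambda:7.3f} ({warm.category})   "
          f"log10 pollen change = {change:+.2f}")
print()
print("warming lifts the cold margin far more than the favourable core: "
      "the largest relative pollen increases appear at the northern edge "
      "of the range, where populations were thermally limited.")
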