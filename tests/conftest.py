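import numpy as np
import pytest

import ragweedsim as r


def make_constant_site(tmin=5.0, tmax=15.0, wet_prob=0.0, rain=0.0,
                       sd=0.0, latitude=45.0, **kwargs) -> r.SiteClimate:
    """Site with the same climate every month (degenerate test climates)."""
    return r.SiteClimate(
        site_id=kwargs.pop("site_id", "constant"),
        latitude=latitude,
        monthly_tmin_mean=(tmin,) * 12,
        monthly_tmax_mean=(tmax,) * 12,
        monthly_wet_day_prob=(wet_prob,) * 12,
        monthly_wet_day_mean_rain=(rain,) * 12,
        temp_residual_sd=sd,
        **kwargs,
    )


@pytest.fixture(scope="session")
def constant_site_factory():
    return make_constant_site


@pytest.fixture(scope="session")
def temperate():
    return r.get_preset("temperate_favourable")


@pytest.fixture(scope="session")
def mediterranean():
    return r.get_preset("mediterranean_dry")


@pytest.fixture(scope="session")
def boreal():
    return r.get_preset("boreal_cold")


@pytest.fixture(scope="session")
def archetype_runs():
    """One 200-replicate ensemble per archetype, shared across tests."""
    runs = {}
    for name in ("temperate_favourable", "mediterranean_dry", "boreal_cold"):
        result, outcomes = r.run_site(r.get_preset(name), n_sim=200, seed=7,
                                      return_outcomes=True)
        runs[name] = (result, outcomes)
    return runs
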