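import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from socsim.forcing import ClimateNormals
from socsim.registry import default_registry
from socsim.rothc import SoilProfile
from socsim.synthetic import UHTURecord, day_length_hours

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_uhtu(
    uhtu_id="u001",
    zone="temperate",
    t_annual=10.0,
    t_amp=10.0,
    precip_monthly=70.0,
    clay=25.0,
    soc0=60.0,
    relative_sd=0.10,
    latitude=45.0,
    feasible=None,
):
    """Hand-built territorial unit with a seasonal cosine climate."""
    months = np.arange(12)
    temp = t_annual + t_amp * np.cos(2 * np.pi * (months - 6) / 12.0)
    precip = np.full(12, float(precip_monthly))
    climate = ClimateNormals(
        temp_mean=temp,
        temp_sd=relative_sd * np.abs(temp),
        precip_mean=precip,
        precip_sd=relative_sd * precip,
        day_length=day_length_hours(latitude),
    )
    return UHTURecord(
        uhtu_id=uhtu_id,
        thermal_zone=zone,
        latitude_band=latitude,
        climate=climate,
        soil=SoilProfile(clay=clay, soc0=soc0),
        clay_sd=relative_sd * clay,
        soc0_sd=relative_sd * soc0,
        feasible_classes=set(feasible) if feasible else set(),
    )


@pytest.fixture
def temperate_uhtu(registry):
    return make_uhtu(feasible=registry.keys())


@pytest.fixture
def dry_subtropical_uhtu(registry):
    # Hot with scarce rainfall: strong irrigation demand.
    return make_uhtu(
        uhtu_id="u_dry",
        zone="subtropical",
        t_annual=19.0,
        t_amp=6.0,
        precip_monthly=25.0,
        latitude=30.0,
        feasible=registry.keys(),
    )
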