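import pytest
from hypothesis import HealthCheck, settings

from hgintake.constants import CONC_MG_PER_KG
from hgintake.simulate import generate_meal_schedule

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def intervention_schedule():
    """The 10-consumption-day / 2-week fried-fish meal plan."""
    return generate_meal_schedule()


@pytest.fixture(scope="session")
def conc_lookup():
    """Reference mean tissue Hg per (species, state), mg/kg wet weight."""
    return dict(CONC_MG_PER_KG)
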