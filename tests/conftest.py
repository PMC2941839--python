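import pytest

from steromet.reference import build_reference
from steromet.registry import load_registry
from steromet.simulator import scenario_preset, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def normal_cohort(registry):
    """200 simulated normal profiles, fixed seed."""
    return simulate_cohort(scenario_preset("normal"), 200, seed=11, registry=registry)


@pytest.fixture(scope="session")
def reference_set(registry, normal_cohort):
    return build_reference(normal_cohort, registry)
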