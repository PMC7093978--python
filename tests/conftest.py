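import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pamkit as pk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_run():
    """A small stringent-preset depletion run shared across tests."""
    profile = pk.make_rate_profile("stringent", k_max=0.5, seed=1)
    config = pk.SimulationConfig(
        profile=profile, reads_per_sample=5000, seed=1, error_rate=0.002
    )
    return pk.simulate_depletion_run(config)


@pytest.fixture(scope="session")
def clean_run():
    """Error-free, full-quality run: read counting must be exact."""
    profile = pk.make_rate_profile("stringent", k_max=0.5, seed=2)
    config = pk.SimulationConfig(
        profile=profile,
        reads_per_sample=4000,
        seed=2,
        error_rate=0.0,
        low_quality_pam_fraction=0.0,
    )
    return pk.simulate_depletion_run(config)


@pytest.fixture(scope="session")
def amplicon_reference():
    rng = np.random.default_rng(42)
    ref = "".join(rng.choice(list("ACGT"), size=200))
    protospacer = ref[80:103]
    return ref, protospacer
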