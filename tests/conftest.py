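import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ctratio as cr

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return cr.MarkerPanel()


@pytest.fixture(scope="session")
def small_panel():
    """Six-marker panel (3 targets, 3 references) for fast end-to-end runs."""
    return cr.MarkerPanel(targets=("miR-150", "miR-221", "miR-24"),
                          references=cr.DEFAULT_REFERENCES)


@pytest.fixture(scope="session")
def cohort(panel):
    """Default synthetic cohort with the standard planted effects."""
    return cr.generate_cohort(seed=11).validate(panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
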