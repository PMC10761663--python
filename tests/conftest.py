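import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petkin.aif import FENG_POPULATION_MEAN, multi_injection_aif
from petkin.protocol import standard_protocol

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    """Canonical (schedule, injections, windows) triple."""
    return standard_protocol()


@pytest.fixture(scope="session")
def mean_triple_aif(protocol):
    """Continuous triple-injection input at the population-mean shape."""
    _, injections, _ = protocol

    def aif(t):
        return multi_injection_aif(FENG_POPULATION_MEAN, injections, t)

    return aif


@pytest.fixture(scope="session")
def short_window_frames(protocol):
    """Frames of the 36-39 + 48-60 min fitting windows."""
    from petkin.protocol import select_window

    schedule, _, windows = protocol
    idx = np.sort(
        np.concatenate(
            [
                select_window(schedule, windows["brain_late"]),
                select_window(schedule, windows["brain_early"]),
            ]
        )
    )
    return schedule.subset(idx)
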