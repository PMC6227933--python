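import numpy as np
import pytest
from hypothesis import HealthCheck, settings as h_settings

from isoshift import McmcSettings, MixingProblem
from isoshift.data import (
    DiscriminationFactor,
    IsotopeSample,
    SourceDistribution,
    group_from_samples,
)

h_settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
h_settings.load_profile("suite")


NO_DTDF = DiscriminationFactor("none", (0.0, 0.0), (0.0, 0.0))


@pytest.fixture(scope="session")
def fast_settings() -> McmcSettings:
    """Cheap chain honoring the >=100-retained-draw rule."""
    return McmcSettings(iterations=12_000, burn_in=2_000, thin=100, seed=0)


@pytest.fixture(scope="session")
def mid_settings() -> McmcSettings:
    """Moderate chain for posterior-location assertions."""
    return McmcSettings(iterations=40_000, burn_in=15_000, thin=25, seed=1)


def make_group(xy, species="consumer", period="P", dtdf=NO_DTDF):
    samples = [IsotopeSample(species, period, float(x), float(y)) for x, y in xy]
    return group_from_samples(samples, dtdf)


@pytest.fixture()
def toy_triangle_problem() -> MixingProblem:
    """Three well-separated sources around a consumer cloud at the centroid."""
    rng = np.random.default_rng(7)
    xy = rng.normal([-19.0, 14.0], [0.15, 0.15], size=(30, 2))
    sources = (
        SourceDistribution("a", (-21.0, 12.0), (0.3, 0.3), 10),
        SourceDistribution("b", (-17.0, 12.0), (0.3, 0.3), 10),
        SourceDistribution("c", (-19.0, 18.0), (0.3, 0.3), 10),
    )
    return MixingProblem(make_group(xy), sources, NO_DTDF)
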