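import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def plain_phantom():
    """A rectangular artifact-free phantom and its ground truth."""
    from buscurate.synthetic_fixtures import build_class_spec, render_phantom

    return render_phantom(build_class_spec("plain", 0, 7))


@pytest.fixture(scope="session")
def caliper_phantom():
    from buscurate.synthetic_fixtures import build_class_spec, render_phantom

    return render_phantom(build_class_spec("calipers", 0, 7))
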