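import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_params():
    from neuritesim import TransportParameters

    return TransportParameters()


@pytest.fixture
def y_spec():
    from neuritesim import YTreeSpec

    return YTreeSpec(d_a=50e-6, d_b=10e-6)


@pytest.fixture
def y_tree(y_spec):
    from neuritesim import build_y_tree

    return build_y_tree(y_spec)
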