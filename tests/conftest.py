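import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from tlstracts.datasets import geometry_registry

    return geometry_registry()


@pytest.fixture(scope="session")
def thf():
    from tlstracts.datasets import load_thf_bypass

    return load_thf_bypass()


@pytest.fixture(scope="session")
def thf_ctrl():
    from tlstracts.datasets import load_thf_control

    return load_thf_control()


@pytest.fixture(scope="session")
def uv():
    from tlstracts.datasets import load_uv_revertants

    return load_uv_revertants()


@pytest.fixture(scope="session")
def uv_canr():
    from tlstracts.datasets import load_uv_canr

    return load_uv_canr()
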