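import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog_features():
    """Features of every published terminator, computed once per session."""
    from haloterm import catalog, extract_features

    return {name: extract_features(catalog.get(name)) for name in catalog.SEQUENCES}
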