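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

from chemobda import (  # noqa: E402
    SynthConfig,
    build_fig_fixture,
    build_toy_bundle,
    materialize,
)


@pytest.fixture(scope="session")
def fig_bundle():
    return build_fig_fixture()


@pytest.fixture(scope="session")
def fig_world(fig_bundle):
    """(bundle, mapping set, database, materialized store) for the
    journal/document worked example."""
    ms = fig_bundle.mapping_set()
    db = fig_bundle.make_database()
    store = materialize(ms, db)
    return fig_bundle, ms, db, store


@pytest.fixture(scope="session")
def toy_bundle():
    return build_toy_bundle(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def toy_world(toy_bundle):
    ms = toy_bundle.mapping_set()
    db = toy_bundle.make_database()
    store = materialize(ms, db)
    return toy_bundle, ms, db, store
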