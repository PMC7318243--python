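import pytest

from covhop.fixtures import fixture_libraries, generate_fixtures


@pytest.fixture(scope="session")
def tiny_libraries():
    return fixture_libraries("tiny")


@pytest.fixture(scope="session")
def small_libraries():
    return fixture_libraries("small")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One shared seeded fixture set for the whole session."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = generate_fixtures(out, seed=2020, scale="tiny")
    return out, manifest


@pytest.fixture(scope="session")
def enumerated_products(tiny_libraries):
    from covhop.enumeration import enumerate_library

    stream, manifest = enumerate_library(tiny_libraries)
    products = list(stream)
    return products, manifest
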