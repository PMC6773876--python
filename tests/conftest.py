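import pytest

from pinora import (
    CalibrationTable,
    FixtureSpec,
    build_zscore_map,
    filter_significant,
    generate_all,
    map_to_pin,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def fixture_data(spec):
    """(pin, deg, gene_sets, expression) for the default synthetic study."""
    return generate_all(spec)


@pytest.fixture(scope="session")
def pin(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def deg(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def gene_sets(fixture_data):
    return fixture_data[2]


@pytest.fixture(scope="session")
def expression(fixture_data):
    return fixture_data[3]


@pytest.fixture(scope="session")
def processed(pin, deg):
    return map_to_pin(filter_significant(deg), pin)


@pytest.fixture(scope="session")
def zmap(processed):
    return build_zscore_map(processed.p_values)


@pytest.fixture(scope="session")
def calib(pin, zmap):
    return CalibrationTable(pin=pin, zmap=zmap, seed=1)
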