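import pytest

from aunphsab import GoldSurface, calibrate, load_fixture


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def plane():
    return GoldSurface()


@pytest.fixture(scope="session")
def two_point_cal(table1, table2):
    """Two-reference calibration on methanethiol + fully ionized citrate."""
    refs = [
        (table1["methanethiol"], table2["methanethiol"].dE_r_obs),
        (table1["citrate(COO−)3"], table2["citrate(COO−)3"].dE_r_obs),
    ]
    return calibrate(refs, r_ref=table2.r_ref)


@pytest.fixture(scope="session")
def np_surface(two_point_cal):
    """Calibrated nanoparticle surface at the reference radius."""
    return two_point_cal.surface()
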