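import pytest

import feedenergy as fe


@pytest.fixture(scope="session")
def table1():
    return {i.ingredient_id: i for i in fe.load_fixture("table1")}


@pytest.fixture(scope="session")
def table2():
    return {f.diet_id: f for f in fe.load_fixture("table2")}


@pytest.fixture(scope="session")
def table3():
    return {f.diet_id: f for f in fe.load_fixture("table3")}


@pytest.fixture(scope="session")
def table4():
    return fe.load_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return fe.load_fixture("table5")


@pytest.fixture(scope="session")
def table6():
    return fe.load_fixture("table6")


@pytest.fixture(scope="session")
def table7():
    return fe.load_fixture("table7")


@pytest.fixture(scope="session")
def de_calibration(table5):
    return fe.fit_calibration(list(zip(table5["ivde"], table5["de"])), response="DE")


@pytest.fixture(scope="session")
def me_calibration(table5):
    return fe.fit_calibration(list(zip(table5["ivde"], table5["me"])), response="ME")


@pytest.fixture(scope="session")
def fixture_report():
    """Full fixture-pipeline report, computed once for the session."""
    return fe.run_fixture_pipeline()
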