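import pytest

from kdrmon.io import load_association_fixture, load_trend_fixture
from kdrmon.simulate import make_reference


@pytest.fixture(scope="session")
def reference():
    return make_reference(seed=0)


@pytest.fixture(scope="session")
def trend_tables():
    return load_trend_fixture()


@pytest.fixture(scope="session")
def association_tables():
    return load_association_fixture()


def find_table(tables, location, group, year=None, insecticide=None):
    hits = [
        t
        for t in tables
        if t.location == location
        and t.group == group
        and (year is None or t.year == year)
        and (insecticide is None or t.insecticide == insecticide)
    ]
    assert len(hits) == 1, f"{location}/{group}/{year}/{insecticide}: {len(hits)} hits"
    return hits[0]
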