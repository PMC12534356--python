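import pytest

import pemriver as pr


@pytest.fixture(scope="session")
def fixture_raw() -> pr.SampleSet:
    return pr.builtin_fixture()


@pytest.fixture(scope="session")
def fixture_half_dl(fixture_raw) -> pr.SampleSet:
    return pr.resolve_censored(fixture_raw, "half_dl")


@pytest.fixture(scope="session")
def main_stem(fixture_half_dl) -> pr.SampleSet:
    return pr.subset(fixture_half_dl, {"main_stem"})


@pytest.fixture(scope="session")
def non_lake(fixture_half_dl) -> pr.SampleSet:
    return pr.subset(fixture_half_dl, {"main_stem", "tributary", "mine_drainage"})


@pytest.fixture(scope="session")
def background(fixture_half_dl) -> "pr.BackgroundProfile":
    return pr.derive_background(fixture_half_dl, ("NY-01", "NY-13"), "half_dl")
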