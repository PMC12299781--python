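import pytest

from stsonify.mapping import MappingConfig
from stsonify.synthetic_ecg import CONDITIONS, make_st_profile


@pytest.fixture(scope="session")
def study_config() -> MappingConfig:
    """The evaluated five-state study configuration (all defaults)."""
    return MappingConfig()


@pytest.fixture(scope="session", params=CONDITIONS)
def condition(request) -> str:
    return request.param


@pytest.fixture(scope="session")
def all_profiles():
    return {cond: make_st_profile(cond) for cond in CONDITIONS}
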