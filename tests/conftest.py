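import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def db():
    from sulfotherm import default_database
    return default_database()


@pytest.fixture(scope="session")
def library():
    from sulfotherm import load_reaction_library
    return load_reaction_library()


@pytest.fixture(scope="session")
def rxn1(library):
    return library["comproportionation"]


@pytest.fixture(scope="session")
def medium():
    from sulfotherm import comproportionation_medium
    return comproportionation_medium()


@pytest.fixture(scope="session")
def medium_solution(medium):
    from sulfotherm import speciate
    return speciate(medium.composition)
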