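import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from crewmet import CrewMember, ExercisePrescription, GRID_STATURES


@pytest.fixture(scope="session")
def five_members():
    """The five reference statures, fully derived."""
    return tuple(CrewMember(stature=s) for s in GRID_STATURES)


@pytest.fixture(scope="session")
def prescription():
    """ISS-like countermeasure prescription (defaults)."""
    return ExercisePrescription()
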