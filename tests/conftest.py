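import pytest
from hypothesis import HealthCheck, settings

import aromatype as at
from aromatype import gcims_fingerprint as ims
from aromatype import synthetic_data as synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library() -> at.GcmsLibrary:
    """The packaged 74-compound GC-MS table."""
    return at.load_packaged_library()


@pytest.fixture(scope="session")
def ims_records() -> list:
    """The packaged 55-signal GC-IMS peak table."""
    return ims.load_ims_table()


@pytest.fixture()
def design() -> synth.StudyDesign:
    return synth.StudyDesign(seed=0)


@pytest.fixture(scope="session")
def archetypes() -> synth.SensoryArchetypes:
    return synth.default_archetypes()
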