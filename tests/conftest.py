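import pytest

from misoqba import derive_frame, reference_cohort


@pytest.fixture(scope="session")
def ref_cohort():
    """The 637-record margin-matched reference cohort."""
    return reference_cohort()


@pytest.fixture(scope="session")
def ref_frame(ref_cohort):
    return derive_frame(ref_cohort)
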