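import pytest

import gestmix as gm


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort with nested case-control sampling."""
    truth = gm.default_truth(seed=42)
    subjects, visits = gm.simulate_cohort(truth)
    return truth, subjects, visits


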