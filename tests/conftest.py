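import pytest

from barcodepop import synthetic_data


@pytest.fixture(scope="session")
def toy():
    return synthetic_data.worked_toy()


@pytest.fixture(scope="session")
def study_aln():
    """One study-like synthetic dataset shared across tests."""
    aln, truth = synthetic_data.generate_study_like(seed=42)
    return aln, truth
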