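import numpy as np
import pytest

from prnascreen import PRNAScaffold, sample_prna


@pytest.fixture(scope="session")
def prna_instance():
    """One validated scaffold realization shared across tests."""
    return sample_prna(PRNAScaffold(), seed=11, name="fixture_prna")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
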