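import pytest

from hooftrim import reference_parameters, run_psa


@pytest.fixture(scope="session")
def reference():
    return reference_parameters()


@pytest.fixture(scope="session")
def reference_psa(reference):
    """One full 2000-iteration probabilistic run, shared across tests."""
    return run_psa(reference, 2000, seed=1)
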