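import pytest

from hifucea import builtin_basecase, run_psa


@pytest.fixture()
def base():
    return builtin_basecase()


@pytest.fixture(scope="session")
def psa_small():
    """Small PSA sample table shared by PSA/VOI unit tests."""
    return run_psa(builtin_basecase(), n_iter=400, seed=11)
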