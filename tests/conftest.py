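import numpy as np
import pytest

from lungcv import PhantomSpec, split_inner_outer

from simutil import run_phantom_subject


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def healthy_run(default_spec):
    """One healthy default-phantom realization shared across tests."""
    res = run_phantom_subject(default_spec)
    res["inner"], res["outer"] = split_inner_outer(res["mask"])
    return res


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
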