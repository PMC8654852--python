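import numpy as np
import pytest

from privrep import ModelParams, Strategy, canonical_set


@pytest.fixture(scope="session")
def no_error_params() -> ModelParams:
    return ModelParams(b=3.0, c=1.0, mu_e=0.0, mu_a=0.0, h0=0.5)


@pytest.fixture(scope="session")
def canon() -> list[Strategy]:
    return canonical_set()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def pytest_addoption(parser):
    parser.addoption(
        "--fast-acceptance",
        action="store_true",
        default=False,
        help="shrink the heavyweight acceptance computations (dev only)",
    )
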