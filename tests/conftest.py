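import numpy as np
import pytest

from rsmval import QuadraticModel, ResponseSurfaceResults
from rsmval.datasets import reference_design, reference_error_ss, reference_surface


@pytest.fixture(scope="session")
def ref_model() -> QuadraticModel:
    """Published count surface: Y = 41.80 - 0.50A - 1.50B - 2.75C - 0.50AB
    + 1.00AC + 0.00BC - 7.90A^2 - 8.40B^2 - 2.90C^2."""
    return reference_surface()


@pytest.fixture(scope="session")
def ref_design():
    return reference_design()


@pytest.fixture(scope="session")
def ref_aggregates() -> tuple[float, float]:
    """(residual SS, pure-error SS) = (11.3, 2.8) on 7 and 4 df."""
    return reference_error_ss()


@pytest.fixture(scope="session")
def ref_results(ref_model, ref_design, ref_aggregates) -> ResponseSurfaceResults:
    res_ss, pe_ss = ref_aggregates
    return ResponseSurfaceResults.from_aggregates(
        ref_model, ref_design, residual_ss=res_ss, pure_error_ss=pe_ss
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
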