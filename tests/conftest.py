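import numpy as np
import pytest

from poppkpd.model_core import (
    DoseEvent,
    default_pd_parameters,
    default_pk_parameters,
)
from poppkpd.synthetic import (
    StudyDesign,
    default_pd_error,
    default_pk_error,
    default_random_effects,
    default_study_design,
)


@pytest.fixture(scope="session")
def pk_ref():
    return default_pk_parameters()


@pytest.fixture(scope="session")
def pd_ref():
    return default_pd_parameters()


@pytest.fixture(scope="session")
def design_ref():
    return default_study_design()


@pytest.fixture(scope="session")
def iiv_ref():
    return default_random_effects()


@pytest.fixture(scope="session")
def pk_error_ref():
    return default_pk_error()


@pytest.fixture(scope="session")
def pd_error_ref():
    return default_pd_error()


@pytest.fixture(scope="session")
def small_design():
    """Two tiny dose groups on thinned grids — fast fits in tests."""
    return StudyDesign(
        groups=((9.0, 3), (36.0, 3)),
        pk_times=(0.0, 1.5, 6, 12, 24, 36, 48, 72, 96, 120, 144, 168, 192),
        pd_times=(0.0, 8, 24, 48, 96, 144, 192, 264),
    )


@pytest.fixture
def dose18():
    return DoseEvent(amount=18.0, time=0.0)
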