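import pytest

from metsdx.criteria import builtin_criteria
from metsdx.simulate import CohortSpec, generate


@pytest.fixture(scope="session")
def registry():
    return builtin_criteria()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 400-record default-condition cohort shared across tests."""
    return generate(CohortSpec(n=400, seed=2024))


@pytest.fixture()
def record_kwargs():
    """A fully classifiable, everywhere-negative baseline record."""
    return dict(
        id="r1",
        sex="female",
        age_years=30.0,
        waist_cm=70.0,
        bmi=22.0,
        sbp_mmHg=110.0,
        dbp_mmHg=70.0,
        glucose_mgdl=85.0,
        tg_mgdl=100.0,
        hdl_mgdl=60.0,
    )
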