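import numpy as np
import pytest

from bgfc.cohort import CohortSpec, calibrate_pipeline, generate_cohort

# small pilot sizes keep the imaging fixtures fast; the full-size pilots are
# exercised by the parameter-recovery tests in test_acceptance.py
TINY_PILOT = {"calibration_pilot": {"n_round1": 24, "n_round2": 32}}


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec.default(
        n_hc=4,
        n_ms=4,
        seed=11,
        rt_outliers={"HC": 0, "MS": 0},
        overrides=TINY_PILOT,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """4+4 subjects with imaging, shared across tests (read-only)."""
    return generate_cohort(small_spec, seed=11)


@pytest.fixture(scope="session")
def one_subject(small_cohort):
    return small_cohort[0]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
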