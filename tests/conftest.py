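import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# fixed base seed for all stochastic recovery/coverage tests
BASE_SEED = 20130822


@pytest.fixture(scope="session")
def base_seed():
    return BASE_SEED


@pytest.fixture()
def rng():
    return np.random.default_rng(BASE_SEED)


@pytest.fixture(scope="session")
def small_cohort():
    from csfpool import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(n_site_a=440, n_site_b=260, seed=BASE_SEED))


def expand_counts_to_cohort(a, b, c, d, carrier, start=0):
    """Subject-level rows reproducing a 2x2 (APOE-e4 x deposition) table.

    Platform A (cutoff 500 pg/mL); deposition rows get Abeta42 400, others 600.
    """
    rows = []
    combos = [(True, True, a), (True, False, b), (False, True, c), (False, False, d)]
    i = start
    for e4, dep, count in combos:
        for _ in range(count):
            rows.append(
                {
                    "subject_id": f"F{i:05d}",
                    "site": "A",
                    "apoe4_dose": 1 if e4 else 0,
                    "abeta42_raw": 400.0 if dep else 600.0,
                    "PSEN1_E318G": 1 if carrier else 0,
                }
            )
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def deposition_fixture_cohort():
    """Cohort whose carrier/non-carrier strata reproduce the bundled
    deposition count tables exactly."""
    carrier = expand_counts_to_cohort(15, 1, 9, 11, carrier=True)
    non = expand_counts_to_cohort(299, 105, 201, 322, carrier=False, start=100)
    return pd.concat([carrier, non], ignore_index=True)
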