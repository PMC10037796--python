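import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gendermech as gm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return gm.default_params(seed=11)


@pytest.fixture(scope="session")
def cohort(params):
    """Complete (no missingness) synthetic cohort, moderate size."""
    return gm.generate_cohort(params, n=4000, seed=11)


@pytest.fixture(scope="session")
def cohort_t(cohort):
    """Cohort with log-outcome columns added."""
    return gm.transform_outcomes(cohort)


@pytest.fixture(scope="session")
def truth(params):
    return gm.compute_truth(params, mc_n=200_000, mc_seed=11)


@pytest.fixture(scope="session")
def masked_cohort(cohort, params):
    return gm.inject_missingness(cohort, params, seed=11)


def toy_cell_table(cell_means: dict, reps: int = 3) -> pd.DataFrame:
    """Tiny complete table whose (S, E) cell means of ``y`` are exact.

    ``cell_means`` maps (s, e) -> mean; each cell gets ``reps`` rows with a
    mean-zero perturbation so the cell mean equals the requested value.
    """
    rows = []
    offsets = np.arange(reps) - (reps - 1) / 2.0  # sums to zero
    i = 0
    for (s, e), mu in cell_means.items():
        for off in offsets:
            rows.append({"id": i, "sex": s, "deprived": e, "y": mu + 0.1 * off})
            i += 1
    return pd.DataFrame(rows)
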