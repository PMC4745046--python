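import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tsdbn.cgbn_core import SPARSE_PRIORS, fit_parameters
from tsdbn.data_io import CohortTable, build_transition_table
from tsdbn.structure_search import hill_climb
from tsdbn.synthetic_data import CohortSpec, default_ground_truth, simulate_cohort


def toy_cohort_frame(n_subjects=2, days=(3, 5, 7), taxa=("Taxa", "Taxb")):
    rows = []
    rng = np.random.default_rng(7)
    for s in range(n_subjects):
        for d in days:
            row = {
                "subject_id": f"S{s + 1}",
                "day_of_life": d,
                "gestational_age_at_birth": 28.0,
                "postconceptional_age": 28.0 + d / 7,
                "antibiotics": 0.1,
                "open_room": "open",
            }
            for t in taxa:
                row[t] = int(rng.integers(1, 100))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_cohort():
    return CohortTable(toy_cohort_frame(), taxa=["Taxa", "Taxb"])


@pytest.fixture(scope="session")
def default_cohort():
    truth = default_ground_truth()
    cohort, archive = simulate_cohort(truth, CohortSpec(seed=11))
    return truth, cohort, archive


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Structure learned and parameters fit on the default synthetic cohort."""
    _, cohort, _ = default_cohort
    table = build_transition_table(cohort)
    structure, trajectory = hill_climb(table, SPARSE_PRIORS)
    fitted = fit_parameters(structure, table, SPARSE_PRIORS)
    return table, structure, trajectory, fitted
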