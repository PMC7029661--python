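import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hyperfc import CohortConfig, simulate_cohort
from hyperfc.hypernetwork import Hypergraph


@pytest.fixture
def toy_hypergraph() -> Hypergraph:
    """V = {0,1,2,3}, E = {e0={0,1,2}, e1={0,1}, e2={2,3}}."""
    inc = np.array(
        [
            [1, 1, 0],
            [1, 1, 0],
            [1, 0, 1],
            [0, 0, 1],
        ],
        dtype=np.uint8,
    )
    return Hypergraph(n_nodes=4, incidence=inc)


@pytest.fixture(scope="session")
def small_cohort():
    """12 ROIs in 3 blocks, one block decorrelated in cohort B."""
    cfg = CohortConfig(
        n_rois=12,
        n_timepoints=80,
        n_subjects_a=8,
        n_subjects_b=8,
        group_sizes=(4, 4, 4),
        within_r=0.7,
        between_r=0.05,
        perturbed_blocks={0},
        perturbed_within_r=0.1,
        seed=11,
    )
    return cfg, simulate_cohort(cfg)


def random_problem(rng, T=10, M=5):
    """Random standardized regression problem with centroid column zeroed."""
    from hyperfc import RegressionProblem

    data = rng.standard_normal((M, T))
    # induce some correlation so supports are non-trivial
    data[1] = 0.7 * data[0] + 0.3 * data[1]
    return RegressionProblem.from_timeseries(data, centroid_index=0)
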