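import numpy as np
import pytest

from genspm.cohort import CohortDesign, simulate_cohort, to_records
from genspm.config import reference_params
from genspm.model import OptimalTrajectory, TrajectoryPair


@pytest.fixture(scope="session")
def chf_params():
    """Reference cholesterol/female parameter set (natural scale)."""
    return reference_params("CH", "F")


@pytest.fixture(scope="session")
def chf_noncarrier(chf_params):
    return chf_params.noncarrier


@pytest.fixture(scope="session")
def small_mixed_cohort(chf_params):
    """20-subject mixed cohort with known, unknown and censored records."""
    design = CohortDesign(
        n_individuals=20,
        entry_age_range=(40, 50),
        max_age=100,
        genotyping_age=70,
        genotyped_fraction=0.8,
        exam_gap_prob=0.15,
        sex="F",
        seed=20260901,
    )
    individuals = simulate_cohort(design, chf_params)
    return to_records(individuals)


@pytest.fixture(scope="session")
def chf_trajectory_pair(chf_params):
    return TrajectoryPair.from_params(chf_params)
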