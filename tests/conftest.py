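import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gutapns.io import PathwayAbundanceTable
from gutapns.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort (51 subjects, 200 species, seed 0)."""
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast unit tests of the model plumbing."""
    cfg = SimulationConfig(n_subjects=25, n_species=30, n_effectors=2,
                           gamma=(2.0, 0.5), seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_pathway_table():
    """Four samples, one pathway, three taxa with hand-checkable strata."""
    data = {
        "PWY-T: toy pathway": [10.0, 8.0, 4.0, 10.0],
        "PWY-T: toy pathway|g__A.s__A_sp1": [6.0, 2.0, 1.0, 0.0],
        "PWY-T: toy pathway|g__B.s__B_sp1": [4.0, 2.0, 0.0, 5.0],
        "PWY-T: toy pathway|g__C.s__C_sp1": [0.0, 4.0, 3.0, 5.0],
        "UNMAPPED": [1.0, 1.0, 1.0, 1.0],
    }
    idx = pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")
    return PathwayAbundanceTable(pd.DataFrame(data, index=idx))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
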