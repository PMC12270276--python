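import numpy as np
import pandas as pd
import pytest

from gutbrainlink.metabolome_qc import MetabolitePanel
from gutbrainlink.synth_cohort import CohortConfig, MediationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def default_cfg():
    """Paper-scale cohort with all defaults."""
    return CohortConfig(seed=11)


@pytest.fixture
def small_cfg():
    """Down-scaled cohort for fast unit tests."""
    return CohortConfig(
        n_patients=40,
        n_controls=35,
        n_metabolites=40,
        planted_pos_idx=tuple(range(4)),
        planted_neg_idx=tuple(range(4, 8)),
        mediation_specs=[
            MediationSpec(0, 0, 1, a=0.5, b=0.4, c_prime=0.1),
            MediationSpec(4, 1, 4, a=-0.5, b=0.4, c_prime=0.0),
        ],
        fail_blank_idx=(34, 35),
        fail_rsd_idx=(36, 37),
        fail_presence_idx=(38, 39),
        seed=7,
    )


def make_panel(sample, qc, blank, ids=None, ion_mode="positive"):
    """Build a MetabolitePanel from raw arrays."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    qc = np.atleast_2d(np.asarray(qc, dtype=float))
    blank = np.atleast_2d(np.asarray(blank, dtype=float))
    if ids is None:
        ids = [f"met{j:04d}" for j in range(sample.shape[1])]
    return MetabolitePanel(
        sample_areas=pd.DataFrame(sample, columns=ids),
        qc_areas=pd.DataFrame(qc, columns=ids),
        blank_areas=pd.DataFrame(blank, columns=ids),
        ion_mode=ion_mode,
    )


@pytest.fixture
def panel_factory():
    return make_panel
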