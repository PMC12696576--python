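import numpy as np
import pytest
from hypothesis import settings

import rcads_ml as r
from rcads_ml.core import frame_from_arrays

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bank():
    return r.default_bank()


@pytest.fixture(scope="session")
def study_cfg():
    """Default generator config mirroring the emulated clinic sample."""
    return r.GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def complete_cfg():
    """A complete 89-record cohort config (no missingness)."""
    return r.GeneratorConfig(n=89, seed=5, missing_sex=0, missing_grade=0, missing_both=0)


@pytest.fixture(scope="session")
def complete_cohort(complete_cfg, bank):
    cohort, truth = r.generate_cohort(complete_cfg, bank)
    return cohort, truth


@pytest.fixture(scope="session")
def norms(complete_cfg, bank):
    return r.build_norms(complete_cfg, reference_n=5000, bank=bank)


def make_cohort(items, sex=None, grade=None, provenance="real"):
    """Build a small Cohort from an items array (complete demographics)."""
    items = np.asarray(items, dtype=float)
    n = len(items)
    if sex is None:
        sex = np.array(["boy", "girl"] * n, dtype=object)[:n]
    if grade is None:
        grade = np.full(n, 7.0)
    return r.Cohort(frame_from_arrays(np.asarray(sex, dtype=object), grade, items),
                    provenance=provenance)
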