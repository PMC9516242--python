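import numpy as np
import pytest

from atherocytof import synthetic


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-sample desk cohort shared by read-only tests."""
    design = synthetic.default_design(
        n_per_group={"NC": 2, "CAS": 2, "ASCVD": 2},
        cells_per_sample=400,
        seed=11,
    )
    return design, synthetic.generate_cohort(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
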