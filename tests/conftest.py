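import numpy as np
import pytest

from genedaly.shrinkage import ShrinkagePrior
from genedaly.synthetic_data import (
    CohortConfig,
    EffectMatrix,
    ExposureSpec,
    generate_cohort,
    hazard_for_incidence,
)


@pytest.fixture(scope="session")
def prior():
    return ShrinkagePrior()


@pytest.fixture(scope="session")
def recovery_cohort():
    """50k-individual cohort with one allele exposure of true log HR 0.30."""
    effects = EffectMatrix(
        np.array([[0.3]]), np.array([[False]]), np.array([1.0])
    )
    cfg = CohortConfig(
        n_individuals=50_000,
        exposures=[ExposureSpec("e0", "allele_dosage", 0.3)],
        n_diseases=1,
        baseline_hazard=hazard_for_incidence(0.10, 80.0),
        seed=42,
    )
    return generate_cohort(cfg, effects), effects
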