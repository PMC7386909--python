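import numpy as np
import pytest

from nkdetect.cohort import Cohort
from nkdetect.synthetic import GeneratorConfig, generate_detection_cohort, reference_spec


@pytest.fixture(scope="session")
def spec():
    return reference_spec()


@pytest.fixture(scope="session")
def detection_cohort(spec):
    """Default-shape synthetic detection cohort (30 benign + 41 cancer)."""
    return generate_detection_cohort(spec, GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort(spec):
    """Cohort with the two groups drawn from identical distributions."""
    return generate_detection_cohort(spec, GeneratorConfig(seed=7, effect_scale=0.0))


@pytest.fixture()
def toy_cohort():
    """Tiny hand-built 6-patient cohort (3 benign, 3 cancer)."""
    rng = np.random.default_rng(5)
    values = rng.uniform(10, 90, size=(6, 32))
    return Cohort(
        values=values,
        psa=np.array([5.0, 6.5, 8.0, 7.0, 9.5, 12.0]),
        labels=np.array([0, 0, 0, 1, 1, 1]),
        patient_ids=[f"P{i}" for i in range(6)],
    )
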