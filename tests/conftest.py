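import numpy as np
import pandas as pd
import pytest

from pathage import Cohort, CohortSpec, generate_cohort


@pytest.fixture()
def tiny_cohort() -> Cohort:
    """Six subjects, two classes, two hand-written features."""
    return Cohort(
        subject_id=np.array([f"S{i}" for i in range(6)], dtype=object),
        age=np.array([70.0, 72.0, 75.0, 68.0, 80.0, 77.0]),
        class_label=np.array([0, 0, 0, 1, 1, 1]),
        class_names=("NC", "AD"),
        features=pd.DataFrame({
            "left": [3300.0, 3280.0, 3250.0, 3180.0, 3100.0, 3150.0],
            "right": [3310.0, 3275.0, 3260.0, 3190.0, 3120.0, 3140.0],
        }),
    )


@pytest.fixture(scope="session")
def small_two_class() -> Cohort:
    """60-subject, low-noise, two-class synthetic cohort (fast searches)."""
    spec = CohortSpec(
        n_per_class=30,
        class_names=("NC", "AD"),
        class_age_means=(76.0, 75.5),
        class_age_sds=(4.7, 7.2),
        class_accel=(0.0, 8.0),
        feature_noise_sd=2.0,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def adni_like() -> Cohort:
    """Reduced-size cohort with the default generator structure (90/class)."""
    spec = CohortSpec(n_per_class=90, seed=11)
    return generate_cohort(spec)
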