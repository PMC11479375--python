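import numpy as np
import pytest

from mear.io import AccelRecording
from mear.simulate import CohortConfig, draw_subject, generate_bout, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 1 walk per speed: cheap but structurally complete."""
    config = CohortConfig(
        n_subjects=4,
        walks_per_speed={"slow": 1, "preferred": 1, "fast": 1},
        seed=7,
    )
    bouts, manifest = generate_cohort(config)
    return config, bouts, manifest


@pytest.fixture(scope="session")
def one_bout():
    config = CohortConfig(n_subjects=2, seed=3)
    subject = draw_subject(config, 0)
    rng = np.random.default_rng(11)
    return generate_bout(subject, "preferred", rng)


@pytest.fixture
def random_recording():
    rng = np.random.default_rng(42)
    return AccelRecording(
        subject_id="S42",
        ear_side="right",
        samples=rng.normal(0.0, 0.5, size=(1000, 3)),
        t0=0.25,
    )
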