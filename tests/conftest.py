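import numpy as np
import pytest

from pacemetrics.pacing_metrics import cohort_variables
from pacemetrics.race_model import RaceCourse, RaceRecord
from pacemetrics.synthetic_data import SyntheticConfig, generate_cohort

#: 3-lap toy course of 1 m laps; times [1/4, 1/5, 1/6] s give speeds [4, 5, 6].
TOY_COURSE = RaceCourse(total_distance=3.0, n_laps=3)

MARATHON = RaceCourse()


@pytest.fixture
def toy_record() -> RaceRecord:
    return RaceRecord("toy", 1, TOY_COURSE, np.array([0.25, 0.2, 1.0 / 6.0]))


def random_record(rng: np.random.Generator, course: RaceCourse = MARATHON) -> RaceRecord:
    """A marathon record with lognormal lap times around ~470 s."""
    times = np.exp(rng.normal(np.log(470.0), 0.08, course.n_laps))
    return RaceRecord("rnd", 1, course, times)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort plus its ground truth."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def default_variables(default_cohort):
    cohort, _ = default_cohort
    return cohort_variables(cohort)
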