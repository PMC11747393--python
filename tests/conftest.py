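import numpy as np
import pytest

from pramnet.data_model import Cohort, ConceptSet, RatingMatrix, canonical_pair_index
from pramnet.simulate import SimulationConfig, simulate_cohort

import pandas as pd


@pytest.fixture(scope="session")
def concepts16() -> ConceptSet:
    return ConceptSet()


@pytest.fixture(scope="session")
def pairs16(concepts16):
    return canonical_pair_index(concepts16)


@pytest.fixture(scope="session")
def concepts5() -> ConceptSet:
    return ConceptSet(("a", "b", "c", "d", "e"))


def make_cohort(
    ratings: np.ndarray,
    race: np.ndarray,
    news_bias: np.ndarray,
    concepts: ConceptSet,
    gender=None,
    income=None,
    age=None,
) -> Cohort:
    """Assemble a cohort directly from arrays (test helper)."""
    n = ratings.shape[0]
    pi = canonical_pair_index(concepts)
    rng = np.random.default_rng(0)
    demo = pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "race": np.asarray(race, int),
            "gender": rng.integers(0, 2, n) if gender is None else gender,
            "income": rng.integers(0, 10, n) if income is None else income,
            "age": rng.integers(18, 76, n).astype(float) if age is None else age,
        }
    )
    rm = RatingMatrix(ratings, tuple(demo["participant_id"]), pi)
    return Cohort(rm, demo, np.asarray(news_bias, float))


@pytest.fixture
def small_null_cohort():
    cfg = SimulationConfig(n_per_group=25, mediator_mean=2.5, mediator_sd=0.8)
    return simulate_cohort(cfg, seed=42)
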