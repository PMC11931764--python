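import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from darndest.reference import PUBLISHED_CUTOFFS, reference_score_table
from darndest.score_io import ScoreTable
from darndest.synthetic import SyntheticConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def internal_table() -> ScoreTable:
    """Worked-example table realising the internal-cohort quadruples."""
    return reference_score_table("internal")


@pytest.fixture(scope="session")
def external_table() -> ScoreTable:
    return reference_score_table("external")


@pytest.fixture(scope="session")
def internal_cutoffs():
    return PUBLISHED_CUTOFFS["internal"]


@pytest.fixture(scope="session")
def big_cohort() -> ScoreTable:
    """One large synthetic cohort shared by the calibration checks."""
    return generate_cohort(SyntheticConfig(n=20_000, seed=20240417))


def random_table(rng: np.random.Generator, n: int, prevalence: float = 0.45) -> ScoreTable:
    """Small random score table guaranteed to contain both classes."""
    labels = rng.binomial(1, prevalence, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    scores = rng.uniform(size=(n, 3))
    # give the scores some signal so cutoffs are not degenerate
    scores = np.clip(scores + 0.25 * labels[:, None] - 0.125, 0.0, 1.0)
    ids = [f"R{i:04d}" for i in range(n)]
    return ScoreTable.from_arrays(ids, labels, scores[:, 0], scores[:, 1], scores[:, 2])
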