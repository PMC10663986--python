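import numpy as np
import pytest

from pathsurv.data_model import SurvivalDataset
from pathsurv.pathway_matrix import PathwayMatrix
from pathsurv.synthetic_data import (
    SimulationConfig,
    simulate_cohort,
    synthetic_pathway_matrix,
)


@pytest.fixture(scope="session")
def toy_pm() -> PathwayMatrix:
    # m1 in p1+p2, m2 in p2 only: 3 edges
    return PathwayMatrix(np.array([[1.0, 1.0], [0.0, 1.0]]), ["m1", "m2"], ["p1", "p2"])


@pytest.fixture(scope="session")
def paper_scale_pm() -> PathwayMatrix:
    return synthetic_pathway_matrix(seed=0)


@pytest.fixture(scope="session")
def small_cohort(paper_scale_pm):
    """100-sample pathway-structured cohort at the motivating study's shape."""
    cfg = SimulationConfig(n=100, pm=paper_scale_pm, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_dataset() -> SurvivalDataset:
    rng = np.random.default_rng(5)
    n = 20
    return SurvivalDataset(
        features=rng.lognormal(size=(n, 3)),
        metabolite_names=["glutamate", "glutamine", "alanine"],
        events=rng.integers(0, 2, size=n) | (np.arange(n) == 0),
        durations=rng.uniform(1, 100, size=n),
    )


def naive_cox_loss(risks, events, durations):
    """Independent double-loop negative log partial likelihood oracle:
    inclusive risk set (d_j >= d_i), Breslow shared denominators."""
    risks = np.asarray(risks, float)
    total = 0.0
    for i in range(len(risks)):
        if events[i] != 1:
            continue
        den = 0.0
        for j in range(len(risks)):
            if durations[j] >= durations[i]:
                den += np.exp(risks[j])
        total += risks[i] - np.log(den)
    return -total


def naive_harrell(risks, events, durations):
    """Brute-force pair enumeration concordance oracle."""
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        for j in range(n):
            if events[i] == 1 and durations[i] < durations[j]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den
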