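import numpy as np
import pytest

from sleepeval.hypnodata import Hypnogram, Hypnodensity, MultiScorerRecord


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_hypnogram(
    rng: np.random.Generator,
    n_epochs: int,
    p_nonstage: float = 0.0,
    source_id: str = "",
) -> Hypnogram:
    tokens = ("W", "N1", "N2", "N3", "REM")
    labels = []
    for _ in range(n_epochs):
        if rng.random() < p_nonstage:
            labels.append(rng.choice(["MOVEMENT", "UNKNOWN"]))
        else:
            labels.append(tokens[rng.integers(5)])
    return Hypnogram(tuple(labels), source_id=source_id)


def random_hypnodensity(
    rng: np.random.Generator, n_epochs: int, source_id: str = ""
) -> Hypnodensity:
    probs = rng.dirichlet(np.ones(5), size=n_epochs)
    return Hypnodensity(probs, source_id=source_id)


@pytest.fixture
def small_record(rng) -> MultiScorerRecord:
    """Five noisy scorings of the same 40-epoch recording."""
    scorers = tuple(
        random_hypnogram(rng, 40, source_id=f"s{i}") for i in range(5)
    )
    return MultiScorerRecord("rec0", scorers)
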