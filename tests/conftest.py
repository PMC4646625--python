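import numpy as np
import pytest

from flaps.synthetic import SynthConfig, make_census, make_landscape, sample_pa


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    """Small-but-representative scenario shared across test modules."""
    return SynthConfig(seed=20120424)


@pytest.fixture(scope="session")
def census_pair(synth_cfg):
    return make_census(synth_cfg)


@pytest.fixture(scope="session")
def truth_table(census_pair):
    return census_pair[0]


@pytest.fixture(scope="session")
def observed_table(census_pair):
    return census_pair[1]


@pytest.fixture(scope="session")
def small_landscape():
    """One-county landscape with a well-spread probability surface."""
    cfg = SynthConfig(
        seed=7, n_states=1, counties_per_state=1, landscape_shape=(150, 150),
        sample_size=3000,
    )
    return cfg, make_landscape(cfg)


@pytest.fixture(scope="session")
def pa_sample(small_landscape):
    cfg, land = small_landscape
    return sample_pa(cfg, land)


def logistic_sample(
    rng: np.random.Generator,
    n: int,
    beta: dict[str, float],
    intercept: float,
    n_noise: int = 0,
):
    """Simulate a presence/absence frame from a known linear logit."""
    import pandas as pd

    names = list(beta)
    X = rng.normal(size=(n, len(names) + n_noise))
    eta = intercept + X[:, : len(names)] @ np.array([beta[c] for c in names])
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    cols = {"y": y}
    for j, c in enumerate(names):
        cols[c] = X[:, j]
    for j in range(n_noise):
        cols["noise%d" % (j + 1)] = X[:, len(names) + j]
    return pd.DataFrame(cols)
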