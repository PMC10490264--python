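import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from homeoscope.simulate import SimulationConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic fixture: 3000 pairs, 4-fold effects, NB
    dispersion 0.05, 3 replicates per group."""
    return simulate_dataset(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, small world for IO/pipeline plumbing tests."""
    return simulate_dataset(
        SimulationConfig(
            seed=7, n_pairs=120, n_singletons_a=15, n_singletons_d=15,
            n_unplaced_a=5, n_unplaced_d=5,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def nb_counts(rng, mu, n_reps, dispersion):
    """Sample an (units x n_reps) NB count block with Var = mu + disp mu^2."""
    mu = np.asarray(mu, dtype=float)
    out = np.empty((len(mu), n_reps), dtype=np.int64)
    for j in range(n_reps):
        if dispersion == 0:
            out[:, j] = rng.poisson(mu)
        else:
            lam = rng.gamma(1.0 / dispersion, mu * dispersion)
            out[:, j] = rng.poisson(lam)
    return out


def two_group_frame(k1, k2):
    """Assemble two count blocks into a counts frame + group labels."""
    k = np.hstack([k1, k2])
    cols = [f"s{i}" for i in range(k.shape[1])]
    counts = pd.DataFrame(k, index=[f"g{i}" for i in range(k.shape[0])], columns=cols)
    groups = pd.Series(
        ["g1"] * k1.shape[1] + ["g2"] * k2.shape[1], index=cols
    )
    return counts, groups
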