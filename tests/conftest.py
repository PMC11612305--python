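import numpy as np
import pandas as pd
import pytest

from parenclitic import BetaMatrix, SyntheticConfig, generate_dataset

#: quick study design used by unit tests (full default design is exercised
#: by the acceptance tests)
SMALL_CONFIG = SyntheticConfig(
    n_baseline=40, n_train_pos=8, n_train_neg=8, n_eval_pos=6, n_eval_neg=8,
    n_loci=24, n_planted=6, seed=11,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_beta():
    frame = pd.DataFrame(
        np.array([[0.1, 0.2, 0.3],
                  [0.9, 0.8, 0.7],
                  [0.5, 0.5, 0.5],
                  [0.0, 1.0, 0.4],
                  [0.25, 0.75, 0.5]]),
        index=[f"cg{i}" for i in range(5)],
        columns=["sA", "sB", "sC"],
    )
    return BetaMatrix(frame)


def random_spd(rng, scale=0.05):
    a = rng.normal(scale=scale, size=(2, 2))
    return a @ a.T + np.diag(rng.uniform(1e-4, scale, size=2))


def random_pair_gmm(rng, max_components=4):
    from parenclitic import PairGMM

    k = int(rng.integers(1, max_components + 1))
    w = rng.dirichlet(np.ones(k))
    means = rng.uniform(0, 1, size=(k, 2))
    covs = np.stack([random_spd(rng) for _ in range(k)])
    return PairGMM(pair=(0, 1), weights=w, means=means, covariances=covs,
                   bic={}, converged={})
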