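import numpy as np
import pytest

from espamarkov import GaussianCentroids, project_simplex_columns


@pytest.fixture
def rng():
    return np.random.default_rng(20240553)


def random_affiliation(rng, K, T):
    """Random feasible column-stochastic matrix."""
    return project_simplex_columns(rng.uniform(size=(K, T)))


def random_onehot(rng, M, T):
    """Random exact one-hot label matrix with every label present."""
    lab = rng.integers(0, M, size=T)
    lab[:M] = np.arange(M)  # guarantee every label occurs
    Pi = np.zeros((M, T))
    Pi[lab, np.arange(T)] = 1.0
    return Pi


def random_instance(rng, D=3, K=2, T=12, M=2):
    """A dimension-consistent random problem (X, Pi, gamma, theta, lam, W)."""
    X = rng.normal(size=(D, T))
    Pi = random_onehot(rng, M, T)
    gamma = random_affiliation(rng, K, T)
    theta = GaussianCentroids(rng.normal(size=(D, K)), rng.uniform(0.5, 2.0, (D, K)))
    lam = random_affiliation(rng, M, K)
    W = random_affiliation(rng, D, 1).ravel()
    # keep Lambda and W strictly positive so logs stay finite
    lam = (lam + 0.05) / (lam + 0.05).sum(axis=0)
    W = (W + 0.05) / (W + 0.05).sum()
    return X, Pi, gamma, theta, lam, W
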