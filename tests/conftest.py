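"""Shared fixtures: random model factories and exhaustive-enumeration oracles.

The brute-force functions evaluate HMM quantities by summing or maximising
over every possible state path; they share no code with the package's
recursions and serve as independent ground truth on short sequences.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from gaitphase import (
    DiscreteEmission,
    GaussianEmission,
    GmmEmission,
    HmmModel,
)


def random_model(
    rng: np.random.Generator,
    family: str = "gaussian",
    n_states: int = 4,
    dim: int = 2,
    n_components: int = 3,
    n_symbols: int = 5,
) -> HmmModel:
    """A dense random model (no structural zeros) of the requested family."""
    A = rng.random((n_states, n_states)) + 0.1
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.random(n_states) + 0.1
    pi /= pi.sum()
    if family == "discrete":
        p = rng.random((n_states, n_symbols)) + 0.1
        p /= p.sum(axis=1, keepdims=True)
        emission = DiscreteEmission(p)
    elif family == "gaussian":
        means = rng.normal(0, 2, (n_states, dim))
        covs = np.stack([np.diag(rng.random(dim) + 0.3) for _ in range(n_states)])
        emission = GaussianEmission(means, covs)
    elif family == "gmm":
        w = rng.random((n_states, n_components)) + 0.1
        w /= w.sum(axis=1, keepdims=True)
        emission = GmmEmission(
            w,
            rng.normal(0, 2, (n_states, n_components, dim)),
            rng.random((n_states, n_components, dim)) + 0.3,
        )
    else:
        raise ValueError(family)
    return HmmModel(pi, A, emission)


def brute_force_logliks(model: HmmModel, obs: np.ndarray) -> tuple[float, float]:
    """(total log-likelihood, best-path log-probability) by path enumeration."""
    logb = model.emission.log_density(obs)
    T, N = logb.shape
    with np.errstate(divide="ignore"):
        logA = np.log(model.transitions)
        logpi = np.log(model.pi)
    totals = []
    for path in itertools.product(range(N), repeat=T):
        lp = logpi[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logb[t, path[t]]
        totals.append(lp)
    return float(logsumexp(totals)), float(max(totals))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
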