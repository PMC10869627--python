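"""Shared fixtures and independent oracles.

The brute-force path-enumeration oracle computes HMM likelihoods and
posteriors by summing over every hidden-state path; it is deliberately
naive (exponential in T) and shares no code with the package's scaled
forward-backward recursions.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from crisishmm import ModelParams, SimConfig, FitConfig, PolicyConfig
from crisishmm.pipeline import run_simulation_experiment


def path_probability(
    m: ModelParams, prior_U: float, path: tuple[int, ...], obs
) -> float:
    """Joint probability of one hidden path and the observations."""
    pr = prior_U if path[0] == 1 else 1.0 - prior_U
    for t, (x, y) in enumerate(zip(path, obs)):
        if t > 0:
            prev = path[t - 1]
            if prev == 1:
                pr *= m.r if x == 1 else 1.0 - m.r
            else:
                pr *= m.q if x == 1 else 1.0 - m.q
        if x == 1:
            pr *= m.p if y == 1 else 1.0 - m.p
        else:
            pr *= 0.0 if y == 1 else 1.0
    return pr


def enumerate_posteriors(m: ModelParams, prior_U: float, obs):
    """Likelihood, state posteriors and transition posteriors by brute force."""
    obs = np.asarray(obs)
    T = len(obs)
    lik = 0.0
    gamma = np.zeros((T, 2))
    xi = np.zeros((max(T - 1, 0), 2, 2))
    for path in product([0, 1], repeat=T):
        pr = path_probability(m, prior_U, path, obs)
        lik += pr
        for t, x in enumerate(path):
            gamma[t, x] += pr
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += pr
    if lik > 0:
        gamma /= lik
        xi /= lik
    return lik, gamma, xi


def random_valid_params(rng: np.random.Generator) -> ModelParams:
    """A parameter triple within the simulator's supported ranges."""
    p = rng.uniform(0.02, 0.98)
    q = rng.uniform(0.02, 0.5)
    r = rng.uniform(0.02, 0.98)
    while abs(q - r) < 1e-3:
        r = rng.uniform(0.02, 0.98)
    return ModelParams(p=p, q=q, r=r)


@pytest.fixture
def pooled_params() -> ModelParams:
    """The pooled average-patient parameters used as an in-package fixture."""
    return ModelParams(p=0.95, q=0.037, r=0.86)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def scaled_experiment():
    """One scaled-down cohort experiment shared by the acceptance tests.

    300 patients (one tenth of the full study, with the forced-r=0 group
    scaled in proportion), 260 weeks split 208/52, single EM run per
    patient with the study's tolerance and iteration cap.
    """
    cfg = SimConfig(n_patients=300, n_weeks=260, train_weeks=208,
                    n_zero_r=30)
    return run_simulation_experiment(
        cfg,
        FitConfig(tol=1e-5, max_iter=1000, n_restarts=1),
        PolicyConfig(tau=0.35),
        seed=123,
    )
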