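"""Shared fixtures: random model parameters and brute-force oracles.

The oracles expand the latent sums explicitly (every (k_1..k_r, l)
combination), independently of the factorized likelihoods they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from vatensor import ModelConfig, SymptomDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_instance(rng, p=4, K=2, r=2, h=2):
    """Random valid parameters for one cause of each model family."""
    phi = rng.uniform(0.05, 0.95, size=(K, p))
    lam_flat = rng.dirichlet(np.ones(K))
    lam = rng.dirichlet(np.ones(K), size=r)
    nu = rng.dirichlet(np.ones(h))
    psi = rng.dirichlet(np.ones(K), size=(h, r))
    s_c = rng.integers(0, r, size=p)
    # ensure every group index is feasible even if unused
    return dict(phi=phi, lam_flat=lam_flat, lam=lam, nu=nu, psi=psi, s_c=s_c)


def brute_prob_parafac(x, phi, lam):
    """Direct K-term mixture sum, linear domain."""
    tot = 0.0
    for k in range(len(lam)):
        tot += lam[k] * np.prod(phi[k] ** x * (1 - phi[k]) ** (1 - x))
    return tot


def brute_prob_grouped(x, phi, lam, s_c):
    """Explicit sum over every class combination (k_1..k_r)."""
    r, K = lam.shape
    tot = 0.0
    for ks in product(range(K), repeat=r):
        w = np.prod([lam[s, ks[s]] for s in range(r)])
        like = 1.0
        for j, xj in enumerate(x):
            pj = phi[ks[s_c[j]], j]
            like *= pj ** xj * (1 - pj) ** (1 - xj)
        tot += w * like
    return tot


def brute_prob_ctucker(x, phi, nu, psi, s_c):
    """Explicit sum over (k_1..k_r, l)."""
    h, r, K = psi.shape
    tot = 0.0
    for l in range(h):
        for ks in product(range(K), repeat=r):
            w = nu[l] * np.prod([psi[l, s, ks[s]] for s in range(r)])
            like = 1.0
            for j, xj in enumerate(x):
                pj = phi[ks[s_c[j]], j]
                like *= pj ** xj * (1 - pj) ** (1 - xj)
            tot += w * like
    return tot


def all_configs(p):
    return ((np.arange(2 ** p)[:, None] >> np.arange(p)) & 1).astype(float)


@pytest.fixture
def small_dataset(rng):
    """A modest labeled/unlabeled dataset for sampler tests."""
    from vatensor import generate_dataset, SimulationConfig

    data, truth = generate_dataset(SimulationConfig(
        C=3, p=6, n_train=120, n_target=60, K=2, r=2, h=2,
        informative_groups=(1, 2), seed=11))
    return data, truth


def empty_dataset(p=4, C=3):
    return SymptomDataset(
        X=np.zeros((0, p), dtype=np.int8),
        Y=np.zeros(0, dtype=np.int64),
        D=np.zeros(0, dtype=np.int64),
        symptom_names=[f"s{j}" for j in range(p)],
        cause_names=[f"c{k}" for k in range(C)],
    )
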