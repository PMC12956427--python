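"""Frozen-state moment checks for every Gibbs full conditional.

Each check freezes the conditioning variables of one update, draws it
repeatedly (the sampler's other state is untouched by that update), and
compares empirical moments with the analytic conditional posterior.
Returns (label, observed, expected, tolerance) tuples where tolerance
is three Monte-Carlo standard errors.
"""

from __future__ import annotations

import numpy as np

from vatensor import GibbsSampler, ModelConfig, SymptomDataset


def build_sampler(X, Y, D, C, cfg, seed=5150):
    n, p = np.shape(X)
    data = SymptomDataset(
        X=np.asarray(X, dtype=np.int8), Y=np.asarray(Y), D=np.asarray(D),
        symptom_names=[f"s{j}" for j in range(p)],
        cause_names=[f"c{k}" for k in range(C)])
    sam = GibbsSampler(data, cfg, rng=np.random.default_rng(seed))
    return sam


def repeat_draws(sam, method, attr, n_draws):
    out = []
    fn = getattr(sam, method)
    for _ in range(n_draws):
        fn()
        out.append(np.array(getattr(sam, attr), copy=True))
    return np.asarray(out)


def dirichlet_moment_tol(alpha, idx, n_draws):
    a = np.asarray(alpha, float)
    a0 = a.sum()
    mean = a[idx] / a0
    var = a[idx] * (a0 - a[idx]) / (a0 ** 2 * (a0 + 1.0))
    return mean, 3.0 * np.sqrt(var / n_draws)


def categorical_freq_tol(prob, n_draws):
    return 3.0 * np.sqrt(prob * (1.0 - prob) / n_draws)


def conditional_moment_checks(n_draws=6000):
    """Moment checks for Y, Z, H, pi, nu, psi, lambda, phi, s, xi."""
    checks = []

    # --- pi: 10 training deaths of cause 0, no target deaths ------------
    cfg = ModelConfig(model="ctucker", K=2, r=2, h=2, n_iter=2, n_burnin=1,
                      seed=1)
    sam = build_sampler(np.zeros((10, 2)), np.zeros(10, int),
                        np.ones(10, int), 3, cfg)
    draws = repeat_draws(sam, "sample_pi", "pi1", n_draws)
    mean, tol = dirichlet_moment_tol([11, 1, 1], 0, n_draws)
    checks.append(("pi1[0] | counts (10,0,0)", draws[:, 0].mean(), mean, tol))
    draws0 = repeat_draws(sam, "sample_pi", "pi0", n_draws)
    mean, tol = dirichlet_moment_tol([1, 1, 1], 0, n_draws)
    checks.append(("pi0[0] | no target deaths", draws0[:, 0].mean(), mean, tol))

    # --- phi: cause 0 class 0 sees 3 ones and 1 zero ---------------------
    X = np.array([[1], [1], [1], [0]])
    sam = build_sampler(X, np.zeros(4, int), np.ones(4, int), 2,
                        ModelConfig(model="grouped", K=2, r=1, n_iter=2,
                                    n_burnin=1, seed=2))
    sam.Z[:] = 0
    draws = repeat_draws(sam, "sample_phi", "phi", n_draws)
    checks.append(("phi[0,0,0] | 3 ones 1 zero",
                   draws[:, 0, 0, 0].mean(), 4.0 / 6.0,
                   3.0 * np.sqrt((4 * 2 / (36.0 * 7)) / n_draws)))
    checks.append(("phi[0,1,0] | no data (prior Beta(1,1))",
                   draws[:, 0, 1, 0].mean(), 0.5,
                   3.0 * np.sqrt((1.0 / 12) / n_draws)))
    assert ((draws > 0) & (draws < 1)).all()

    # --- y: C=2, p=1, K=1 closed-form posterior odds ---------------------
    X = np.array([[1]])
    sam = build_sampler(X, np.array([-1]), np.array([0]), 2,
                        ModelConfig(model="parafac", K=1, n_iter=2,
                                    n_burnin=1, seed=3))
    sam.phi = np.array([[[0.8]], [[0.3]]])
    sam._refresh_logphi()
    sam.pi0 = np.array([0.6, 0.4])
    draws = repeat_draws(sam, "sample_y", "Y", n_draws)
    post0 = 0.6 * 0.8 / (0.6 * 0.8 + 0.4 * 0.3)
    checks.append(("P(Y=c0 | x=1), Bayes rule", (draws[:, 0] == 0).mean(),
                   post0, categorical_freq_tol(post0, n_draws)))

    # --- y under flat likelihood reproduces pi0 --------------------------
    sam = build_sampler(X, np.array([-1]), np.array([0]), 2,
                        ModelConfig(model="parafac", K=1, n_iter=2,
                                    n_burnin=1, seed=4))
    sam.phi = np.full((2, 1, 1), 0.5)
    sam._refresh_logphi()
    sam.pi0 = np.array([0.7, 0.3])
    draws = repeat_draws(sam, "sample_y", "Y", n_draws)
    checks.append(("P(Y=c0) | flat likelihood", (draws[:, 0] == 0).mean(),
                   0.7, categorical_freq_tol(0.7, n_draws)))

    # --- z (ctucker): 1-symptom group, K=2, hand-computed posterior ------
    cfg = ModelConfig(model="ctucker", K=2, r=2, h=1, n_iter=2, n_burnin=1,
                      seed=5)
    sam = build_sampler(np.array([[1, 0]]), np.array([0]), np.array([1]),
                        2, cfg)
    sam.s[:] = np.array([0, 1])     # one symptom per group for all causes
    sam._refresh_group_onehot()
    sam.H[:] = 0
    phi = np.full((2, 2, 2), 0.5)
    phi[0, :, 0] = [0.9, 0.2]       # group 0's symptom, classes (0, 1)
    sam.phi = phi
    sam._refresh_logphi()
    psi = np.zeros((2, 1, 2, 2))
    psi[...] = [0.4, 0.6]
    sam.psi = psi
    draws = repeat_draws(sam, "sample_z", "Z", n_draws)
    w0 = 0.4 * 0.9 / (0.4 * 0.9 + 0.6 * 0.2)   # x=1 observed
    checks.append(("P(Z=0) | one-symptom group", (draws[:, 0, 0] == 0).mean(),
                   w0, categorical_freq_tol(w0, n_draws)))

    # --- z with class-constant phi follows its prior weights -------------
    sam.phi = np.full((2, 2, 2), 0.5)
    sam._refresh_logphi()
    draws = repeat_draws(sam, "sample_z", "Z", n_draws)
    checks.append(("P(Z=0) | flat profiles", (draws[:, 0, 0] == 0).mean(),
                   0.4, categorical_freq_tol(0.4, n_draws)))

    # --- h: posterior proportional to nu * prod_s psi --------------------
    cfg = ModelConfig(model="ctucker", K=2, r=2, h=2, n_iter=2, n_burnin=1,
                      seed=6)
    sam = build_sampler(np.array([[0, 0]]), np.array([0]), np.array([1]),
                        2, cfg)
    sam.Z[:] = np.array([0, 1])
    nu = np.array([[0.3, 0.7], [0.5, 0.5]])
    sam.nu = nu
    psi = np.empty((2, 2, 2, 2))
    psi[0, 0] = [[0.9, 0.1], [0.2, 0.8]]
    psi[0, 1] = [[0.5, 0.5], [0.5, 0.5]]
    psi[1] = 0.5
    sam.psi = psi
    w = nu[0] * np.array([0.9 * 0.8, 0.5 * 0.5])
    w = w / w.sum()
    draws = repeat_draws(sam, "sample_h", "H", n_draws)
    checks.append(("P(H=0) | fixed Z", (draws[:, 0] == 0).mean(),
                   w[0], categorical_freq_tol(w[0], n_draws)))

    # --- nu: frozen (Y, H) counts -> Dirichlet moments --------------------
    sam.Y[:] = 0
    sam.H[:] = 0
    draws = repeat_draws(sam, "sample_nu", "nu", n_draws)
    mean, tol = dirichlet_moment_tol([0.5 + 1, 0.5], 0, n_draws)
    checks.append(("nu[0,0] | one (c0, l0) death", draws[:, 0, 0].mean(),
                   mean, tol))

    # --- psi: frozen (Y, H, Z) counts -------------------------------------
    draws = repeat_draws(sam, "sample_psi", "psi", n_draws)
    mean, tol = dirichlet_moment_tol([2, 1], 0, n_draws)
    checks.append(("psi[0,0,0,0] | one class-0 death",
                   draws[:, 0, 0, 0, 0].mean(), mean, tol))
    mean, tol = dirichlet_moment_tol([1, 2], 1, n_draws)
    checks.append(("psi[0,0,1,1] | one class-1 death",
                   draws[:, 0, 0, 1, 1].mean(), mean, tol))

    # --- lambda (grouped): frozen (Y, Z) counts ---------------------------
    cfgg = ModelConfig(model="grouped", K=2, r=2, n_iter=2, n_burnin=1,
                       seed=7)
    samg = build_sampler(np.array([[0, 0], [0, 0]]), np.array([0, 0]),
                         np.array([1, 1]), 2, cfgg)
    samg.Z[:] = np.array([[0, 1], [0, 1]])
    draws = repeat_draws(samg, "sample_lambda", "lam", n_draws)
    mean, tol = dirichlet_moment_tol([3, 1], 0, n_draws)
    checks.append(("lam[0,0,0] | two class-0 deaths",
                   draws[:, 0, 0, 0].mean(), mean, tol))

    # --- s: flat profiles make the grouping follow xi ---------------------
    cfg = ModelConfig(model="ctucker", K=2, r=2, h=1, n_iter=2, n_burnin=1,
                      seed=8)
    sam = build_sampler(np.array([[1, 0]]), np.array([0]), np.array([1]),
                        2, cfg)
    sam.phi = np.full((2, 2, 2), 0.5)
    sam._refresh_logphi()
    sam.xi = np.array([[0.25, 0.75], [0.5, 0.5]])
    draws = repeat_draws(sam, "sample_s", "s", n_draws)
    checks.append(("P(s=0) | flat profiles", (draws[:, 0, 0] == 0).mean(),
                   0.25, categorical_freq_tol(0.25, n_draws)))

    # --- s: two deaths, hand-computed two-term product --------------------
    cfg = ModelConfig(model="ctucker", K=2, r=2, h=1, n_iter=2, n_burnin=1,
                      seed=9)
    sam = build_sampler(np.array([[1, 1], [0, 1]]), np.array([0, 0]),
                        np.array([1, 1]), 2, cfg)
    sam.Z[:] = np.array([[0, 1], [1, 0]])
    phi = np.empty((2, 2, 2))
    phi[0] = [[0.9, 0.6], [0.3, 0.2]]
    phi[1] = 0.5
    sam.phi = phi
    sam._refresh_logphi()
    sam.xi = np.array([[0.5, 0.5], [0.5, 0.5]])
    # symptom j=0: group 0 -> classes (Z_i0) = (0, 1): phi (0.9, 0.3)
    #              group 1 -> classes (Z_i1) = (1, 0): phi (0.3, 0.9)
    w_g0 = 0.9 * (1 - 0.3)
    w_g1 = 0.3 * (1 - 0.9)
    p_g0 = w_g0 / (w_g0 + w_g1)
    draws = repeat_draws(sam, "sample_s", "s", n_draws)
    checks.append(("P(s_{c0,j0}=0) | two deaths", (draws[:, 0, 0] == 0).mean(),
                   p_g0, categorical_freq_tol(p_g0, n_draws)))

    # --- xi: frozen s counts ----------------------------------------------
    sam.s[:] = np.array([[0, 0], [0, 1]])
    draws = repeat_draws(sam, "sample_xi", "xi", n_draws)
    mean, tol = dirichlet_moment_tol([0.5 + 2, 0.5], 0, n_draws)
    checks.append(("xi[0,0] | both symptoms in group 0",
                   draws[:, 0, 0].mean(), mean, tol))

    return checks
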