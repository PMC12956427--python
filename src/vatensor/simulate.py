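"""Synthetic verbal-autopsy data generated from the c-Tucker model.

The generator reproduces the simulation design used to study the
dimension-grouped decompositions: C=20 causes, p=80 symptoms, 2000
labeled training deaths and 1000 unlabeled target deaths, symptoms
generated ancestrally (Y -> H -> Z -> X) from a c-Tucker model with
K=3 latent classes per group, r=5 symptom groups and h=3 upper-level
classes.  Two scenarios are supported:

* Scenario I — pure label shift: the training and target domains share
  all conditional parameters and differ only in the cause prevalences
  pi^(0), pi^(1) ~ Dir(1, ..., 1).
* Scenario II — additional conditional shift: the group-class weights
  psi are drawn independently per domain, so p(X | Y) itself differs
  between domains and every fitted model is misspecified.

The group matrix is cyclic: each row lists r sequential blocks of
g = p/r symptoms, and each successive cause's row is the previous row
rotated by one symptom.  To mimic the low signal-to-noise ratio of real
VA data only the symptoms falling in the "informative" groups (3, 4, 5
by default, 1-based) have cause-specific Bernoulli profiles; the rest
share one class-dependent profile across all causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelConfig, SymptomDataset

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "make_group_matrix",
    "draw_prevalences",
    "draw_scenario_weights",
    "draw_profiles",
    "generate_dataset",
    "resample_experiment",
]


@dataclass
class SimulationConfig:
    """Dimensions and scenario of the synthetic-data generator.

    Defaults are the study conditions: C=20, p=80, 2000 training and
    1000 target deaths, K=3, r=5, h=3, beta concentrations uniform on
    the integers 1..10, informative groups {3, 4, 5} (1-based).
    """

    C: int = 20
    p: int = 80
    n_train: int = 2000
    n_target: int = 1000
    K: int = 3
    r: int = 5
    h: int = 3
    scenario: str = "I"
    beta_range: tuple[int, int] = (1, 10)
    informative_groups: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.informative_groups is None:
            # groups 1..2 carry shared (non-informative) profiles when
            # there are enough groups to spare; tiny r keeps everything
            # informative
            self.informative_groups = (tuple(range(3, self.r + 1))
                                       if self.r >= 3
                                       else tuple(range(1, self.r + 1)))
        if self.scenario not in ("I", "II", "custom"):
            raise ValueError("scenario must be 'I', 'II' or 'custom'")
        if self.p % self.r:
            raise ValueError("p must be divisible by r (g = p/r symptoms per group)")
        if min(self.C, self.p, self.K, self.r, self.h) < 1 or self.C < 2:
            raise ValueError("invalid dimensions")
        if not all(1 <= g <= self.r for g in self.informative_groups):
            raise ValueError("informative group indices must lie in 1..r")
        lo, hi = self.beta_range
        if lo < 1 or hi < lo:
            raise ValueError("beta_range must satisfy 1 <= lo <= hi")


@dataclass
class SimulationTruth:
    """Everything the generator drew, for parameter-recovery scoring."""

    config: SimulationConfig
    pi0: np.ndarray            # (C,)
    pi1: np.ndarray            # (C,)
    nu: np.ndarray             # (C, h)
    psi: np.ndarray            # (C, h, r, K) — Scenario I / custom
    phi: np.ndarray            # (C, K, p)
    s: np.ndarray              # (C, p) 0-based groups
    Y: np.ndarray = field(default=None)  # true causes for ALL deaths
    H: np.ndarray = field(default=None)
    Z: np.ndarray = field(default=None)
    D: np.ndarray = field(default=None)
    psi_by_domain: np.ndarray | None = None  # (2, C, h, r, K) Scenario II

    def psi_for_domain(self, g: int) -> np.ndarray:
        if self.psi_by_domain is not None:
            return self.psi_by_domain[g]
        return self.psi


def make_group_matrix(C: int, p: int, r: int) -> np.ndarray:
    """Cyclic cause-specific group matrix, 0-based entries in 0..r-1.

    With g = p/r, cause c (0-based) assigns symptom j to group
    ``((j - c) mod p) // g``, so row c+1 is row c rotated by one symptom
    position and every row holds exactly g symptoms per group.
    """
    if p % r:
        raise ValueError("p must be divisible by r")
    g = p // r
    c_idx = np.arange(C)[:, None]
    j_idx = np.arange(p)[None, :]
    return ((j_idx - c_idx) % p) // g


def draw_prevalences(C: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Independent flat-Dirichlet prevalences (pi0 target, pi1 training)."""
    pi0 = rng.dirichlet(np.ones(C))
    pi1 = rng.dirichlet(np.ones(C))
    return pi0, pi1


def draw_scenario_weights(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Draw (nu, psi, psi_by_domain) for the configured scenario.

    nu is always uniform, nu_cl = 1/h.  psi_cls ~ Dir(beta_cls * 1_K)
    with integer concentrations beta_cls uniform on beta_range.  Under
    Scenario II, psi is drawn independently per domain and the shared
    ``psi`` return value is None.
    """
    C, h, r, K = config.C, config.h, config.r, config.K
    nu = np.full((C, h), 1.0 / h)

    def _draw_psi() -> np.ndarray:
        beta = draw_concentrations(config, rng)
        g = rng.standard_gamma(np.broadcast_to(beta[..., None], (C, h, r, K)))
        return g / g.sum(axis=-1, keepdims=True)

    if config.scenario == "II":
        psi_by_domain = np.stack([_draw_psi(), _draw_psi()])
        return nu, None, psi_by_domain
    return nu, _draw_psi(), None


def draw_concentrations(config: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Symmetric-Dirichlet concentrations beta_cls (C, h, r).

    Integers drawn uniformly from beta_range, inclusive on both ends.
    """
    lo, hi = config.beta_range
    return rng.integers(lo, hi + 1,
                        size=(config.C, config.h, config.r)).astype(float)


def draw_profiles(config: SimulationConfig, s: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Symptom profiles phi (C, K, p) with informative structure.

    A (c, j) cell whose group s_cj is *not* informative uses a profile
    shared across causes (still latent-class-dependent); informative
    cells get independent cause-specific probabilities.  All entries are
    iid Beta(1, 1).
    """
    C, K, p = config.C, config.K, config.p
    shared = rng.uniform(size=(K, p))
    specific = rng.uniform(size=(C, K, p))
    informative0 = np.asarray(config.informative_groups) - 1
    is_informative = np.isin(s, informative0)          # (C, p)
    return np.where(is_informative[:, None, :], specific,
                    np.broadcast_to(shared, (C, K, p)))


def generate_dataset(
    config: SimulationConfig | None = None, **kwargs
) -> tuple[SymptomDataset, SimulationTruth]:
    """Ancestral c-Tucker sampling of a training/target VA dataset.

    Deaths are ordered training first, target second.  Target-cause
    labels are hidden in the returned :class:`SymptomDataset` (Y = -1)
    but preserved in the :class:`SimulationTruth`.
    """
    if config is None:
        config = SimulationConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    C, p, K, r, h = config.C, config.p, config.K, config.r, config.h
    n1, n0 = config.n_train, config.n_target
    n = n1 + n0

    pi0, pi1 = draw_prevalences(C, rng)
    s = make_group_matrix(C, p, r)
    nu, psi, psi_by_domain = draw_scenario_weights(config, rng)
    phi = draw_profiles(config, s, rng)

    D = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
    Y = np.empty(n, dtype=np.int64)
    Y[:n1] = _categorical(rng, np.broadcast_to(pi1, (n1, C)))
    Y[n1:] = _categorical(rng, np.broadcast_to(pi0, (n0, C)))

    H = _categorical(rng, nu[Y])                        # (n,)
    psi_eff = np.empty((n, r, K))
    if psi_by_domain is not None:
        for g in (0, 1):
            rows = D == g
            psi_eff[rows] = psi_by_domain[g][Y[rows], H[rows]]
    else:
        psi_eff = psi[Y, H]
    Z = np.empty((n, r), dtype=np.int64)
    for sg in range(r):
        Z[:, sg] = _categorical(rng, psi_eff[:, sg])

    # X_ij ~ Bern(phi[c, Z_{i, s_cj}, j])
    s_y = s[Y]                                          # (n, p)
    z_sel = np.take_along_axis(Z, s_y, axis=1)          # (n, p)
    probs = phi[Y[:, None], z_sel, np.arange(p)[None, :]]
    X = (rng.uniform(size=(n, p)) < probs).astype(np.int8)

    Y_obs = Y.copy()
    Y_obs[n1:] = -1
    data = SymptomDataset(
        X=X, Y=Y_obs, D=D,
        symptom_names=[f"symptom_{j + 1}" for j in range(p)],
        cause_names=[f"cause_{c + 1}" for c in range(C)],
    )
    truth = SimulationTruth(
        config=config, pi0=pi0, pi1=pi1, nu=nu,
        psi=psi if psi is not None else (
            psi_by_domain[0] if psi_by_domain is not None else None),
        phi=phi, s=s, Y=Y, H=H, Z=Z, D=D, psi_by_domain=psi_by_domain,
    )
    return data, truth


def _categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draws from (n, C) probabilities."""
    cum = probs.cumsum(axis=1)
    cum /= cum[:, -1:]
    u = rng.uniform(size=(probs.shape[0], 1))
    return np.minimum((cum < u).sum(axis=1), probs.shape[1] - 1)


def resample_experiment(
    X: np.ndarray,
    Y: np.ndarray,
    seed: int,
    train_frac: float = 0.8,
    n_train: int | None = None,
    n_target: int | None = None,
    symptom_names=None,
    cause_names=None,
) -> tuple[SymptomDataset, np.ndarray, np.ndarray]:
    """Train/target resampling of a fully labeled dataset.

    Training rows are drawn with replacement from a ``train_frac``
    subset at the source prevalence; the target set is resampled with
    replacement from the held-out rows, stratified by cause to match a
    fresh pi0 ~ Dir(1, ..., 1).  Causes absent from the held-out pool
    get their pi0 mass renormalized away (with a warning).

    Returns ``(dataset, pi0_drawn, hidden_target_causes)``.
    """
    import warnings

    rng = np.random.default_rng(seed)
    X = np.asarray(X)
    Y = np.asarray(Y)
    n, p = X.shape
    C = int(Y.max()) + 1
    if cause_names is None:
        cause_names = [f"cause_{c + 1}" for c in range(C)]
    if symptom_names is None:
        symptom_names = [f"symptom_{j + 1}" for j in range(p)]

    perm = rng.permutation(n)
    cut = int(round(train_frac * n))
    pool_train, pool_held = perm[:cut], perm[cut:]
    n_train = n_train if n_train is not None else cut
    n_target = n_target if n_target is not None else n - cut

    tr_rows = rng.choice(pool_train, size=n_train, replace=True)

    pi0 = rng.dirichlet(np.ones(C))
    held_by_cause = [pool_held[Y[pool_held] == c] for c in range(C)]
    available = np.array([len(hc) > 0 for hc in held_by_cause])
    if not available.all():
        warnings.warn(
            "some causes have no held-out deaths; their target prevalence "
            "was renormalized over the remaining causes")
        pi0 = np.where(available, pi0, 0.0)
        pi0 = pi0 / pi0.sum()
    counts = rng.multinomial(n_target, pi0)
    tg_rows = np.concatenate([
        rng.choice(held_by_cause[c], size=counts[c], replace=True)
        if counts[c] else np.empty(0, dtype=int)
        for c in range(C)
    ])
    rows = np.concatenate([tr_rows, tg_rows])
    D = np.concatenate([np.ones(n_train, int), np.zeros(len(tg_rows), int)])
    Y_obs = Y[rows].copy()
    hidden = Y_obs[n_train:].copy()
    Y_obs[n_train:] = -1
    data = SymptomDataset(X=X[rows], Y=Y_obs, D=D,
                          symptom_names=symptom_names,
                          cause_names=cause_names)
    return data, pi0, hidden


def config_for_fit(sim: SimulationConfig, model: str = "ctucker",
                   K: int | None = None, **kwargs) -> ModelConfig:
    """Model configuration matching the generator's latent dimensions."""
    return ModelConfig(model=model, K=K if K is not None else sim.K,
                       r=sim.r, h=sim.h, **kwargs)
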