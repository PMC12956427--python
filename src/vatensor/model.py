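"""Core data containers and conditional symptom likelihoods.

The package models verbal-autopsy (VA) records: for death ``i`` a binary
symptom vector ``X_i ∈ {0,1}^p`` and, for training deaths, a cause label
``Y_i ∈ {1..C}``.  The conditional probability tensor ``p(X | Y=c)`` is
approximated by one of three nested decompositions:

``parafac``
    A ``K``-component mixture of independent Bernoulli products (the
    classical latent-class model),
    ``p(x|c) = Σ_k λ_ck Π_j φ_ckj^{x_j} (1-φ_ckj)^{1-x_j}``.

``grouped``
    ``r`` independent PARAFAC mixtures, one per symptom group.  Symptom
    ``j`` belongs to group ``s_cj ∈ {1..r}`` (the grouping is
    cause-specific), and each group carries its own latent class
    indicator with weights ``λ_cs``.

``ctucker``
    The collapsed-Tucker model: the joint weights over the ``r`` group
    indicators are themselves factorized through an upper-level class
    ``H ∈ {1..h}``, ``λ_c,k1..kr = Σ_l ν_cl Π_s ψ_clsks``.  With ``h=1``
    this is the grouped model; with ``h=r=1`` it is PARAFAC.

All public likelihoods are evaluated in log space using the factorized
forms, never the exponential ``K^r``-term expansion.  Probabilities φ are
clamped to ``[CLAMP_EPS, 1-CLAMP_EPS]`` before logs are taken.

Indices are 0-based everywhere inside the package; 1-based labels appear
only at the file I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

CLAMP_EPS = 1e-12

ModelName = Literal["parafac", "grouped", "ctucker"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SymptomDataset:
    """Binary symptom matrix with (partial) cause labels and domain flags.

    Parameters
    ----------
    X : (n, p) array of {0, 1}
        Symptom indicators.  Entries under a False ``mask`` entry are
        ignored (treated as missing) and may hold any value.
    Y : (n,) int array
        Cause labels in ``0..C-1``; ``-1`` marks unknown (target deaths).
    D : (n,) int array of {0, 1}
        Domain flag: 1 = training (label observed), 0 = target.
    symptom_names, cause_names : sequences of str
    mask : (n, p) bool array, optional
        True where the symptom was observed.  ``None`` means fully
        observed.
    """

    X: np.ndarray
    Y: np.ndarray
    D: np.ndarray
    symptom_names: Sequence[str]
    cause_names: Sequence[str]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        self.Y = np.asarray(self.Y, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.int64)
        self.validate()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_causes(self) -> int:
        return len(self.cause_names)

    @property
    def train_index(self) -> np.ndarray:
        return np.flatnonzero(self.D == 1)

    @property
    def target_index(self) -> np.ndarray:
        return np.flatnonzero(self.D == 0)

    def validate(self) -> None:
        n, p = self.X.shape
        if p < 1:
            raise ValueError("dataset needs p >= 1 symptoms")
        # n = 0 is permitted so that a chain can be run on no data at all
        # (every parameter then follows its prior)
        C = len(self.cause_names)
        if C < 2:
            raise ValueError("need at least 2 causes")
        if len(self.symptom_names) != p:
            raise ValueError("symptom_names length does not match p")
        if self.Y.shape != (n,) or self.D.shape != (n,):
            raise ValueError("Y and D must have length n")
        obs = self.mask if self.mask is not None else np.ones_like(self.X, bool)
        if self.mask is not None and self.mask.shape != (n, p):
            raise ValueError("mask shape must match X")
        vals = self.X[obs]
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("observed symptom entries must be 0 or 1")
        if not np.isin(self.D, (0, 1)).all():
            raise ValueError("domain flags must be 0 or 1")
        if ((self.D == 1) & (self.Y < 0)).any():
            raise ValueError("every training death needs a known cause")
        if (self.Y >= C).any():
            raise ValueError("cause label out of range")


@dataclass
class ModelConfig:
    """Model choice, latent dimensions, priors and chain settings.

    ``K`` latent classes per symptom group, ``r`` symptom groups and (for
    the c-Tucker model) ``h`` upper-level classes.  Hyperparameters
    default to the flat choices: Dirichlet(1) for class weights and the
    prevalence π, Beta(1, 1) for symptom probabilities; ν and ξ always
    carry the Dir(1/h) and Dir(1/r) priors.
    """

    model: ModelName = "ctucker"
    K: int = 3
    r: int = 5
    h: int = 3
    dirichlet_a: float | np.ndarray = 1.0   # λ prior (grouped)
    dirichlet_b: float | np.ndarray = 1.0   # ψ prior (ctucker)
    alpha: float | np.ndarray = 1.0         # π prior
    beta_a: float = 1.0                     # φ prior
    beta_b: float = 1.0
    n_iter: int = 3000
    n_burnin: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("parafac", "grouped", "ctucker"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "parafac":
            self.r = 1
        if self.model != "ctucker":
            self.h = 1
        if self.K < 1 or self.r < 1 or self.h < 1:
            raise ValueError("latent dimensions must be >= 1")
        for name in ("dirichlet_a", "dirichlet_b", "alpha"):
            v = np.asarray(getattr(self, name), dtype=float)
            if (v <= 0).any():
                raise ValueError(f"{name} must be positive")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta hyperparameters must be positive")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


def _simplex_check(a: np.ndarray, axis: int, what: str) -> None:
    a = np.asarray(a, float)
    if (a < -1e-12).any() or not np.allclose(a.sum(axis=axis), 1.0, atol=1e-8):
        raise ValueError(f"{what} rows must lie on the probability simplex")


@dataclass
class SymptomProfiles:
    """Per-cause, per-class Bernoulli symptom probabilities φ (C, K, p)."""

    phi: np.ndarray

    def validate(self) -> None:
        if ((self.phi < 0) | (self.phi > 1)).any():
            raise ValueError("phi entries must lie in [0, 1]")


@dataclass
class GroupAssignment:
    """Cause-specific symptom grouping s (C, p) and its weights ξ (C, r)."""

    s: np.ndarray
    xi: np.ndarray

    def validate(self) -> None:
        r = self.xi.shape[1]
        if (self.s < 0).any() or (self.s >= r).any():
            raise ValueError("group indices out of range")
        _simplex_check(self.xi, -1, "xi")


@dataclass
class CTuckerWeights:
    """Upper-level weights ν (C, h) and group-class weights ψ (C, h, r, K)."""

    nu: np.ndarray
    psi: np.ndarray

    def validate(self) -> None:
        _simplex_check(self.nu, -1, "nu")
        _simplex_check(self.psi, -1, "psi")


@dataclass
class GroupedWeights:
    """Per-group class weights λ (C, r, K), simplex over the last axis."""

    lam: np.ndarray

    def validate(self) -> None:
        _simplex_check(self.lam, -1, "lam")


@dataclass
class PrevalenceParams:
    """Cause-specific mortality fractions for target (π⁰) and training (π¹)."""

    pi0: np.ndarray
    pi1: np.ndarray

    def validate(self) -> None:
        _simplex_check(self.pi0, -1, "pi0")
        _simplex_check(self.pi1, -1, "pi1")


@dataclass
class LatentState:
    """Per-death latent indicators: Z (n, r) group classes, H (n,) upper."""

    Z: np.ndarray
    H: np.ndarray | None = None


# ---------------------------------------------------------------------------
# likelihoods


def _clamped_logs(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    phi = np.clip(np.asarray(phi, float), CLAMP_EPS, 1.0 - CLAMP_EPS)
    return np.log(phi), np.log1p(-phi)


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.isfinite(np.asarray(a, float)).all():
            raise ValueError("non-finite parameter value")


def _bernoulli_terms(
    x: np.ndarray, phi_c: np.ndarray, mask: np.ndarray | None
) -> np.ndarray:
    """Per-class, per-symptom log Bernoulli terms, (K, p).

    Masked symptoms contribute 0 (exact marginalization for factors that
    are conditionally independent given the latent state).
    """
    x = np.asarray(x, float)
    phi_c = np.atleast_2d(phi_c)
    if x.ndim != 1 or phi_c.shape[1] != x.shape[0]:
        raise ValueError("x and phi_c dimensions do not match")
    _check_finite(x, phi_c)
    lp, l1p = _clamped_logs(phi_c)
    terms = x * lp + (1.0 - x) * l1p
    if mask is not None:
        terms = np.where(np.asarray(mask, bool), terms, 0.0)
    return terms


def loglik_parafac(
    x: np.ndarray,
    phi_c: np.ndarray,
    lam_c: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """log p(x | Y=c) under the K-class PARAFAC mixture.

    ``phi_c`` is (K, p) and ``lam_c`` a length-K simplex.  With K=1 this
    is the conditionally-independent (naive Bayes) log-likelihood.
    """
    lam_c = np.asarray(lam_c, float)
    _check_finite(lam_c)
    terms = _bernoulli_terms(x, phi_c, mask)
    if lam_c.shape != (terms.shape[0],):
        raise ValueError("lam_c length must equal the number of classes K")
    llam = np.log(np.clip(lam_c, CLAMP_EPS, None))
    return float(logsumexp(llam + terms.sum(axis=1)))


def loglik_grouped(
    x: np.ndarray,
    phi_c: np.ndarray,
    lam_c: np.ndarray,
    s_c: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """log p(x | Y=c) under r independent per-group PARAFAC mixtures.

    ``lam_c`` is (r, K); ``s_c`` holds 0-based group indices per symptom.
    Groups with no symptoms contribute 0.
    """
    lam_c = np.atleast_2d(np.asarray(lam_c, float))
    s_c = np.asarray(s_c, int)
    _check_finite(lam_c)
    r = lam_c.shape[0]
    if s_c.shape != (np.shape(x)[0],) or (s_c < 0).any() or (s_c >= r).any():
        raise ValueError("s_c entries must index one of the r groups")
    terms = _bernoulli_terms(x, phi_c, mask)  # (K, p)
    A = _group_sums(terms, s_c, r)            # (r, K)
    llam = np.log(np.clip(lam_c, CLAMP_EPS, None))
    return float(logsumexp(llam + A, axis=1).sum())


def loglik_ctucker(
    x: np.ndarray,
    phi_c: np.ndarray,
    nu_c: np.ndarray,
    psi_c: np.ndarray,
    s_c: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """log p(x | Y=c) under the collapsed-Tucker decomposition.

    ``nu_c`` is (h,), ``psi_c`` is (h, r, K).  Evaluated through the
    factorized form log Σ_l ν_l Π_s Σ_k ψ_lsk Π_{j∈s} Bern(x_j; φ_kj),
    so the cost is O(h·r·K + p·K) rather than K^r.
    """
    nu_c = np.asarray(nu_c, float)
    psi_c = np.asarray(psi_c, float)
    _check_finite(nu_c, psi_c)
    h, r, K = psi_c.shape
    if nu_c.shape != (h,):
        raise ValueError("nu_c length must equal psi_c's first dimension")
    s_c = np.asarray(s_c, int)
    if (s_c < 0).any() or (s_c >= r).any():
        raise ValueError("s_c entries must index one of the r groups")
    terms = _bernoulli_terms(x, phi_c, mask)
    A = _group_sums(terms, s_c, r)  # (r, K)
    lpsi = np.log(np.clip(psi_c, CLAMP_EPS, None))
    per_group = logsumexp(lpsi + A[None, :, :], axis=2)  # (h, r)
    lnu = np.log(np.clip(nu_c, CLAMP_EPS, None))
    return float(logsumexp(lnu + per_group.sum(axis=1)))


def _group_sums(terms: np.ndarray, s_c: np.ndarray, r: int) -> np.ndarray:
    """Sum (K, p) log terms within each symptom group -> (r, K)."""
    K = terms.shape[0]
    A = np.zeros((r, K))
    np.add.at(A, s_c, terms.T)
    return A


def loglik(
    x: np.ndarray,
    model: ModelName,
    phi_c: np.ndarray,
    *,
    lam_c: np.ndarray | None = None,
    nu_c: np.ndarray | None = None,
    psi_c: np.ndarray | None = None,
    s_c: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Dispatch to the model-specific conditional log-likelihood."""
    if model == "parafac":
        return loglik_parafac(x, phi_c, lam_c, mask)
    if model == "grouped":
        return loglik_grouped(x, phi_c, lam_c, s_c, mask)
    if model == "ctucker":
        return loglik_ctucker(x, phi_c, nu_c, psi_c, s_c, mask)
    raise ValueError(f"unknown model {model!r}")


MAX_ENUM_P = 16


def enumerate_joint(
    model: ModelName,
    phi_c: np.ndarray,
    *,
    lam_c: np.ndarray | None = None,
    nu_c: np.ndarray | None = None,
    psi_c: np.ndarray | None = None,
    s_c: np.ndarray | None = None,
) -> np.ndarray:
    """Probability of every symptom configuration under p(X | Y=c).

    Returns a length-``2^p`` vector ordered so that entry ``b`` is the
    configuration whose j-th symptom equals bit j of ``b`` (little
    endian).  Intended as a brute-force oracle; refuses p > 16.
    """
    p = np.atleast_2d(phi_c).shape[1]
    if p > MAX_ENUM_P:
        raise ValueError(f"enumeration over 2^{p} configurations refused (p > {MAX_ENUM_P})")
    grid = ((np.arange(2 ** p)[:, None] >> np.arange(p)) & 1).astype(float)
    out = np.empty(2 ** p)
    for b, x in enumerate(grid):
        out[b] = np.exp(
            loglik(x, model, phi_c, lam_c=lam_c, nu_c=nu_c, psi_c=psi_c, s_c=s_c)
        )
    return out


def parameter_count(p: int, K: int, r: int = 1, parameterization: str = "grouped") -> int:
    """Free symptom-profile (φ) entries per cause.

    The dimension-grouped models need ``p·K`` regardless of r; expressing
    the same dependence structure with a flat PARAFAC over all ``K^r``
    class combinations needs ``p·K^r`` (``parameterization="expanded"``).
    """
    if p < 1 or K < 1 or r < 1:
        raise ValueError("dimensions must be positive")
    if parameterization == "grouped":
        return p * K
    if parameterization == "expanded":
        return p * K ** r
    raise ValueError(f"unknown parameterization {parameterization!r}")


def expanded_profile_count(K: int, r: int) -> int:
    """Number of distinct expanded symptom profiles, K^r."""
    if K < 1 or r < 1:
        raise ValueError("dimensions must be positive")
    return K ** r
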