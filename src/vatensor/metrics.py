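"""Evaluation metrics and latent-dimension utilization diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .gibbs import PosteriorSamples

__all__ = [
    "csmf_accuracy",
    "top_cause_accuracy",
    "adjusted_rand",
    "UtilizationReport",
    "utilization",
    "select_dimensions",
]


def _check_simplex(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a vector")
    if (v < -1e-9).any() or abs(v.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must lie on the probability simplex")
    return v


def csmf_accuracy(pi_hat: np.ndarray, pi_true: np.ndarray) -> float:
    """CSMF accuracy: 1 - sum|pi_hat - pi| / (2 (1 - min_c pi_c)).

    The L1 error between estimated and true cause-specific mortality
    fractions, rescaled so the score lies in [0, 1] with 1 for a perfect
    estimate and 0 for a point mass on the least prevalent cause.
    """
    pi_hat = _check_simplex(pi_hat, "pi_hat")
    pi_true = _check_simplex(pi_true, "pi_true")
    if pi_hat.shape != pi_true.shape or pi_hat.size < 2:
        raise ValueError("pi_hat and pi_true must share a length C >= 2")
    denom = 2.0 * (1.0 - pi_true.min())
    return float(1.0 - np.abs(pi_hat - pi_true).sum() / denom)


def top_cause_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of deaths whose predicted top cause is the true cause."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predictions and truth must be equal-length, non-empty")
    return float(np.mean(predicted == truth))


def adjusted_rand(part1: np.ndarray, part2: np.ndarray) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    part1 = np.asarray(part1)
    part2 = np.asarray(part2)
    if part1.shape != part2.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(part1, part2))


@dataclass
class UtilizationReport:
    """Posterior occupancy of symptom groups and latent classes.

    ``group_util[s]`` — fraction of stored draws in which at least one
    (cause, symptom) cell is assigned to group s.
    ``group_mass[s]`` — share of all (cause, symptom, draw) assignment
    mass carried by group s (sums to 1); this is the "group variation"
    statistic used for choosing r.
    ``class_util[s, k]`` — fraction of draws in which class k of group s
    was occupied by at least ``occupancy_threshold`` of the deaths.
    ``order`` — groups sorted by decreasing mass.
    """

    group_util: np.ndarray
    group_mass: np.ndarray
    class_util: np.ndarray
    order: np.ndarray
    occupancy_threshold: float


def utilization(samples: PosteriorSamples,
                occupancy_threshold: float = 0.05) -> UtilizationReport:
    """Summarize how many groups/classes the posterior actually uses."""
    s_draws = samples.s                       # (S, C, p)
    S = s_draws.shape[0]
    r = samples.xi.shape[2]
    counts = np.stack([
        np.bincount(s_draws[d].ravel(), minlength=r) for d in range(S)
    ])                                        # (S, r)
    group_util = (counts > 0).mean(axis=0)
    group_mass = counts.sum(axis=0) / max(counts.sum(), 1)
    class_util = (samples.z_occupancy >= occupancy_threshold).mean(axis=0)
    order = np.argsort(-group_mass, kind="stable")
    return UtilizationReport(group_util=group_util, group_mass=group_mass,
                             class_util=class_util, order=order,
                             occupancy_threshold=occupancy_threshold)


def select_dimensions(report: UtilizationReport,
                      variation_target: float = 0.95,
                      util_cutoff: float = 0.05,
                      class_share: float = 0.8) -> tuple[int, int]:
    """Advisory (r*, K*) suggestion from a utilization report.

    r* is the smallest number of groups whose combined assignment mass
    reaches ``variation_target``.  K* is the smallest per-group class
    budget covering at least ``class_share`` of the classes whose
    utilization exceeds ``util_cutoff``.
    """
    mass_sorted = np.sort(report.group_mass)[::-1]
    cum = np.cumsum(mass_sorted)
    r_star = int(np.searchsorted(cum, variation_target - 1e-12) + 1)
    r_star = min(r_star, mass_sorted.size)

    used = report.class_util >= util_cutoff            # (r, K)
    per_group = used.sum(axis=1)
    total = per_group.sum()
    if total == 0:
        return r_star, 1
    K_max = report.class_util.shape[1]
    k_star = K_max
    for K in range(1, K_max + 1):
        if np.minimum(per_group, K).sum() >= class_share * total:
            k_star = K
            break
    return r_star, k_star
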