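"""Post-hoc interpretation of the fitted latent structure.

Summaries built from posterior draws: the modal symptom grouping and
its certainty, anchor-symptom tables per group, marginal latent-class
weights, the expanded (flat-PARAFAC-equivalent) symptom profiles, and a
cause dendrogram from pairwise grouping similarity.

Profile summaries are posterior means taken without any relabeling of
latent classes across draws; cause prediction is invariant to label
switching, but these summaries are not, so a single representative draw
can be requested instead wherever that matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .gibbs import PosteriorSamples
from .metrics import adjusted_rand
from .model import SymptomDataset

__all__ = [
    "grouping_mode",
    "anchor_table",
    "marginal_class_weights",
    "expand_profiles",
    "cause_dendrogram",
]

MAX_EXPANSION = 2 ** 20


def grouping_mode(samples: PosteriorSamples) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode of the group matrix s and its assignment probability.

    Returns ``(mode, prob)``, both (C, p): the most frequent group per
    (cause, symptom) across stored draws (ties to the lowest group
    index) and its relative frequency p(s_cj = mode_cj | data).
    """
    s_draws = samples.s                     # (S, C, p)
    S, C, p = s_draws.shape
    r = samples.xi.shape[2]
    counts = np.zeros((r, C, p), dtype=np.int64)
    for g in range(r):
        counts[g] = (s_draws == g).sum(axis=0)
    mode = counts.argmax(axis=0)
    prob = counts.max(axis=0) / S
    return mode, prob


def anchor_table(
    mode: np.ndarray,
    prob: np.ndarray,
    data: SymptomDataset,
    cause: int,
    top_m: int = 5,
) -> pd.DataFrame:
    """Anchor symptoms per group for one cause.

    Within each group, symptoms assigned to it by the posterior mode are
    ordered by assignment probability (descending), ties by the
    empirical conditional frequency p(X_j = 1 | Y = cause) in the
    training data (descending), then by symptom index; only the first
    ``top_m`` are kept.  Groups are renumbered in order of decreasing
    average empirical conditional frequency over all their member
    symptoms.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    tr = data.train_index
    rows = tr[data.Y[tr] == cause]
    if rows.size:
        if data.mask is not None:
            m = data.mask[rows]
            with np.errstate(invalid="ignore"):
                emp = np.where(m.sum(0) > 0,
                               (data.X[rows] * m).sum(0) / np.maximum(m.sum(0), 1),
                               0.0)
        else:
            emp = data.X[rows].mean(axis=0)
    else:
        emp = np.zeros(data.p)

    groups_present = np.unique(mode[cause])
    mean_emp = {
        g: emp[mode[cause] == g].mean() for g in groups_present
    }
    group_order = sorted(groups_present, key=lambda g: -mean_emp[g])

    records = []
    for rank, g in enumerate(group_order):
        members = np.flatnonzero(mode[cause] == g)
        key = sorted(members,
                     key=lambda j: (-prob[cause, j], -emp[j], j))[:top_m]
        for j in key:
            records.append({
                "group": rank + 1,
                "original_group": int(g) + 1,
                "symptom": data.symptom_names[j],
                "assignment_prob": float(prob[cause, j]),
                "empirical_freq": float(emp[j]),
            })
    return pd.DataFrame.from_records(records)


def marginal_class_weights(nu_c: np.ndarray, psi_c: np.ndarray) -> np.ndarray:
    """p(Z_is = k | Y = c) = sum_l nu_cl psi_clsk, an (r, K) matrix."""
    nu_c = np.asarray(nu_c, float)
    psi_c = np.asarray(psi_c, float)
    return np.einsum("l,lsk->sk", nu_c, psi_c)


@dataclass
class ExpandedProfiles:
    """Top expanded profiles under the flat-PARAFAC-equivalent view."""

    tuples: np.ndarray    # (m, r) class index per group
    weights: np.ndarray   # (m,) joint weights, descending
    profiles: np.ndarray  # (m, p) stitched Bernoulli probabilities
    total_count: int      # K^r


def expand_profiles(
    phi_c: np.ndarray,
    s_c: np.ndarray,
    nu_c: np.ndarray,
    psi_c: np.ndarray,
    max_profiles: int | None = None,
) -> ExpandedProfiles:
    """Enumerate the K^r expanded symptom profiles for one cause.

    A class tuple (k_1..k_r) has joint weight
    ``sum_l nu_cl prod_s psi_cls,k_s`` and the stitched profile assigns
    symptom j the probability ``phi_c[k_{s_cj}, j]``.  Weights over the
    full enumeration sum to 1.  Refuses K^r beyond an enumeration budget
    unless ``max_profiles`` caps the returned list.
    """
    phi_c = np.asarray(phi_c, float)
    psi_c = np.asarray(psi_c, float)
    nu_c = np.asarray(nu_c, float)
    h, r, K = psi_c.shape
    total = K ** r
    if total > MAX_EXPANSION:
        raise ValueError(
            f"K^r = {total} expanded profiles exceed the enumeration budget "
            f"({MAX_EXPANSION}); pass max_profiles and reduce K or r, or "
            "inspect marginal_class_weights instead")

    # weights tensor: sum over l of outer products of psi rows
    w = np.zeros((K,) * r)
    for l in range(h):
        t = nu_c[l]
        acc = np.array(t)
        for sg in range(r):
            acc = np.multiply.outer(acc, psi_c[l, sg])
        w = w + acc
    flat = w.reshape(-1)

    m = total if max_profiles is None else min(max_profiles, total)
    top = np.argsort(-flat, kind="stable")[:m]
    tuples = np.stack(np.unravel_index(top, (K,) * r), axis=1)
    s_c = np.asarray(s_c, int)
    p = phi_c.shape[1]
    profiles = phi_c[tuples[:, s_c], np.arange(p)[None, :]]
    return ExpandedProfiles(tuples=tuples, weights=flat[top],
                            profiles=profiles, total_count=total)


def cause_dissimilarity(mode: np.ndarray) -> np.ndarray:
    """Pairwise 1 - ARI between the modal groupings of every cause pair.

    ARI can be negative, so entries may exceed 1; they are not clipped.
    """
    C = mode.shape[0]
    d = np.zeros((C, C))
    for a in range(C):
        for b in range(a + 1, C):
            d[a, b] = d[b, a] = 1.0 - adjusted_rand(mode[a], mode[b])
    return d


def cause_dendrogram(
    mode: np.ndarray,
    cause_names: list[str] | None = None,
    method: str = "average",
) -> tuple[np.ndarray, str]:
    """Agglomerative cause tree from grouping dissimilarity.

    Returns the scipy linkage matrix and a Newick string with cause
    names as leaves and merge heights as node depths.
    """
    C = mode.shape[0]
    if cause_names is None:
        cause_names = [f"cause_{c + 1}" for c in range(C)]
    if len(cause_names) != C:
        raise ValueError("cause_names length must match the mode matrix")
    d = cause_dissimilarity(mode)
    lk = linkage(squareform(d, checks=False), method=method)
    return lk, _linkage_to_newick(lk, cause_names)


def _linkage_to_newick(lk: np.ndarray, names: list[str]) -> str:
    tree = to_tree(lk)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
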