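"""Latent-structure summaries: modes, anchors, expansions, dendrogram."""

import numpy as np
import pytest

from vatensor import ModelConfig, SymptomDataset
from vatensor.gibbs import PosteriorSamples
from vatensor.interpret import (anchor_table, cause_dendrogram,
                                cause_dissimilarity, expand_profiles,
                                grouping_mode, marginal_class_weights)


def _samples_with_s(s_draws, r=2, K=2):
    s_draws = np.asarray(s_draws)
    S, C, p = s_draws.shape
    cfg = ModelConfig(model="grouped", K=K, r=r, n_iter=S + 1, n_burnin=0)
    return PosteriorSamples(
        model="grouped", config=cfg,
        phi=np.full((S, C, K, p), 0.5), s=s_draws,
        xi=np.full((S, C, r), 1.0 / r),
        pi0=np.full((S, C), 1.0 / C), pi1=np.full((S, C), 1.0 / C),
        y_target=np.zeros((S, 0), int),
        z_occupancy=np.full((S, r, K), 1.0 / K),
        target_index=np.arange(0),
        lam=np.full((S, C, r, K), 1.0 / K))


class TestGroupingMode:
    def test_single_draw_is_its_own_mode(self):
        s = np.array([[[0, 1, 1]]])
        mode, prob = grouping_mode(_samples_with_s(s))
        np.testing.assert_array_equal(mode, [[0, 1, 1]])
        np.testing.assert_allclose(prob, 1.0)

    def test_majority_vote_with_frequency(self):
        s = np.array([[[0, 0]], [[0, 1]], [[1, 0]]])
        mode, prob = grouping_mode(_samples_with_s(s))
        np.testing.assert_array_equal(mode, [[0, 0]])
        np.testing.assert_allclose(prob, [[2 / 3, 2 / 3]])

    def test_tie_goes_to_lowest_group(self):
        s = np.array([[[1, 0]], [[0, 1]]])
        mode, prob = grouping_mode(_samples_with_s(s))
        np.testing.assert_array_equal(mode, [[0, 0]])
        np.testing.assert_allclose(prob, 0.5)

    def test_invariant_to_draw_order(self, rng):
        s = rng.integers(0, 2, size=(9, 2, 4))
        m1, p1 = grouping_mode(_samples_with_s(s))
        m2, p2 = grouping_mode(_samples_with_s(s[::-1]))
        assert np.array_equal(m1, m2) and np.allclose(p1, p2)


class TestAnchorTable:
    def _data(self):
        X = np.array([
            [1, 1, 0, 0],
            [1, 0, 0, 0],
            [1, 1, 1, 0],
        ], dtype=np.int8)
        return SymptomDataset(
            X=X, Y=np.zeros(3, int), D=np.ones(3, int),
            symptom_names=["a", "b", "c", "d"], cause_names=["x", "y"])

    def test_orders_by_probability_then_frequency(self):
        data = self._data()
        mode = np.array([[0, 0, 1, 1], [0, 0, 0, 0]])
        prob = np.array([[0.9, 0.9, 0.8, 0.6], [1, 1, 1, 1]])
        table = anchor_table(mode, prob, data, cause=0, top_m=5)
        grp = table[table["original_group"] == 1]
        # equal probs 0.9: symptom 'a' (freq 1.0) precedes 'b' (freq 2/3)
        assert list(grp["symptom"]) == ["a", "b"]
        # groups reordered by decreasing mean empirical frequency
        assert table.iloc[0]["group"] == 1
        assert table.iloc[0]["symptom"] == "a"

    def test_truncates_to_top_m(self):
        data = self._data()
        mode = np.zeros((2, 4), int)
        prob = np.array([[0.9, 0.8, 0.7, 0.6], [1, 1, 1, 1]])
        table = anchor_table(mode, prob, data, cause=0, top_m=2)
        assert len(table) == 2
        assert list(table["symptom"]) == ["a", "b"]


class TestMarginalClassWeights:
    def test_single_upper_class_returns_psi(self, rng):
        psi = rng.dirichlet(np.ones(3), size=(1, 2))
        got = marginal_class_weights(np.array([1.0]), psi)
        np.testing.assert_allclose(got, psi[0])

    def test_uniform_nu_averages(self, rng):
        psi = rng.dirichlet(np.ones(3), size=(2, 2))
        got = marginal_class_weights(np.array([0.5, 0.5]), psi)
        np.testing.assert_allclose(got, psi.mean(axis=0))

    def test_rows_on_simplex_and_match_monte_carlo(self, rng):
        h, r, K = 3, 2, 3
        nu = rng.dirichlet(np.ones(h))
        psi = rng.dirichlet(np.ones(K), size=(h, r))
        w = marginal_class_weights(nu, psi)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        n = 40000
        hs = rng.choice(h, p=nu, size=n)
        for s in range(r):
            z = np.array([rng.choice(K, p=psi[l, s]) for l in hs[:4000]])
            emp = np.bincount(z, minlength=K) / len(z)
            assert np.abs(emp - w[s]).max() < 0.03


class TestExpandProfiles:
    def test_flat_equivalent_count(self, rng):
        nu = rng.dirichlet(np.ones(2))
        psi = rng.dirichlet(np.ones(4), size=(2, 8))
        phi = rng.uniform(size=(4, 8))
        s_c = np.repeat(np.arange(8), 1)
        out = expand_profiles(phi, s_c, nu, psi, max_profiles=10)
        assert out.total_count == 65536
        assert len(out.weights) == 10
        assert (np.diff(out.weights) <= 1e-15).all()

    def test_full_enumeration_weights_sum_to_one(self, rng):
        nu = rng.dirichlet(np.ones(2))
        psi = rng.dirichlet(np.ones(3), size=(2, 3))
        phi = rng.uniform(size=(3, 6))
        s_c = np.array([0, 0, 1, 1, 2, 2])
        out = expand_profiles(phi, s_c, nu, psi)
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert out.profiles.shape == (27, 6)

    def test_single_group_reduces_to_marginal_weights(self, rng):
        nu = rng.dirichlet(np.ones(3))
        psi = rng.dirichlet(np.ones(4), size=(3, 1))
        phi = rng.uniform(size=(4, 5))
        out = expand_profiles(phi, np.zeros(5, int), nu, psi)
        expected = marginal_class_weights(nu, psi)[0]
        np.testing.assert_allclose(np.sort(out.weights),
                                   np.sort(expected), atol=1e-12)

    def test_stitched_profile_uses_group_classes(self, rng):
        phi = np.array([[0.1, 0.2], [0.8, 0.9]])
        nu = np.array([1.0])
        psi = np.array([[[0.5, 0.5], [0.5, 0.5]]])  # h=1, r=2, K=2
        out = expand_profiles(phi, np.array([0, 1]), nu, psi)
        row = out.tuples.tolist().index([0, 1])
        np.testing.assert_allclose(out.profiles[row], [0.1, 0.9])

    def test_refuses_oversized_enumeration(self, rng):
        nu = np.ones(1)
        psi = np.full((1, 12, 8), 1 / 8)  # 8^12 tuples
        with pytest.raises(ValueError):
            expand_profiles(np.full((8, 12), 0.5), np.arange(12) % 12,
                            nu, psi)


class TestCauseDendrogram:
    def test_dissimilarity_symmetric_zero_diagonal(self, rng):
        mode = rng.integers(0, 3, size=(4, 10))
        d = cause_dissimilarity(mode)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)

    def test_identical_rows_merge_first(self):
        mode = np.array([
            [0, 0, 1, 1, 2, 2],
            [0, 0, 1, 1, 2, 2],
            [0, 1, 2, 0, 1, 2],
        ])
        lk, newick = cause_dendrogram(mode, ["a", "b", "c"])
        first = {int(lk[0, 0]), int(lk[0, 1])}
        assert first == {0, 1}
        assert lk[0, 2] == pytest.approx(0.0)
        assert newick.endswith(";") and "a" in newick

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(12)
        mode = rng.integers(0, 3, size=(5, 12))
        names = [f"c{k}" for k in range(5)]
        _, n1 = cause_dendrogram(mode, names)
        perm = [3, 1, 4, 0, 2]
        _, n2 = cause_dendrogram(mode[perm], [names[i] for i in perm])

        def clusters(newick):
            # collect leaf-name sets of every internal node
            import re
            sets = []
            stack = []
            for tok in re.findall(r"\(|\)|[^(),:;]+(?=[:,);])", newick):
                if tok == "(":
                    stack.append([])
                elif tok == ")":
                    grp = stack.pop()
                    sets.append(frozenset(grp))
                    if stack:
                        stack[-1].extend(grp)
                elif not tok.replace(".", "").replace("-", "").isdigit():
                    if stack:
                        stack[-1].append(tok)
            return set(sets)

        assert clusters(n1) == clusters(n2)

    def test_three_cause_agglomeration_matches_manual(self):
        mode = np.array([
            [0, 0, 0, 1, 1, 1],
            [0, 0, 1, 1, 1, 1],
            [0, 1, 0, 1, 0, 1],
        ])
        d = cause_dissimilarity(mode)
        lk, _ = cause_dendrogram(mode, ["a", "b", "c"])
        # closest pair merges first at its pairwise distance
        i, j = np.unravel_index(np.argmin(d + np.eye(3) * 9), d.shape)
        assert {int(lk[0, 0]), int(lk[0, 1])} == {i, j}
        assert lk[0, 2] == pytest.approx(d[i, j])
        # final merge at the average of the remaining distances
        k = ({0, 1, 2} - {i, j}).pop()
        assert lk[1, 2] == pytest.approx((d[k, i] + d[k, j]) / 2)
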