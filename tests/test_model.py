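"""Conditional symptom likelihoods and their brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vatensor import (
    ModelConfig,
    SymptomDataset,
    enumerate_joint,
    expanded_profile_count,
    loglik_ctucker,
    loglik_grouped,
    loglik_parafac,
    parameter_count,
)
from conftest import (
    all_configs,
    brute_prob_ctucker,
    brute_prob_grouped,
    brute_prob_parafac,
    random_instance,
)


class TestParafacLikelihood:
    def test_two_class_single_symptom_mixture(self):
        # 0.5 * 0.2 + 0.5 * 0.6 = 0.4 for x = 1
        ll = loglik_parafac(np.array([1.0]), np.array([[0.2], [0.6]]),
                            np.array([0.5, 0.5]))
        assert ll == pytest.approx(np.log(0.4), abs=1e-12)

    def test_single_class_is_independent_bernoulli(self, rng):
        p = 6
        phi = rng.uniform(0.1, 0.9, size=(1, p))
        x = rng.integers(0, 2, size=p).astype(float)
        expected = np.sum(x * np.log(phi[0]) + (1 - x) * np.log(1 - phi[0]))
        assert loglik_parafac(x, phi, np.array([1.0])) == pytest.approx(expected)

    def test_uninformative_profiles_ignore_weights(self, rng):
        p, K = 5, 3
        phi = np.full((K, p), 0.5)
        for _ in range(3):
            lam = rng.dirichlet(np.ones(K))
            x = rng.integers(0, 2, size=p).astype(float)
            assert loglik_parafac(x, phi, lam) == pytest.approx(p * np.log(0.5))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            loglik_parafac(np.array([1.0, 0.0]), np.array([[0.2]]),
                           np.array([1.0]))

    def test_nonfinite_parameter_raises(self):
        with pytest.raises(ValueError):
            loglik_parafac(np.array([1.0]), np.array([[np.nan]]),
                           np.array([1.0]))


class TestGroupedLikelihood:
    def test_one_group_reduces_to_parafac(self, rng):
        inst = random_instance(rng, p=5, K=3, r=1)
        x = rng.integers(0, 2, size=5).astype(float)
        a = loglik_grouped(x, inst["phi"], inst["lam"], np.zeros(5, int))
        b = loglik_parafac(x, inst["phi"], inst["lam"][0])
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_symptom_per_group_is_per_symptom_mixture(self, rng):
        p = 4
        inst = random_instance(rng, p=p, K=2, r=p)
        s_c = np.arange(p)
        x = rng.integers(0, 2, size=p).astype(float)
        expected = 0.0
        for j in range(p):
            pj = inst["phi"][:, j]
            mix = inst["lam"][j] @ (pj ** x[j] * (1 - pj) ** (1 - x[j]))
            expected += np.log(mix)
        got = loglik_grouped(x, inst["phi"], inst["lam"], s_c)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_latent_enumeration_oracle(self, rng):
        inst = random_instance(rng, p=4, K=2, r=2)
        for x in all_configs(4):
            expected = brute_prob_grouped(x, inst["phi"], inst["lam"],
                                          inst["s_c"])
            got = np.exp(loglik_grouped(x, inst["phi"], inst["lam"],
                                        inst["s_c"]))
            assert got == pytest.approx(expected, abs=1e-12)


class TestCTuckerLikelihood:
    def test_single_upper_class_reduces_to_grouped(self, rng):
        inst = random_instance(rng, p=5, K=2, r=2, h=1)
        x = rng.integers(0, 2, size=5).astype(float)
        a = loglik_ctucker(x, inst["phi"], np.array([1.0]), inst["psi"],
                           inst["s_c"])
        b = loglik_grouped(x, inst["phi"], inst["psi"][0], inst["s_c"])
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_dimensions_reduce_to_parafac(self, rng):
        inst = random_instance(rng, p=5, K=3, r=1, h=1)
        x = rng.integers(0, 2, size=5).astype(float)
        a = loglik_ctucker(x, inst["phi"], np.array([1.0]), inst["psi"],
                           np.zeros(5, int))
        b = loglik_parafac(x, inst["phi"], inst["psi"][0, 0])
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_expanded_sum_oracle(self, rng):
        inst = random_instance(rng, p=4, K=2, r=2, h=2)
        for x in all_configs(4):
            expected = brute_prob_ctucker(x, inst["phi"], inst["nu"],
                                          inst["psi"], inst["s_c"])
            got = np.exp(loglik_ctucker(x, inst["phi"], inst["nu"],
                                        inst["psi"], inst["s_c"]))
            assert got == pytest.approx(expected, abs=1e-12)


class TestEnumerateJoint:
    @pytest.mark.parametrize("p", [2, 3, 5, 7])
    def test_normalizes_for_all_models(self, rng, p):
        inst = random_instance(rng, p=p, K=2, r=2, h=2)
        for model, kw in [
            ("parafac", dict(lam_c=inst["lam_flat"])),
            ("grouped", dict(lam_c=inst["lam"], s_c=inst["s_c"])),
            ("ctucker", dict(nu_c=inst["nu"], psi_c=inst["psi"],
                             s_c=inst["s_c"])),
        ]:
            table = enumerate_joint(model, inst["phi"], **kw)
            assert table.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_class_is_product_measure(self, rng):
        p = 3
        phi = rng.uniform(0.2, 0.8, size=(1, p))
        table = enumerate_joint("parafac", phi, lam_c=np.array([1.0]))
        for b, x in enumerate(all_configs(p)):
            expected = np.prod(phi[0] ** x * (1 - phi[0]) ** (1 - x))
            assert table[b] == pytest.approx(expected, abs=1e-12)

    def test_refuses_large_p(self):
        with pytest.raises(ValueError):
            enumerate_joint("parafac", np.full((1, 17), 0.5),
                            lam_c=np.array([1.0]))


class TestNumericalContracts:
    def test_extreme_probabilities_stay_finite(self):
        phi = np.array([[1e-300, 1.0 - 1e-16, 0.0, 1.0]])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        ll = loglik_parafac(x, phi, np.array([1.0]))
        assert np.isfinite(ll)

    def test_masked_symptom_marginalizes_exactly(self, rng):
        inst = random_instance(rng, p=4, K=2, r=2, h=2)
        mask = np.array([True, True, False, True])
        x = np.array([1.0, 0.0, 0.0, 1.0])
        got = np.exp(loglik_ctucker(x, inst["phi"], inst["nu"], inst["psi"],
                                    inst["s_c"], mask=mask))
        both = 0.0
        for fill in (0.0, 1.0):
            xc = x.copy()
            xc[2] = fill
            both += np.exp(loglik_ctucker(xc, inst["phi"], inst["nu"],
                                          inst["psi"], inst["s_c"]))
        assert got == pytest.approx(both, abs=1e-12)

    def test_symptom_order_invariance(self, rng):
        inst = random_instance(rng, p=5, K=2, r=2, h=2)
        x = rng.integers(0, 2, size=5).astype(float)
        perm = rng.permutation(5)
        a = loglik_ctucker(x, inst["phi"], inst["nu"], inst["psi"],
                           inst["s_c"])
        b = loglik_ctucker(x[perm], inst["phi"][:, perm], inst["nu"],
                           inst["psi"], inst["s_c"][perm])
        assert a == pytest.approx(b, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(p=st.integers(2, 8), seed=st.integers(0, 10 ** 6))
def test_enumeration_normalizes_under_random_draws(p, seed):
    rng = np.random.default_rng(seed)
    inst = random_instance(rng, p=p, K=2, r=2, h=2)
    table = enumerate_joint("ctucker", inst["phi"], nu_c=inst["nu"],
                            psi_c=inst["psi"], s_c=inst["s_c"])
    assert table.sum() == pytest.approx(1.0, abs=1e-10)
    assert (table >= 0).all()


class TestParameterCounts:
    def test_grouped_profile_count(self):
        assert parameter_count(80, 3) == 240

    def test_expanded_equivalent_count(self):
        assert expanded_profile_count(4, 8) == 65536
        assert parameter_count(80, 4, 8, "expanded") == 80 * 65536

    def test_single_group_counts_coincide(self):
        assert parameter_count(12, 3, 1, "grouped") == \
            parameter_count(12, 3, 1, "expanded")


class TestContainers:
    def test_training_rows_require_labels(self):
        with pytest.raises(ValueError):
            SymptomDataset(
                X=np.zeros((2, 2), dtype=np.int8),
                Y=np.array([-1, 0]), D=np.array([1, 1]),
                symptom_names=["a", "b"], cause_names=["x", "y"])

    def test_non_binary_symptom_rejected(self):
        with pytest.raises(ValueError):
            SymptomDataset(
                X=np.array([[2, 0]], dtype=np.int8),
                Y=np.array([0]), D=np.array([1]),
                symptom_names=["a", "b"], cause_names=["x", "y"])

    def test_parafac_config_forces_single_group(self):
        cfg = ModelConfig(model="parafac", K=5, r=7, h=4)
        assert cfg.r == 1 and cfg.h == 1

    def test_invalid_burnin_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_iter=10, n_burnin=10)
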