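"""Association-measure correctness against brute-force pair/entropy oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rankpls as rp
from rankpls.exceptions import ConfigError, DegenerateInputWarning, InvalidInputError
from oracles import pair_counts_oracle, spearman_oracle, theil_u_oracle


def _random_ordinal_pair(rng, n_max=30):
    n = int(rng.integers(2, n_max + 1))
    x = rng.integers(1, int(rng.integers(2, 7)) + 1, n).astype(float)
    y = rng.integers(1, int(rng.integers(2, 7)) + 1, n).astype(float)
    return x, y


class TestPairCounts:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3, 4], [1, 3, 2, 4], dict(n_c=5, n_d=1, n_0=6, n_1=0, n_2=0)),
        ([1, 2, 2, 3], [1, 2, 3, 3], dict(n_c=4, n_d=0, n_0=6, n_1=1, n_2=1)),
        ([5, 5, 5], [1, 2, 3], dict(n_c=0, n_d=0, n_0=3, n_1=3, n_2=0)),
    ])
    def test_hand_enumerated_examples(self, x, y, expected):
        pc = rp.count_pairs(x, y)
        for k, v in expected.items():
            assert getattr(pc, k) == v

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            x, y = _random_ordinal_pair(rng)
            pc = rp.count_pairs(x, y)
            ref = pair_counts_oracle(x, y)
            assert pc.n_c == ref["n_c"] and pc.n_d == ref["n_d"]
            assert pc.n_1 == ref["n_1"] and pc.n_2 == ref["n_2"]
            assert pc.n_0 == ref["n_0"]

    def test_invariants(self, rng):
        for _ in range(50):
            x, y = _random_ordinal_pair(rng)
            pc = rp.count_pairs(x, y)
            n = len(x)
            assert pc.n_0 == n * (n - 1) // 2
            assert pc.n_c + pc.n_d <= pc.n_0
            assert min(pc.n_c, pc.n_d, pc.n_1, pc.n_2) >= 0

    def test_tie_free_inputs_have_no_tie_terms(self, rng):
        x = rng.permutation(12).astype(float)
        y = rng.permutation(12).astype(float)
        pc = rp.count_pairs(x, y)
        assert pc.n_1 == pc.n_2 == 0
        assert pc.n_c + pc.n_d == pc.n_0

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            rp.count_pairs([1, 2], [1, 2, 3])
        with pytest.raises(InvalidInputError):
            rp.count_pairs([1], [1])


COEFFS = {
    "rho_s": rp.spearman_rho,
    "tau_a": rp.kendall_tau_a,
    "tau_b": rp.kendall_tau_b,
    "tau_c": rp.stuart_tau_c,
    "somers_d": rp.somers_d,
    "gk_gamma": rp.gk_gamma,
    "gk_tau": rp.gk_tau,
    "theil_u": rp.theil_u,
}


class TestCoefficientValues:
    @pytest.mark.parametrize("func, x, y, expected", [
        (rp.spearman_rho, [1, 2, 3, 4], [1, 2, 3, 4], 1.0),
        (rp.spearman_rho, [1, 2, 3, 4], [4, 3, 2, 1], -1.0),
        (rp.spearman_rho, [1, 2, 3], [2, 1, 3], 0.5),
        (rp.kendall_tau_a, [1, 2, 3, 4], [1, 2, 3, 4], 1.0),
        (rp.kendall_tau_a, [1, 2, 3, 4], [1, 3, 2, 4], 4 / 6),
        (rp.kendall_tau_a, [1, 2, 2, 3], [1, 2, 3, 3], 4 / 6),
        (rp.kendall_tau_b, [1, 2, 2, 3], [1, 2, 3, 3], 0.8),
        (rp.stuart_tau_c, [1, 2, 2, 3], [1, 2, 3, 3], 0.75),
        (rp.somers_d, [1, 2, 2, 3], [1, 2, 3, 3], 0.8),
        (rp.gk_tau, [1, 2, 2, 3], [1, 2, 3, 3], 8 / 6),
        (rp.gk_gamma, [1, 2, 2, 3], [1, 2, 3, 3], 1.0),
        (rp.gk_gamma, [1, 2, 3, 4], [4, 3, 2, 1], -1.0),
    ])
    def test_hand_derivable_values(self, func, x, y, expected):
        assert func(x, y) == pytest.approx(expected, abs=1e-12)

    def test_theil_u_against_entropy_oracle_table(self):
        # joint table [[2, 1], [0, 1]] over (x, y)
        x = [0, 0, 0, 1]
        y = [0, 0, 1, 1]
        assert rp.theil_u(x, y) == pytest.approx(theil_u_oracle(x, y), abs=1e-12)
        assert rp.theil_u(x, y) == pytest.approx(0.3837, abs=1e-4)

    def test_theil_u_extremes(self):
        assert rp.theil_u([1, 2, 3, 1], [4, 5, 6, 4]) == pytest.approx(1.0)  # bijective
        assert rp.theil_u([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)  # independent

    def test_tie_free_kendall_family_coincides(self, rng):
        x = rng.permutation(15).astype(float)
        y = rng.permutation(15).astype(float)
        ta = rp.kendall_tau_a(x, y)
        assert rp.kendall_tau_b(x, y) == pytest.approx(ta, abs=1e-12)
        assert rp.somers_d(x, y) == pytest.approx(ta, abs=1e-12)
        assert rp.gk_gamma(x, y) == pytest.approx(ta, abs=1e-12)
        assert rp.gk_tau(x, y) == pytest.approx(2 * ta, abs=1e-12)

    def test_spearman_matches_pearson_of_midranks(self, rng):
        for _ in range(30):
            x, y = _random_ordinal_pair(rng)
            assert rp.spearman_rho(x, y) == pytest.approx(
                spearman_oracle(x, y), abs=1e-12
            )

    def test_spearman_scipy_crosscheck(self, rng):
        from scipy import stats
        x, y = _random_ordinal_pair(rng, n_max=25)
        assert rp.spearman_rho(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_kendall_tau_b_scipy_crosscheck(self, rng):
        from scipy import stats
        for _ in range(10):
            x, y = _random_ordinal_pair(rng, n_max=25)
            ours = rp.kendall_tau_b(x, y)
            ref = stats.kendalltau(x, y).statistic
            if np.isnan(ref):
                assert ours == 0.0
            else:
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_gk_tau_classical_range_and_extremes(self, rng):
        x, y = _random_ordinal_pair(rng)
        v = rp.gk_tau(x, y, mode="classical")
        assert 0.0 <= v <= 1.0
        z = [1, 2, 3, 1, 2, 3]
        assert rp.gk_tau(z, z, mode="classical") == pytest.approx(1.0)
        with pytest.raises(ConfigError):
            rp.gk_tau(x, y, mode="bogus")


class TestDegenerateInputs:
    @pytest.mark.parametrize("func", [
        rp.kendall_tau_b, rp.somers_d, rp.spearman_rho, rp.theil_u,
    ])
    def test_constant_first_argument_flags_and_returns_zero(self, func):
        with pytest.warns(DegenerateInputWarning):
            assert func([3, 3, 3, 3], [1, 2, 3, 4]) == 0.0

    def test_gamma_with_no_untied_pairs(self):
        # constant y: every pair tied in y, so no concordant or discordant pairs
        with pytest.warns(DegenerateInputWarning):
            assert rp.gk_gamma([1, 2, 3], [5, 5, 5]) == 0.0


class TestSymmetryProperties:
    def _asym_witness(self):
        return np.array([1.0, 2, 2, 3]), np.array([1.0, 2, 3, 3])

    @pytest.mark.parametrize("func", [
        rp.spearman_rho, rp.kendall_tau_a, rp.kendall_tau_b,
        rp.stuart_tau_c, rp.gk_gamma,
    ])
    def test_symmetric_measures(self, func, rng):
        for _ in range(20):
            x, y = _random_ordinal_pair(rng)
            assert func(x, y) == pytest.approx(func(y, x), abs=1e-12)

    def test_somers_d_asymmetry_witness(self):
        x = [1, 1, 2, 3]  # ties only in x
        y = [1, 2, 3, 4]
        assert rp.somers_d(x, y) != rp.somers_d(y, x)

    def test_theil_u_asymmetry_witness(self):
        x = [1, 1, 2, 2]
        y = [1, 2, 3, 4]  # y determines x but not conversely
        assert rp.theil_u(x, y) == pytest.approx(1.0)
        assert rp.theil_u(y, x) < 1.0

    @pytest.mark.parametrize("name, func", list(COEFFS.items()))
    def test_sign_equivariance_under_response_reversal(self, name, func, rng):
        x, y = _random_ordinal_pair(rng)
        v = func(x, y)
        v_neg = func(x, -y)
        if name == "theil_u":
            assert v_neg == pytest.approx(v, abs=1e-12)
        else:
            assert v_neg == pytest.approx(-v, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.integers(1, 5), min_size=3, max_size=20),
           st.lists(st.integers(1, 5), min_size=3, max_size=20))
    def test_monotone_relabeling_invariance(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.array(xs[:n], dtype=float)
        y = np.array(ys[:n], dtype=float)
        relabel = lambda v: v**3 + 2 * v  # strictly increasing on positives
        for func in COEFFS.values():
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateInputWarning)
                assert func(relabel(x), relabel(y)) == pytest.approx(
                    func(x, y), abs=1e-12
                )


class TestWeightVector:
    def test_identical_column_dominates(self, rng):
        y = rng.integers(1, 4, 40).astype(float)
        Z = np.column_stack([rng.integers(1, 4, 40) for _ in range(4)] + [y])
        w = rp.weight_vector(Z, y, "rho_s")
        assert np.argmax(np.abs(w)) == 4
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_standard_is_centered_cross_product_direction(self, rng):
        Z = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        w = rp.weight_vector(Z, y, "standard")
        ref = (Z - Z.mean(0)).T @ (y - y.mean())
        ref = ref / np.linalg.norm(ref)
        assert np.allclose(w, ref, atol=1e-12)

    def test_single_column_is_unit(self, rng):
        Z = rng.integers(1, 5, (30, 1)).astype(float)
        y = rng.integers(1, 4, 30).astype(float)
        w = rp.weight_vector(Z, y, "tau_b")
        assert abs(abs(w[0]) - 1.0) < 1e-12

    def test_sign_restoration_for_theil_u(self, rng):
        y = np.tile([1.0, 2, 3], 20)
        z_pos = y.copy()
        z_neg = 4 - y  # perfectly anti-monotone
        Z = np.column_stack([z_pos, z_neg])
        w = rp.weight_vector(Z, y, "theil_u")
        assert w[0] > 0 and w[1] < 0

    def test_unknown_measure_rejected(self, rng):
        with pytest.raises(ConfigError):
            rp.weight_vector(np.ones((5, 2)), np.arange(5), "nope")

    def test_degenerate_columns_get_zero_weight(self, rng):
        y = rng.integers(1, 4, 30).astype(float)
        Z = np.column_stack([np.full(30, 7.0), rng.integers(1, 4, 30)])
        w = rp.weight_vector(Z, y, "tau_b")
        assert w[0] == 0.0
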