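"""Nonparametric statistics against hand formulas, enumeration and simulation oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sp_stats

from pfcdyn.io_core import ValidationError
from pfcdyn.stats import (baseline_contrast, chi_squared_proportions, cohens_d,
                          kruskal_wallis, partial_bonferroni_factor,
                          permutation_test, posthoc_wilcoxon,
                          scheirer_ray_hare)


def srh_oracle(values, fa, fb):
    """Reference H statistics: two-way sums of squares computed from scratch on ranks."""
    r = sp_stats.rankdata(values)
    fa = np.asarray(fa)
    fb = np.asarray(fb)
    grand = r.mean()
    n = len(r)
    ss_total = np.sum((r - grand) ** 2)
    ms = ss_total / (n - 1)

    def ss(group_of):
        keys = sorted(set(group_of))
        return sum(
            np.sum(group_of == k) * (r[group_of == k].mean() - grand) ** 2
            for k in keys
        )

    ss_a = ss(fa)
    ss_b = ss(fb)
    cells = np.array([f"{x}|{y}" for x, y in zip(fa, fb)])
    ss_ab = ss(cells) - ss_a - ss_b
    return ss_a / ms, ss_b / ms, ss_ab / ms


def perm_oracle(deltas, tail):
    """Exhaustive sign-flip enumeration via itertools (independent route)."""
    deltas = np.asarray(deltas, float)
    t_obs = deltas.mean()
    stats = [np.mean(np.array(signs) * deltas)
             for signs in itertools.product((-1, 1), repeat=len(deltas))]
    stats = np.array(stats)
    if tail == "two":
        return np.mean(np.abs(stats) >= abs(t_obs) - 1e-12)
    if tail == "less":
        return np.mean(stats <= t_obs + 1e-12)
    return np.mean(stats >= t_obs - 1e-12)


class TestScheirerRayHare:
    def test_all_equal_values_give_zero_h_and_p_one(self):
        r = scheirer_ray_hare([1.0] * 12, [0, 1] * 6, [0, 0, 1, 1] * 3)
        assert all(v == 0 for v in r.statistic.values())
        assert all(p == 1.0 for p in r.p_value.values())

    def test_pure_factor_a_shift_loads_on_a(self):
        rng = np.random.default_rng(1)
        fa = np.repeat([0, 1], 40)
        fb = np.tile([0, 1], 40)
        v = rng.standard_normal(80) + 3.0 * fa
        r = scheirer_ray_hare(v, fa, fb)
        assert r.statistic["A"] > 20
        assert r.statistic["B"] < 4
        assert r.p_value["A"] < 0.001

    def test_matches_from_scratch_rank_anova_oracle(self):
        rng = np.random.default_rng(2)
        fa = np.repeat([0, 1, 2], 20)
        fb = np.tile(np.repeat([0, 1], 10), 3)
        v = rng.standard_normal(60) + 0.5 * fa - 0.3 * fb
        v[rng.integers(0, 60, 10)] = v[0]  # inject ties
        r = scheirer_ray_hare(v, fa, fb)
        ha, hb, hab = srh_oracle(v, fa, fb)
        assert r.statistic["A"] == pytest.approx(ha, abs=1e-9)
        assert r.statistic["B"] == pytest.approx(hb, abs=1e-9)
        assert r.statistic["AxB"] == pytest.approx(hab, abs=1e-9)

    def test_reduces_to_kruskal_wallis_with_constant_factor(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(30)
        v[5:10] = v[5]  # ties exercise the tie-corrected identity
        groups = np.repeat([0, 1, 2], 10)
        r = scheirer_ray_hare(v, groups, np.zeros(30))
        kw = kruskal_wallis(v, groups)
        assert r.statistic["A"] == pytest.approx(kw.statistic, abs=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(4)
        fa = np.repeat([0, 1, 2], 20)
        fb = np.tile(np.repeat([0, 1], 10), 3)
        rej = {"A": 0, "B": 0, "AxB": 0}
        n_reps = 500
        for _ in range(n_reps):
            r = scheirer_ray_hare(rng.standard_normal(60), fa, fb)
            for k in rej:
                rej[k] += r.p_value[k] < 0.05
        for k, c in rej.items():
            assert 0.02 < c / n_reps < 0.085, (k, c / n_reps)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValidationError, match="empty cell"):
            scheirer_ray_hare([1, 2, 3, 4], [0, 0, 1, 1], [0, 1, 0, 0])


class TestKruskalWallis:
    def test_hand_computable_two_group_case(self):
        r = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert r.statistic == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_give_p_near_one(self):
        r = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert r.p_value > 0.9

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestPermutationTest:
    @pytest.mark.parametrize("tail", ["two", "less", "greater"])
    def test_matches_exhaustive_enumeration(self, tail):
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.standard_normal(9)
            r = permutation_test(d, tail=tail)
            assert r.p_value == pytest.approx(perm_oracle(d, tail), abs=1e-12)

    def test_constant_negative_shift_extreme_one_tailed(self):
        d = np.full(50, -0.1)
        r = permutation_test(d, n_permutations=999, tail="less",
                             rng=np.random.default_rng(1))
        assert r.p_value == pytest.approx(1.0 / 1000.0)

    def test_all_zero_differences_flagged_p_one(self):
        r = permutation_test(np.zeros(10))
        assert r.p_value == 1.0
        assert "all differences zero" in r.flags

    def test_two_tailed_is_twice_one_tailed_for_symmetric_stat(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal(10)  # continuous: no sign-flip ties
        p_two = permutation_test(d, tail="two").p_value
        p_one = min(permutation_test(d, tail="less").p_value,
                    permutation_test(d, tail="greater").p_value)
        assert p_two == pytest.approx(min(1.0, 2 * p_one), abs=2.0 / 2 ** 10)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        ps = [permutation_test(rng.standard_normal(30), n_permutations=1999,
                               rng=rng).p_value for _ in range(500)]
        assert sp_stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            permutation_test([0.1, 0.2])


class TestChiSquared:
    def test_proportional_rows_give_near_zero(self):
        r = chi_squared_proportions([[10, 20, 30], [20, 40, 60]])
        assert r.statistic == pytest.approx(0.0, abs=1e-9)

    def test_hand_formula_two_by_two(self):
        r = chi_squared_proportions([[20, 80], [50, 50]])
        assert r.statistic == pytest.approx(19.78, abs=0.1)

    def test_posthoc_flags_only_the_differing_pair(self):
        table = [[50, 50], [50, 50], [90, 10]]
        r = chi_squared_proportions(table, condition_labels=["sal", "lo", "hi"],
                                    posthoc=True)
        assert r.p_value < 0.001
        ph = r.posthoc
        assert not ph["sal vs lo"]["significant"]
        assert ph["sal vs hi"]["significant"]
        assert ph["lo vs hi"]["significant"]
        assert r.correction["factor"] == 3

    def test_small_expected_cells_flagged(self):
        r = chi_squared_proportions([[1, 0, 9], [0, 2, 8]])
        assert any("expected" in f for f in r.flags)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_squared_proportions([[0, 0], [1, 2]])


class TestPartialBonferroni:
    def test_rank_one_data_gives_factor_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 1)) @ np.array([[1.0, -2.0, 0.5, 3.0]])
        assert partial_bonferroni_factor(X) == 1

    def test_five_orthogonal_equal_variance_columns_give_five(self):
        from scipy.linalg import hadamard
        Q = hadamard(8)[:, :5].astype(float)
        X = np.vstack([Q, -Q])  # exactly centred, equal column variance
        assert partial_bonferroni_factor(X) == 5

    @pytest.mark.parametrize("r", [2, 3, 4])
    def test_latent_factor_construction_recovers_rank(self, r):
        rng = np.random.default_rng(r)
        Z = rng.standard_normal((200, r))
        W = rng.standard_normal((r, 30))
        X = Z @ W + 1e-4 * rng.standard_normal((200, 30))
        assert partial_bonferroni_factor(X) == r

    def test_scale_invariance_with_standardisation(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 6))
        scales = np.array([1.0, 10.0, 0.1, 100.0, 5.0, 0.01])
        f1 = partial_bonferroni_factor(X, standardize=True)
        f2 = partial_bonferroni_factor(X * scales, standardize=True)
        assert f1 == f2
        assert 1 <= f1 <= 6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            partial_bonferroni_factor(np.ones((10, 3)))


class TestEffectSizesAndContrasts:
    def test_cohens_d_zero_for_equal_means(self):
        assert cohens_d([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(0.0)

    def test_cohens_d_unit_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 20000)
        b = rng.normal(0.0, 1.0, 20000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_cohens_d_simulation_recovery(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 10_000)
        b = rng.normal(-0.8, 1.0, 10_000)
        assert cohens_d(a, b) == pytest.approx(0.8, abs=0.05)

    def test_cohens_d_zero_pooled_sd_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_percent_difference_arithmetic(self):
        out = baseline_contrast([1.0], [1.2], [1.0], [1.0])
        assert out["percent_diff"] == pytest.approx(20.0)
        out = baseline_contrast([2.0], [2.4], [1.0], [1.2])
        assert out["percent_diff"] == pytest.approx(0.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            baseline_contrast([0.0], [1.0], [1.0], [1.0])

    def test_suppression_recovery(self):
        rng = np.random.default_rng(2)
        base_drug = rng.normal(10, 0.5, 200)
        post_drug = rng.normal(7, 0.5, 200)     # 30% suppression
        base_sal = rng.normal(10, 0.5, 200)
        post_sal = rng.normal(10, 0.5, 200)
        out = baseline_contrast(base_drug, post_drug, base_sal, post_sal)
        assert out["percent_diff"] == pytest.approx(-30.0, abs=3.0)


class TestPosthocWilcoxon:
    def test_identical_paired_samples_give_p_one(self):
        v = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        g = np.repeat(["x", "y"], 4)
        reports = posthoc_wilcoxon(v, g, paired=True)
        assert reports[0].p_value == 1.0

    def test_three_groups_give_three_tests_at_alpha_over_three(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(30)
        g = np.repeat(["a", "b", "c"], 10)
        reports = posthoc_wilcoxon(v, g)
        assert len(reports) == 3
        for r in reports:
            assert r.correction["alpha_corrected"] == pytest.approx(0.05 / 3)

    def test_partial_bonferroni_factor_override(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(20)
        g = np.repeat(["a", "b"], 10)
        reports = posthoc_wilcoxon(v, g, correction_factor=7)
        assert reports[0].correction["method"] == "partial_bonferroni"
        assert reports[0].correction["alpha_corrected"] == pytest.approx(0.05 / 7)
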