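"""Group statistics, t-to-Z conversion, cluster FWE, slope comparison."""

import numpy as np
import pytest
from scipy import stats

from midfc.cohort import ConnectivityDesign, SubjectRecord, simulate_zmap_cohort
from midfc.grf import estimate_smoothness
from midfc.inference import (
    cluster_fwe,
    one_sample_t,
    paired_t,
    regress_age,
    slope_difference_test,
    t_to_z,
    two_sample_t,
)


def stack(arr):
    """Wrap (n, v) voxel data as (n, v, 1, 1) map stacks."""
    arr = np.asarray(arr, dtype=float)
    return arr.reshape(*arr.shape, 1, 1)


class TestOneSampleT:
    def test_matches_direct_formula(self, rng):
        x = rng.normal(2.0, 3.0, size=(8, 5))
        out = one_sample_t(stack(x))
        expect = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(8))
        np.testing.assert_allclose(out.stat[:, 0, 0], expect, atol=1e-10)
        assert out.df == 7

    def test_antisymmetric_data_gives_zero(self, rng):
        x = rng.standard_normal((4, 6))
        out = one_sample_t(stack(np.vstack([x, -x])))
        np.testing.assert_allclose(out.stat[:, 0, 0], 0.0, atol=1e-12)

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 3"):
            one_sample_t(stack(rng.standard_normal((2, 4))))

    def test_zero_variance_voxel_warns(self):
        x = np.ones((5, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = one_sample_t(stack(x))
        assert np.all(out.stat == 0.0)


class TestPairedT:
    def test_equals_one_sample_on_differences(self, rng):
        a = rng.standard_normal((6, 7))
        b = rng.standard_normal((6, 7))
        np.testing.assert_allclose(paired_t(stack(a), stack(b)).stat,
                                   one_sample_t(stack(a - b)).stat,
                                   atol=1e-12)

    def test_identical_inputs_give_zero_everywhere(self, rng):
        a = rng.standard_normal((5, 4))
        with pytest.warns(UserWarning):
            out = paired_t(stack(a), stack(a))
        np.testing.assert_array_equal(out.stat[:, 0, 0], 0.0)

    def test_antisymmetry(self, rng):
        a = rng.standard_normal((6, 7))
        b = rng.standard_normal((6, 7))
        np.testing.assert_allclose(paired_t(stack(a), stack(b)).stat,
                                   -paired_t(stack(b), stack(a)).stat,
                                   atol=1e-12)

    def test_subject_mismatch_listed(self):
        from midfc.connectivity import SubjectZMap
        eye = np.eye(4)
        za = [SubjectZMap(np.zeros((2, 2, 2)), "VTA", f"s{i}", 100, eye)
              for i in range(3)]
        zb = [SubjectZMap(np.zeros((2, 2, 2)), "SNc", f"x{i}", 100, eye)
              for i in range(3)]
        with pytest.raises(ValueError, match="mismatch"):
            paired_t(za, zb)


class TestTwoSampleT:
    def test_matches_pooled_oracle(self, rng):
        a = rng.normal(1.0, 2.0, size=(4, 6))
        b = rng.normal(0.0, 2.0, size=(4, 6))
        out = two_sample_t(stack(a), stack(b))
        expect = stats.ttest_ind(a, b, axis=0, equal_var=True).statistic
        np.testing.assert_allclose(out.stat[:, 0, 0], expect, atol=1e-10)
        assert out.df == 6

    def test_identical_groups_give_zero(self, rng):
        a = rng.standard_normal((4, 5))
        out = two_sample_t(stack(a), stack(a.copy()))
        np.testing.assert_allclose(out.stat[:, 0, 0], 0.0, atol=1e-12)

    def test_swapping_groups_flips_sign(self, rng):
        a = rng.standard_normal((4, 5))
        b = rng.standard_normal((5, 5))
        np.testing.assert_allclose(two_sample_t(stack(a), stack(b)).stat,
                                   -two_sample_t(stack(b), stack(a)).stat,
                                   atol=1e-12)

    def test_tiny_group_rejected(self, rng):
        with pytest.raises(ValueError):
            two_sample_t(stack(rng.standard_normal((1, 3))),
                         stack(rng.standard_normal((4, 3))))


class TestRegressAge:
    def test_exact_linear_relation_recovered(self):
        ages = np.array([20.0, 25.0, 31.0, 38.0, 44.0, 49.0])
        z = 0.01 * ages + 0.2
        out = regress_age(stack(z[:, None]), ages)
        # noise-free fit: slope t is huge and positive
        assert out.stat[0, 0, 0] > 1e5

    def test_matches_ols_oracle(self, rng):
        import statsmodels.api as sm
        ages = rng.uniform(18, 49, 20)
        z = rng.standard_normal((20, 3))
        out = regress_age(stack(z), ages)
        for v in range(3):
            fit = sm.OLS(z[:, v], sm.add_constant(ages)).fit()
            assert out.stat[v, 0, 0] == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert out.df == 18

    def test_subject_permutation_invariance(self, rng):
        ages = rng.uniform(18, 49, 12)
        z = rng.standard_normal((12, 4))
        perm = rng.permutation(12)
        np.testing.assert_allclose(regress_age(stack(z), ages).stat,
                                   regress_age(stack(z[perm]), ages[perm]).stat,
                                   atol=1e-10)

    def test_subgroup_selection(self, rng):
        ages = rng.uniform(18, 49, 10)
        z = rng.standard_normal((10, 2))
        sel = np.arange(10) < 6
        np.testing.assert_allclose(
            regress_age(stack(z), ages, select=sel).stat,
            regress_age(stack(z[sel]), ages[sel]).stat, atol=1e-12)

    def test_constant_ages_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            regress_age(stack(rng.standard_normal((5, 2))), np.full(5, 30.0))


class TestTToZ:
    def test_zero_maps_to_zero(self, rng):
        out = one_sample_t(stack(np.vstack([rng.standard_normal((3, 4))] ) ))
        tmap = one_sample_t(stack(np.vstack([[1., -1, 0.5], [-1, 1, -0.5],
                                             [1., -1, 0.5], [-1, 1, -0.5]])))
        z = t_to_z(tmap)
        idx = tmap.stat == 0.0
        assert np.all(z.stat[idx] == 0.0)

    def test_high_df_limit(self):
        from midfc.inference import GroupStatMap
        t = np.full((1, 1, 1), 1.96)
        m = GroupStatMap(stat=t, stat_type="t", df=1e6, contrast="x", n=2,
                         mask=np.ones((1, 1, 1), bool))
        assert t_to_z(m).stat[0, 0, 0] == pytest.approx(1.96, abs=1e-3)

    def test_monotone_in_t(self):
        from midfc.inference import GroupStatMap
        t = np.linspace(-9, 9, 41).reshape(-1, 1, 1)
        m = GroupStatMap(stat=t, stat_type="t", df=15, contrast="x", n=16,
                         mask=np.ones(t.shape, bool))
        z = t_to_z(m).stat.ravel()
        assert np.all(np.diff(z) > 0)

    def test_requires_t_input(self):
        from midfc.inference import GroupStatMap
        m = GroupStatMap(stat=np.zeros((2, 2, 2)), stat_type="Z", df=10,
                         contrast="x", n=11, mask=np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError, match="t map"):
            t_to_z(m)


class TestClusterFwe:
    def make_records(self, n):
        return [SubjectRecord(f"s{i:03d}", 30.0, "female", "Yale", 2.0, 200)
                for i in range(n)]

    def test_planted_focal_effect_detected(self):
        # Cohen's d = 1.5 in a compact blob, 30 subjects: the cluster
        # survives FWE correction in every repeat
        shape = (20, 22, 20)
        target = np.zeros(shape, bool)
        target[8:12, 9:13, 8:12] = True
        design = ConnectivityDesign(base_rho=np.tanh(0.15),
                                    target_region=target)
        records = self.make_records(30)
        hits = 0
        for rep in range(10):
            maps = simulate_zmap_cohort(records, design, shape,
                                        seed=1000 + rep, noise_sd=0.1)
            stat = one_sample_t(maps)
            clusters = cluster_fwe(stat, forming_p=0.001, alpha=0.05)
            hit = any(c["sign"] > 0 and target[c["peak_ijk"]]
                      for c in clusters)
            hits += hit
        assert hits >= 9

    def test_empty_result_without_suprathreshold_voxels(self):
        records = self.make_records(10)
        design = ConnectivityDesign(base_rho=0.0, target_region=None)
        maps = simulate_zmap_cohort(records, design, (14, 14, 14), seed=5,
                                    noise_sd=0.05)
        stat = one_sample_t(maps * 0.01)
        assert cluster_fwe(stat, forming_p=1e-6, alpha=0.05) == []

    def test_invalid_thresholds_rejected(self, rng):
        stat = one_sample_t(stack(rng.standard_normal((5, 4))))
        with pytest.raises(ValueError):
            cluster_fwe(stat, forming_p=0.0, alpha=0.05,
                        smoothness=None)


class TestSlopeDifference:
    def test_alternating_relabel_not_significant(self):
        # the same age-z relation alternately labeled male/female: the two
        # fitted slopes coincide, so the difference statistic vanishes
        ages = np.tile(np.linspace(20, 48, 8), 2)
        z = 0.01 * ages + 0.2
        sex = np.array(["male", "female"] * 8)
        res = slope_difference_test(z, ages, sex)
        assert res.slope_men == pytest.approx(res.slope_women, abs=1e-12)
        assert not res.significant

    def test_noise_free_separation_is_significant(self):
        ages = np.array([20, 25, 30, 35, 40, 45.0] * 2)
        sex = np.array(["male"] * 6 + ["female"] * 6)
        z = np.where(sex == "male", 0.02 * ages, 0.0)
        res = slope_difference_test(z, ages, sex)
        assert res.significant
        assert res.p < 1e-12
        assert res.slope_men == pytest.approx(0.02, abs=1e-12)
        assert res.slope_women == pytest.approx(0.0, abs=1e-12)

    def test_matches_interaction_model_oracle(self, rng):
        # the two-separate-lines t equals the age-by-sex interaction t in
        # a full linear model with separate intercepts and slopes
        import statsmodels.api as sm
        n = 12
        ages = rng.uniform(18, 49, n)
        sex = np.array(["male"] * 6 + ["female"] * 6)
        z = rng.standard_normal(n)
        male = (sex == "male").astype(float)
        X = np.column_stack([np.ones(n), ages, male, ages * male])
        fit = sm.OLS(z, X).fit()
        res = slope_difference_test(z, ages, sex)
        assert res.t == pytest.approx(fit.tvalues[3], abs=1e-10)
        assert res.df == n - 4
        assert res.p == pytest.approx(fit.pvalues[3], abs=1e-10)

    def test_bonferroni_threshold(self, rng):
        ages = rng.uniform(18, 49, 20)
        sex = np.array(["male", "female"] * 10)
        res = slope_difference_test(rng.standard_normal(20), ages, sex,
                                    n_tests=12)
        assert res.alpha_corrected == pytest.approx(0.05 / 12)

    def test_small_sex_group_rejected(self, rng):
        ages = np.array([20.0, 30, 40, 25])
        sex = np.array(["male", "female", "female", "female"])
        with pytest.raises(ValueError, match="3 subjects"):
            slope_difference_test(rng.standard_normal(4), ages, sex)
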