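import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fishhealth.errors import InsufficientDataError, ValidationError
from fishhealth.stats import (
    compare_k_groups,
    compare_two_groups,
    mlr_backward_aic,
    partial_spearman,
    pca,
    spearman_matrix,
)


def mw_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating every rank split."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_obs = min(u_obs, n1 * len(y) - u_obs)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        u = min(u, n1 * len(y) - u)
        total += 1
        if u <= u_obs + 1e-9:
            count += 1
    return count / total


class TestTwoGroups:
    def test_forced_nonparametric_small_sample_exact(self):
        res = compare_two_groups([1, 2, 3], [4, 5, 6], force="nonparametric")
        assert res.test_name == "mann_whitney_u"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 rank splits

    def test_identical_groups_not_significant(self):
        res = compare_two_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert not res.significant
        assert res.p_value > 0.9

    def test_large_normal_samples_take_parametric_route(self, rng):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        res = compare_two_groups(list(x), list(y))
        assert res.test_name == "student_t"
        assert res.p_value > 0.001
        assert "ks_normal=True" in res.decision_path

    def test_skewed_data_takes_nonparametric_route(self, rng):
        x = rng.lognormal(0, 1.5, 150)
        y = rng.lognormal(0.2, 1.5, 150)
        res = compare_two_groups(list(x), list(y))
        assert res.test_name == "mann_whitney_u"

    def test_exact_p_matches_enumeration_for_small_n(self, rng):
        for _ in range(5):
            x = rng.permutation(np.arange(1.0, 11.0))[:4]
            y = np.setdiff1d(np.arange(1.0, 11.0), x)[:5]
            res = compare_two_groups(list(x), list(y), force="nonparametric")
            assert res.p_value == pytest.approx(mw_exact_oracle(x, y), abs=1e-9)

    def test_too_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_two_groups([1, 2], [3, 4, 5])


class TestKGroups:
    def test_three_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = compare_k_groups([g, g, g])
        assert res.p_value > 0.99

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        groups = [list(rng.normal(0, 1, 50)), list(rng.normal(0, 1, 50)),
                  list(rng.normal(3, 1, 50))]
        assert compare_k_groups(groups).p_value < 0.001

    def test_constant_groups_force_kruskal_at_maximum(self):
        res = compare_k_groups([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
        assert res.test_name == "kruskal_wallis"
        # H reaches its tie-corrected maximum of 8 for n = 9 in 3 blocks
        assert res.statistic == pytest.approx(8.0)


class TestSpearman:
    def test_monotone_transform_preserves_rho(self, rng):
        x = rng.normal(0, 1, 50)
        table = pd.DataFrame({"x": x, "y": x**3, "z": -x})
        rho, _ = spearman_matrix(table)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["x", "z"] == pytest.approx(-1.0)

    def test_allometric_cohort_length_weight_correlated(self):
        # cubic allometry with small multiplicative noise across a wide
        # length range: ranks of W track ranks of L almost perfectly
        from fishhealth.model import Season, SpeciesSeasonProfile
        from fishhealth.synthetic import GeneratorConfig, generate_cohort

        prof = SpeciesSeasonProfile(
            species="Wide", season=Season.RAINY, trophic_level=4.0, n=400,
            mean_length_cm=40.0, se_length_cm=0.5, mean_weight_g=700.0,
            se_weight_g=10.0, mean_cf=1.0, se_cf=0.01, mean_hsi=1.0,
            se_hsi=0.05, mean_thg_ugg=0.3, se_thg_ugg=0.003,
            prevalence=0.5, mean_intensity=3.0)
        cohort = generate_cohort(GeneratorConfig(
            profiles=[prof], sigma_log_weight=0.05, seed=61))
        table = pd.DataFrame({
            "L": [s.length_cm for s in cohort],
            "W": [s.weight_g for s in cohort],
        })
        rho, p = spearman_matrix(table)
        assert rho.loc["L", "W"] > 0.85
        assert p.loc["L", "W"] < 1e-10

    def test_constant_variable_reported_absent(self):
        table = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "c": [7.0] * 5})
        rho, _ = spearman_matrix(table)
        assert np.isnan(rho.loc["x", "c"])
        assert rho.loc["x", "x"] == 1.0

    def test_pairwise_complete_handling(self):
        table = pd.DataFrame({
            "x": [1.0, 2, 3, 4, 5, np.nan],
            "y": [2.0, 4, 6, 8, 10, 12],
        })
        rho, _ = spearman_matrix(table)
        assert rho.loc["x", "y"] == pytest.approx(1.0)


class TestPartialSpearman:
    def test_identical_series_fully_correlated(self, rng):
        x = rng.normal(0, 1, 100)
        z = rng.normal(0, 1, 100)
        rho, p = partial_spearman(x, x.copy(), z)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_independent_triple_near_zero(self):
        rng = np.random.default_rng(9)
        rho, _ = partial_spearman(rng.normal(0, 1, 2000),
                                  rng.normal(0, 1, 2000),
                                  rng.normal(0, 1, 2000))
        assert abs(rho) < 0.05

    def test_confounded_pair_vanishes_after_control(self):
        rng = np.random.default_rng(17)
        z = rng.normal(0, 1, 2000)
        x = z + rng.normal(0, 0.3, 2000)
        y = z + rng.normal(0, 0.3, 2000)
        raw, _ = partial_spearman(x, y, rng.normal(0, 1, 2000))
        controlled, _ = partial_spearman(x, y, z)
        assert raw > 0.8
        assert abs(controlled) < 0.1

    def test_degenerate_control_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValidationError):
            partial_spearman(x, np.ones(10), x)


class TestPca:
    def test_perfectly_correlated_pair_loads_on_pc1(self, rng):
        x = rng.normal(0, 1, 100)
        res = pca(pd.DataFrame({"a": x, "b": 3 * x}))
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_independent_variables_split_variance_evenly(self):
        rng = np.random.default_rng(23)
        table = pd.DataFrame(rng.normal(0, 1, size=(5000, 4)),
                             columns=list("abcd"))
        res = pca(table)
        assert np.all(np.abs(res.explained_fraction - 0.25) < 0.03)

    def test_variance_conservation_and_orthonormal_loadings(self, default_cohort):
        table = pd.DataFrame({
            "L": [s.length_cm for s in default_cohort],
            "W": [s.weight_g for s in default_cohort],
            "Hg": [s.thg_ugg for s in default_cohort],
            "A": [s.parasite_count for s in default_cohort],
            "TL": [s.trophic_level for s in default_cohort],
        })
        res = pca(table)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        V = res.loadings.to_numpy()
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)

    def test_sign_flip_of_variable_keeps_explained_variance(self, rng):
        x = rng.normal(0, 1, size=(200, 3))
        t1 = pd.DataFrame(x, columns=list("abc"))
        t2 = t1.copy()
        t2["b"] = -t2["b"]
        f1 = pca(t1).explained_fraction
        f2 = pca(t2).explained_fraction
        assert np.allclose(f1, f2, atol=1e-12)


class TestBackwardAic:
    def test_exact_linear_function_recovered(self, rng):
        x1, x2 = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
        y = 2.0 + 3.0 * x1 - 1.5 * x2
        table = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        path, best = mlr_backward_aic(table, "y", ["x1", "x2"])
        assert best.coefficients["x1"] == pytest.approx(3.0, abs=1e-8)
        assert best.coefficients["x2"] == pytest.approx(-1.5, abs=1e-8)
        assert best.adjusted_r2 == pytest.approx(1.0, abs=1e-10)

    def test_path_aic_monotone_nonincreasing(self, default_cohort):
        table = pd.DataFrame({
            "A": [float(s.parasite_count) for s in default_cohort],
            "Hg": [s.thg_ugg for s in default_cohort],
            "CF": [100 * s.weight_g / s.length_cm**3 for s in default_cohort],
            "TL": [s.trophic_level for s in default_cohort],
        })
        path, best = mlr_backward_aic(table, "A", ["Hg", "CF", "TL"])
        aics = [f.aic for f in path]
        assert all(a >= b for a, b in zip(aics, aics[1:]))
        assert best.aic == min(aics)

    def test_pure_noise_candidates_mostly_eliminated(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            table = pd.DataFrame(rng.normal(0, 1, size=(150, 4)),
                                 columns=["y", "a", "b", "c"])
            _, best = mlr_backward_aic(table, "y", ["a", "b", "c"])
            if len(best.terms) == 0:
                wins += 1
        assert wins >= 10  # intercept-only wins for the majority of seeds

    def test_collinear_terms_rejected_by_name(self, rng):
        x = rng.normal(0, 1, 50)
        table = pd.DataFrame({"y": rng.normal(0, 1, 50), "a": x, "b": 2 * x})
        with pytest.raises(ValidationError, match="collinear"):
            mlr_backward_aic(table, "y", ["a", "b"])
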