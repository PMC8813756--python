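import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from placentadeconv import (
    CohortConfig,
    bonferroni,
    ga_sex_associations,
    generate_cohort,
    global_rank_manova,
    paired_celltype_tests,
    relative_effects,
    sample_phenotypes,
    sample_proportions,
    signed_rank_z,
    spearman_associations,
)


def _props(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"c{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=cols)


class TestSpearman:
    def test_self_correlation_is_one(self, rng):
        A = _props(rng.random((20, 2)))
        res = spearman_associations(A, A)
        assert res.rho.iloc[0, 0] == pytest.approx(1.0)

    def test_perfect_antitone(self):
        A = _props(np.array([[1], [2], [3], [4], [5]], dtype=float))
        B = _props(np.array([[5], [4], [3], [2], [1]], dtype=float))
        res = spearman_associations(A, B)
        assert res.rho.iloc[0, 0] == pytest.approx(-1.0)

    def test_tied_values_match_manual_midrank_pearson(self):
        """Six points with ties equal the mid-rank Pearson computed by hand."""
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([10.0, 9.0, 7.0, 7.0, 5.0, 1.0])
        res = spearman_associations(_props(x[:, None]), _props(y[:, None]))
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert res.rho.iloc[0, 0] == pytest.approx(manual, abs=1e-12)

    def test_matches_scipy_for_small_n(self, rng):
        for n in (6, 8):
            x = rng.random(n)
            y = rng.random(n)
            res = spearman_associations(_props(x[:, None]), _props(y[:, None]))
            sp = stats.spearmanr(x, y)
            assert res.rho.iloc[0, 0] == pytest.approx(sp.statistic, abs=1e-12)
            assert res.p_raw.iloc[0, 0] == pytest.approx(sp.pvalue, abs=1e-9)

    def test_bonferroni_is_pure_scaling(self):
        p = np.array([0.001, 0.5, 0.9])
        np.testing.assert_allclose(bonferroni(p, 12), np.minimum(1, p * 12))


class TestPairedSignedRank:
    def test_identical_matrices_null(self):
        p1 = _props(np.random.default_rng(0).dirichlet([2, 2, 2], size=10))
        res = paired_celltype_tests(p1, p1.copy())
        assert (res.table["Z"] == 0).all()
        assert (res.table["p_raw"] == 1).all()

    def test_exact_enumeration_n6_all_positive(self):
        """Six strictly positive differences: one-sided exact p = 1/64.

        The two-sided normal-approximation p must agree with the exhaustive
        two-sided sign-flip enumeration to within the approximation's error.
        """
        d = np.array([0.3, 0.5, 0.2, 0.4, 0.6, 0.1])
        z, p_norm, n = signed_rank_z(d)
        assert n == 6 and z > 0
        # exhaustive null: all 2^6 sign assignments of |d| ranks
        r = stats.rankdata(np.abs(d))
        w_obs = r[d > 0].sum()
        ws = [sum(r[i] for i in range(6) if signs[i]) for signs in
              itertools.product([0, 1], repeat=6)]
        mu = np.mean(ws)
        p_exact_two = np.mean([abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in ws])
        assert np.mean([w >= w_obs for w in ws]) == pytest.approx(1 / 64)
        assert p_norm == pytest.approx(p_exact_two, abs=0.035)

    def test_enumeration_n8_random_signs(self, rng):
        """Normal-approximation p tracks the exact enumeration for n = 8."""
        d = rng.normal(0.05, 0.2, 8)
        d = d[d != 0]
        z, p_norm, _ = signed_rank_z(d)
        r = stats.rankdata(np.abs(d))
        w_obs = r[d > 0].sum()
        n = len(d)
        ws = np.array([sum(r[i] for i in range(n) if s[i]) for s in
                       itertools.product([0, 1], repeat=n)])
        mu = ws.mean()
        p_exact = np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12)
        assert p_norm == pytest.approx(p_exact, abs=0.05)

    def test_misaligned_samples_rejected(self):
        p1 = _props(np.full((8, 2), 0.5))
        p2 = p1.copy()
        p2.index = [f"t{i}" for i in range(8)]
        with pytest.raises(ValueError, match="aligned"):
            paired_celltype_tests(p1, p2)

    def test_synthetic_cvs_to_term_directions(self):
        """CVS->term composition change reproduces the expected signs.

        Trophoblasts and stromal cells fall from first trimester to term
        while syncytiotrophoblasts rise.
        """
        n = 85
        cvs_cfg = CohortConfig(n_samples=n, study_preset="CVS-ITU", seed=1)
        term_cfg = CohortConfig(n_samples=n, study_preset="term-ITU", seed=2)
        ph = sample_phenotypes(cvs_cfg, 1)
        p1 = sample_proportions(cvs_cfg, ph, 3)
        p2 = sample_proportions(term_cfg, ph, 4)
        p2.index = p1.index
        res = paired_celltype_tests(p1, p2)
        diff = res.table["median_difference_pct"]
        assert diff["Trophoblasts"] > 0  # higher in CVS
        assert diff["Stromal"] > 0
        assert diff["Syncytiotrophoblasts"] < 0  # rises toward term
        sig = res.table["p_bonferroni"]
        for ct in ("Trophoblasts", "Stromal", "Syncytiotrophoblasts"):
            assert sig[ct] < 0.01


class TestRelativeEffects:
    def test_identical_groups_half(self):
        vals = np.tile(np.linspace(0.1, 0.9, 10)[:, None], (2, 1))
        props = _props(vals)
        groups = ["a"] * 10 + ["b"] * 10
        eff = relative_effects(props, groups)
        np.testing.assert_allclose(eff.to_numpy(), 0.5)

    def test_dominant_group_hand_value(self):
        """n_A = n_B = 3, A all larger: mid-rank formula gives 0.75 / 0.25."""
        props = _props(np.array([[0.9], [0.8], [0.7], [0.3], [0.2], [0.1]]))
        eff = relative_effects(props, ["A", "A", "A", "B", "B", "B"])
        assert eff.loc["A"].iloc[0] == pytest.approx(0.75)
        assert eff.loc["B"].iloc[0] == pytest.approx(0.25)

    def test_weighted_mean_exactly_half(self, rng):
        props = _props(rng.random((30, 4)))
        groups = rng.choice(["x", "y", "z"], size=30, p=[0.5, 0.3, 0.2])
        eff = relative_effects(props, groups)
        sizes = pd.Series(groups).value_counts()
        for ct in props.columns:
            wm = sum(eff.loc[g, ct] * sizes[g] for g in eff.index) / 30
            assert wm == pytest.approx(0.5, abs=1e-12)


class TestGlobalRankTest:
    def test_identical_groups_degenerate(self):
        props = _props(np.tile([[0.5, 0.5]], (12, 1)))
        res = global_rank_manova(props, ["a"] * 6 + ["b"] * 6, n_permutations=99, seed=0)
        assert res.anova_type_statistic == 0.0
        assert res.p_permutation == 1.0

    def test_separated_groups_significant(self, rng):
        a = rng.dirichlet([20, 5], size=20)
        b = rng.dirichlet([5, 20], size=20)
        props = _props(np.vstack([a, b]))
        res = global_rank_manova(props, ["a"] * 20 + ["b"] * 20, n_permutations=199, seed=1)
        assert res.p_permutation <= 0.01

    def test_small_group_rejected(self):
        props = _props(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError, match=">= 3"):
            global_rank_manova(props, ["a", "a", "a", "b", "b"])

    def test_permutation_p_in_valid_range(self, rng):
        props = _props(rng.random((18, 3)))
        res = global_rank_manova(props, ["a", "b", "c"] * 6, n_permutations=99, seed=2)
        assert 1 / 100 <= res.p_permutation <= 1.0


class TestGASexAssociations:
    def test_ga_trend_detected(self):
        cfg = CohortConfig(n_samples=1000, study_preset="CVS-ITU", ga_effect_size=0.02, seed=8)
        ph = sample_phenotypes(cfg, 8)
        props = sample_proportions(cfg, ph, 9)
        res = ga_sex_associations(props, ph)
        t = res.table
        assert t.loc["Trophoblasts", "ga_rho"] < 0
        assert t.loc["Syncytiotrophoblasts", "ga_rho"] > 0
        assert t.loc["Trophoblasts", "ga_p_bonferroni"] < 0.01
        assert t.loc["Syncytiotrophoblasts", "ga_p_bonferroni"] < 0.01

    def test_null_ga_mostly_clean(self):
        """Without a GA effect, Bonferroni-adjusted associations stay quiet."""
        hits = 0
        for seed in range(10):
            cfg = CohortConfig(n_samples=200, study_preset="CVS-ITU",
                               ga_effect_size=0.0, seed=100 + seed)
            ph = sample_phenotypes(cfg, 200 + seed)
            props = sample_proportions(cfg, ph, 300 + seed)
            res = ga_sex_associations(props, ph)
            hits += int((res.table["ga_p_bonferroni"] <= 0.01).any())
        assert hits <= 1

    def test_no_sex_effect_in_proportions(self):
        """Sex never enters the composition model, so no sex association appears."""
        cfg = CohortConfig(n_samples=1000, study_preset="CVS-ITU", seed=12)
        ph = sample_phenotypes(cfg, 12)
        props = sample_proportions(cfg, ph, 13)
        res = ga_sex_associations(props, ph)
        assert (res.table["sex_p_bonferroni"] > 0.01).all()
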