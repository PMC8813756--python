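import numpy as np
import pandas as pd
import pytest

from placentadeconv import (
    adjusted_r2,
    build_model_matrix,
    default_model_specs,
    high_r2_intersection,
    per_cpg_r2,
    repeated_cv,
)
from placentadeconv.model_selection import MODEL_NAMES, ModelSpec


@pytest.fixture(scope="module")
def toy_inputs(small_cohort):
    from placentadeconv import deconvolve_cohort, reffree_factorize

    rb = deconvolve_cohort(small_cohort.betas, small_cohort.reference, "rpc").proportions
    rf = reffree_factorize(small_cohort.betas, 3, n_top_variable_cpgs=150, seed=0).Omega
    return rb, rf, small_cohort.phenotypes


class TestModelMatrix:
    def test_intercept_only(self, toy_inputs):
        rb, rf, ph = toy_inputs
        X = build_model_matrix(ModelSpec("intercept"), rb, rf, ph)
        assert list(X.columns) == ["intercept"]
        assert (X["intercept"] == 1.0).all()

    def test_ref_based_drops_one_simplex_column(self, toy_inputs):
        rb, rf, ph = toy_inputs
        X = build_model_matrix(ModelSpec("ref_based", uses_ref_based=True), rb, rf, ph)
        assert X.shape[1] == 1 + 5  # intercept + (6 - 1) cell types
        # the most abundant type is the dropped baseline
        assert "rb_Syncytiotrophoblasts" not in X.columns

    def test_full_model_column_count(self, toy_inputs):
        rb, rf, ph = toy_inputs
        spec = ModelSpec("ref_based+phenotypes", uses_ref_based=True, uses_phenotypes=True)
        X = build_model_matrix(spec, rb, rf, ph)
        n_anc = sum(c.startswith("ancestry") for c in ph.columns)
        assert X.shape[1] == 1 + 5 + 1 + 1 + n_anc

    def test_six_canonical_specs(self):
        assert tuple(s.name for s in default_model_specs()) == MODEL_NAMES


class TestRepeatedCV:
    def test_known_linear_truth_wins(self, toy_inputs):
        """Outcome built from reference-based proportions is won by that family."""
        rb, rf, ph = toy_inputs
        rng = np.random.default_rng(1)
        w = rng.normal(0, 30, rb.shape[1])
        y0 = rb.to_numpy() @ w
        y = pd.Series(y0 + rng.normal(0, 0.01 * np.ptp(y0), len(y0)), index=rb.index)
        designs = {s.name: build_model_matrix(s, rb, rf, ph) for s in default_model_specs()}
        cv = repeated_cv(y, designs, folds=5, repeats=30, seed=2)
        fam = cv.win_proportions["ref_based"] + cv.win_proportions["ref_based+phenotypes"]
        assert fam >= 0.8
        assert cv.winner_adjusted_r2 > 0.95

    def test_intercept_rmse_approximates_sd(self, rng):
        """Intercept-only out-of-sample RMSE estimates the outcome's SD."""
        y = pd.Series(rng.normal(0, 2.0, 300), index=[f"s{i}" for i in range(300)])
        X = pd.DataFrame({"intercept": 1.0}, index=y.index)
        cv = repeated_cv(y, {"intercept": X}, folds=10, repeats=20, seed=0)
        assert abs(cv.mean_rmse["intercept"] - y.std()) / y.std() < 0.05

    def test_duplicate_specs_split_by_tie_rule(self, rng):
        y = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=60)}, index=y.index)
        cv = repeated_cv(y, {"first": X, "second": X.copy()}, folds=5, repeats=10, seed=1)
        assert int(cv.wins["first"]) == 10 and int(cv.wins["second"]) == 0
        assert int(cv.wins.sum()) == 10

    def test_shared_partitions_across_models(self, monkeypatch, rng):
        """Every model in a repeat sees the identical fold partition."""
        import placentadeconv.model_selection as ms

        calls = []
        orig = ms._fold_indices

        def spy(n, folds, rng_):
            out = orig(n, folds, rng_)
            calls.append([a.copy() for a in out])
            return out

        monkeypatch.setattr(ms, "_fold_indices", spy)
        y = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        X1 = pd.DataFrame({"intercept": 1.0}, index=y.index)
        X2 = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=40)}, index=y.index)
        ms.repeated_cv(y, {"a": X1, "b": X2}, folds=4, repeats=3, seed=5)
        assert len(calls) == 3  # one partition per repeat, reused by both models

    def test_rmse_shape_and_win_conservation(self, toy_inputs):
        rb, rf, ph = toy_inputs
        y = pd.Series(np.arange(len(rb), dtype=float), index=rb.index)
        designs = {s.name: build_model_matrix(s, rb, rf, ph) for s in default_model_specs()}
        cv = repeated_cv(y, designs, folds=5, repeats=8, seed=3)
        assert cv.rmse.shape == (8, 6)
        assert int(cv.wins.sum()) == 8
        assert abs(cv.win_proportions.sum() - 1) < 1e-12


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        X = pd.DataFrame({"intercept": 1.0, "x": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        assert adjusted_r2(y, X) == pytest.approx(1.0)

    def test_intercept_only_is_zero(self, rng):
        y = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)])
        X = pd.DataFrame({"intercept": 1.0}, index=y.index)
        assert adjusted_r2(y, X) == pytest.approx(0.0, abs=1e-12)

    def test_hand_solved_six_points(self):
        """Simple regression on six points, solved by hand.

        x = (0,1,2,3,4,5), y = (1,1,2,2,4,5): slope = Sxy/Sxx = 14.5/17.5,
        R^2 = slope*Sxy/Syy = (14.5^2/17.5)/12.833..., adj = 1-(1-R^2)*5/4.
        """
        x = np.arange(6.0)
        y = pd.Series([1.0, 1.0, 2.0, 2.0, 4.0, 5.0], index=list("abcdef"))
        X = pd.DataFrame({"intercept": 1.0, "x": x}, index=y.index)
        sxy, sxx = 14.5, 17.5
        syy = float(np.sum((y.to_numpy() - y.mean()) ** 2))
        r2 = (sxy**2 / sxx) / syy
        assert adjusted_r2(y, X) == pytest.approx(1 - (1 - r2) * 5 / 4, abs=1e-12)

    def test_unadjusted_r2_nested_monotone(self, toy_inputs):
        """Adding predictors never lowers the raw R² of the full-data fit."""
        rb, rf, ph = toy_inputs
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=len(rb)), index=rb.index)

        def raw_r2(X):
            Xv = X.to_numpy()
            yv = y.loc[X.index].to_numpy()
            coef, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
            return 1 - np.sum((yv - Xv @ coef) ** 2) / np.sum((yv - yv.mean()) ** 2)

        base = build_model_matrix(ModelSpec("ref_based", uses_ref_based=True), rb, rf, ph)
        bigger = build_model_matrix(
            ModelSpec("ref_based+phenotypes", uses_ref_based=True, uses_phenotypes=True),
            rb, rf, ph,
        )
        assert raw_r2(bigger) >= raw_r2(base) - 1e-12


class TestPerCpgR2:
    def test_linear_cpg_near_one_and_noise_near_zero(self, rng):
        n = 200
        design = pd.DataFrame(
            {"intercept": 1.0, "a": rng.normal(size=n), "b": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        lin = 0.5 + 0.1 * design["a"] - 0.05 * design["b"]
        noise = rng.normal(0.5, 0.1, size=(1000, n))
        betas = pd.DataFrame(
            np.vstack([lin.to_numpy(), noise]),
            index=["cg_lin"] + [f"cg{i}" for i in range(1000)],
            columns=design.index,
        )
        r2 = per_cpg_r2(betas, design, design)
        assert r2.loc["cg_lin", "ref_based"] > 0.999
        null_mean = r2.drop(index="cg_lin")["ref_based"].mean()
        assert abs(null_mean) < 0.01
        assert len(r2) == 1001


class TestHighR2Intersection:
    def test_strict_threshold(self):
        tables = [
            pd.Series({"cg1": 0.31, "cg2": 0.30, "cg3": 0.50}),
            pd.Series({"cg1": 0.40, "cg2": 0.99, "cg3": 0.10}),
        ]
        assert high_r2_intersection(tables) == {"cg1"}

    def test_matches_brute_force_set_logic(self, rng):
        tables = [
            pd.Series(rng.random(50), index=[f"cg{i}" for i in range(50)])
            for _ in range(4)
        ]
        got = high_r2_intersection(tables, threshold=0.30)
        brute = {
            f"cg{i}"
            for i in range(50)
            if all(t[f"cg{i}"] > 0.30 for t in tables)
        }
        assert got == brute
        assert got == high_r2_intersection(tables[::-1], threshold=0.30)
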