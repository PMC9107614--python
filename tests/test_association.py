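"""FNC computation, covariate residualization, LASSO, group statistics."""

import numpy as np
import pandas as pd
import pytest

from eptkit.association import (
    fnc,
    group_discrimination,
    lasso_select,
    residualize_covariates,
    voxelwise_group_glm,
)
from eptkit.core import TimepointSelection, pearson
from eptkit.synthetic_data import SymptomModel, make_symptom_cohort


def _cohort_frame(rng, n=120):
    return pd.DataFrame(
        {
            "age": rng.uniform(18, 65, n),
            "sex": rng.integers(0, 2, n),
            "site": rng.integers(0, 3, n).astype(str),
            "mfd": rng.uniform(0.05, 0.25, n),
        }
    )


class TestFnc:
    def test_self_correlation_is_one(self, rng):
        t = rng.standard_normal(200)
        r = fnc(t, np.vstack([t, -t]))
        np.testing.assert_allclose(r, [1.0, -1.0], atol=1e-12)

    def test_independent_courses_near_zero(self, rng):
        sel = TimepointSelection(np.arange(150), "all", 150)
        hits = 0
        for _ in range(50):
            t = rng.standard_normal(200)
            o = rng.standard_normal((9, 200))
            hits += np.all(np.abs(fnc(t, o, sel)) < 0.25)
        assert hits >= 48  # |r| < 0.25 with probability > 0.99 per draw

    def test_coupled_pair_estimate_within_sampling_error(self, rng):
        errs = []
        for _ in range(50):
            a = rng.standard_normal(200)
            b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(200)
            errs.append(abs(fnc(a, b[None, :])[0] - 0.5))
        assert np.median(errs) < 0.12

    def test_restricted_to_selection(self, rng):
        t = rng.standard_normal(200)
        o = rng.standard_normal((3, 200))
        sel = TimepointSelection(np.arange(0, 200, 10), "all", 20)
        expected = [pearson(t[sel.indices], o[k, sel.indices]) for k in range(3)]
        np.testing.assert_allclose(fnc(t, o, sel), expected, atol=1e-12)

    def test_constant_other_course_flagged_nan(self, rng):
        t = rng.standard_normal(100)
        o = np.vstack([np.ones(100), rng.standard_normal(100)])
        with pytest.warns(UserWarning, match="constant"):
            r = fnc(t, o)
        assert np.isnan(r[0]) and np.isfinite(r[1])


class TestResidualize:
    def test_exact_linear_function_of_age_zeroed(self, rng):
        cohort = _cohort_frame(rng)
        values = 2.0 * cohort["age"].to_numpy() - 7.0
        res = residualize_covariates(values, cohort)
        assert np.abs(res).max() < 1e-8

    def test_site_effect_removed(self, rng):
        cohort = _cohort_frame(rng, n=300)
        values = rng.standard_normal(300) * 0.05
        values[cohort["site"] == "2"] += 0.4
        res = residualize_covariates(values, cohort)
        means = [res[cohort["site"] == s].mean() for s in "012"]
        assert max(means) - min(means) < 0.02

    def test_residual_orthogonal_to_design(self, rng):
        from eptkit.association import covariate_design

        cohort = _cohort_frame(rng)
        values = rng.standard_normal(len(cohort))
        res = residualize_covariates(values, cohort)
        D = covariate_design(cohort)
        assert np.abs(D.T @ res).max() < 1e-8

    def test_residualize_then_correlate_is_partial_correlation(self, rng):
        # correlation of covariate residuals must equal the partial
        # correlation computed by an independent implementation
        import pingouin as pg

        cohort = _cohort_frame(rng, n=200)
        cohort["site"] = "0"  # single site so the designs coincide exactly
        x = rng.standard_normal(200) + 0.02 * cohort["age"].to_numpy()
        y = rng.standard_normal(200) + 0.03 * cohort["age"].to_numpy()
        ours = pearson(residualize_covariates(x, cohort), residualize_covariates(y, cohort))
        df = pd.DataFrame({"x": x, "y": y, "age": cohort["age"],
                           "sex": cohort["sex"], "mfd": cohort["mfd"]})
        oracle = pg.partial_corr(df, x="x", y="y", covar=["age", "sex", "mfd"])["r"].iloc[0]
        assert ours == pytest.approx(float(oracle), abs=1e-10)


class TestLasso:
    def test_planted_pairs_selected_nulls_rejected(self):
        coh = make_symptom_cohort(
            300, model=SymptomModel(pairs=(0, 1), betas=(2.0, 4.0)),
            seed=7, score_all=True)
        X = residualize_covariates(coh[[f"fnc_{j}" for j in range(9)]].to_numpy(), coh)
        y = residualize_covariates(coh["symptom"].to_numpy(float), coh)
        rep = lasso_select(X, y, cv=10, reps=20, seed=3)
        assert rep.selection_frequency[0] >= 0.9
        assert rep.selection_frequency[1] >= 0.9
        assert rep.selection_frequency[2:].max() <= 0.2
        assert set(rep.nonzero) >= {0, 1}

    def test_null_cohort_returns_all_zero_model(self):
        coh = make_symptom_cohort(
            300, model=SymptomModel(pairs=(), betas=()), seed=8, score_all=True)
        X = residualize_covariates(coh[[f"fnc_{j}" for j in range(9)]].to_numpy(), coh)
        y = residualize_covariates(coh["symptom"].to_numpy(float), coh)
        rep = lasso_select(X, y, cv=10, reps=20, seed=3)
        assert (rep.coefficients == 0).all(axis=1).mean() >= 0.8

    def test_reproducible_given_seed(self, rng):
        X = rng.standard_normal((100, 9))
        y = X[:, 0] + rng.standard_normal(100)
        a = lasso_select(X, y, reps=5, seed=11)
        b = lasso_select(X, y, reps=5, seed=11)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        assert a.chosen_lambda == b.chosen_lambda

    def test_insufficient_subjects_raises(self, rng):
        with pytest.raises(ValueError, match="at least 50"):
            lasso_select(rng.standard_normal((30, 9)), rng.standard_normal(30))

    def test_missing_values_raise(self, rng):
        X = rng.standard_normal((60, 9))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            lasso_select(X, rng.standard_normal(60))


class TestGroupDiscrimination:
    def test_offset_feature_detected(self, rng):
        n = 300
        diag = np.array(["case"] * 150 + ["control"] * 150)
        f = rng.normal(0, 0.2, n)
        f[:150] += 0.5
        res = group_discrimination(f[:, None], diag)
        assert res["significant"].iloc[0]

    def test_identical_classes_rarely_significant(self):
        local = np.random.default_rng(2024)
        diag = np.array(["case"] * 100 + ["control"] * 100)
        pvals = [
            group_discrimination(local.standard_normal(200)[:, None], diag)["p_value"].iloc[0]
            for _ in range(10)
        ]
        assert np.median(pvals) > 0.05

    def test_perfect_separation_penalized_refit(self):
        diag = np.array(["case"] * 30 + ["control"] * 30)
        f = np.concatenate([np.ones(30), -np.ones(30)])
        res = group_discrimination(f[:, None], diag)
        assert res["penalized"].iloc[0]
        assert np.isfinite(res["p_value"]).all()

    def test_too_few_subjects_raises(self, rng):
        diag = np.array(["case"] * 5 + ["control"] * 30)
        with pytest.raises(ValueError, match="at least 20"):
            group_discrimination(rng.standard_normal(35)[:, None], diag)


class TestVoxelwiseGlm:
    def test_planted_blob_survives_fdr(self, rng):
        n, v = 60, 500
        maps = rng.standard_normal((n, v))
        diag = np.array(["case"] * 30 + ["control"] * 30)
        blob = slice(40, 60)
        maps[:30, blob] += 1.5
        tstat, sig = voxelwise_group_glm(maps, diag)
        assert sig[blob].mean() > 0.8
        assert sig[np.r_[0:40, 60:500]].mean() < 0.05

    def test_null_false_discovery_controlled(self, rng):
        fdps = []
        for _ in range(20):
            maps = rng.standard_normal((60, 300))
            diag = np.array(["case"] * 30 + ["control"] * 30)
            _, sig = voxelwise_group_glm(maps, diag)
            fdps.append(sig.mean())
        assert np.mean(fdps) <= 0.05

    def test_constant_maps_raise(self):
        diag = np.array(["case"] * 25 + ["control"] * 25)
        with pytest.raises(ValueError, match="constant"):
            voxelwise_group_glm(np.ones((50, 100)), diag)


class TestPortionSpecificRecovery:
    def test_effects_recovered_from_their_own_portion_only(self):
        models = {
            "all": SymptomModel(pairs=(0,), betas=(3.0,)),
            "ept": SymptomModel(pairs=(3,), betas=(3.0,)),
            "eat": SymptomModel(pairs=(6,), betas=(3.0,)),
        }
        coh = make_symptom_cohort(300, portion_models=models, seed=9, score_all=True)
        y = residualize_covariates(coh["symptom"].to_numpy(float), coh)
        planted = {"all": 0, "ept": 3, "eat": 6}
        for portion, pair in planted.items():
            X = residualize_covariates(
                coh[[f"fnc_{portion}_{j}" for j in range(9)]].to_numpy(), coh)
            rep = lasso_select(X, y, cv=10, reps=10, seed=4)
            assert rep.selection_frequency[pair] >= 0.9
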