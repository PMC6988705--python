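import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from craniomirror.association import (adjust_bh, adjust_holm, effect_table,
                                      fit_feature_model,
                                      fit_random_intercept_ml,
                                      fit_univariate_lm, impute_ancestry_pcs,
                                      univariate_effect_table)

from conftest import synthetic_covariates
from oracles import bh_bruteforce, holm_bruteforce


class TestMultiplicityAdjustments:
    def test_holm_worked_examples(self):
        assert adjust_holm([0.01, 0.03, 0.04]) == pytest.approx([0.03, 0.06, 0.06])
        assert adjust_holm([0.5]) == pytest.approx([0.5])
        assert adjust_holm([0.6, 0.9]) == pytest.approx([1.0, 1.0])

    def test_bh_worked_examples(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    def test_against_bruteforce_oracles(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(1, 200))
            p = rng.random(n)
            assert np.max(np.abs(adjust_holm(p) - holm_bruteforce(p))) < 1e-12
            assert np.max(np.abs(adjust_bh(p) - bh_bruteforce(p))) < 1e-12

    def test_bh_dominated_by_holm(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(int(rng.integers(2, 100)))
            assert np.all(adjust_bh(p) <= adjust_holm(p) + 1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            adjust_holm([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_bh([-0.1])


class TestUnivariateLM:
    def test_identical_groups_null(self):
        y = np.concatenate([np.arange(5.0), np.arange(5.0)])
        g = np.array(["DEL"] * 5 + ["CTRL"] * 5)
        row = fit_univariate_lm(y, g, "DEL")
        assert row.coef == pytest.approx(0.0)
        assert row.p == pytest.approx(1.0)

    def test_matches_pooled_t_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1, 26)
            b = rng.normal(1, 1, 23)
            y = np.concatenate([a, b])
            g = np.array(["DEL"] * 26 + ["CTRL"] * 23)
            row = fit_univariate_lm(y, g, "DEL")
            t, p = stats.ttest_ind(a, b, equal_var=True)
            assert row.p == pytest.approx(p, abs=1e-10)
            assert row.coef == pytest.approx(a.mean() - b.mean(), abs=1e-10)

    def test_label_swap_negates_coefficient(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 40)
        g = np.array(["DEL"] * 20 + ["CTRL"] * 20)
        r1 = fit_univariate_lm(y, g, "DEL")
        g2 = np.where(g == "DEL", "CTRL", "DEL")
        r2 = fit_univariate_lm(y, g2, "DEL")
        assert r2.coef == pytest.approx(-r1.coef, abs=1e-12)
        assert r2.p == pytest.approx(r1.p, abs=1e-12)

    def test_zero_variance_both_groups_raises(self):
        y = np.array([1.0] * 4 + [2.0] * 4)
        g = np.array(["DEL"] * 4 + ["CTRL"] * 4)
        with pytest.raises(ValueError, match="zero variance"):
            fit_univariate_lm(y, g, "DEL")


class TestAncestryPCImputation:
    @staticmethod
    def _toy():
        cov = pd.DataFrame({
            "subject_id": ["p1", "p2", "c1", "c2", "c3", "lone"],
            "age": [40.0, 38.0, 10.0, 13.0, 16.0, 30.0],
            "PC1": [0.5, -0.5, 1.0, np.nan, 2.0, np.nan],
            "PC2": [0.1, -0.1, 0.9, np.nan, 1.9, np.nan],
        })
        ped = pd.DataFrame({
            "subject_id": ["p1", "p2", "c1", "c2", "c3", "lone"],
            "father_id": [None, None, "p1", "p1", "p1", None],
            "mother_id": [None, None, "p2", "p2", "p2", None],
        })
        return cov, ped

    def test_observed_rows_unchanged(self):
        cov, ped = self._toy()
        out = impute_ancestry_pcs(cov, ped, seed=0)
        assert out.loc[out.subject_id == "c1", "PC1"].iloc[0] == 1.0
        assert (out.loc[out.subject_id.isin(["p1", "p2", "c1", "c3"]),
                        "pc_imputed"] == "observed").all()

    def test_nearest_sibling_in_age_wins(self):
        cov, ped = self._toy()
        out = impute_ancestry_pcs(cov, ped, seed=0)
        # c2 (age 13): siblings c1 (gap 3) and c3 (gap 3)... adjust ages
        cov.loc[cov.subject_id == "c2", "age"] = 15.0  # gaps: c1=5, c3=1
        out = impute_ancestry_pcs(cov, ped, seed=0)
        row = out[out.subject_id == "c2"]
        assert row["PC1"].iloc[0] == 2.0  # from c3
        assert row["pc_imputed"].iloc[0] == "sibling"

    def test_parent_fallback_is_seeded_and_reproducible(self):
        cov, ped = self._toy()
        # remove sibling PCs so c2 must fall back to a parent
        cov.loc[cov.subject_id.isin(["c1", "c3"]), ["PC1", "PC2"]] = np.nan
        out1 = impute_ancestry_pcs(cov, ped, seed=7)
        out2 = impute_ancestry_pcs(cov, ped, seed=7)
        v1 = out1.loc[out1.subject_id == "c2", "PC1"].iloc[0]
        assert v1 in (0.5, -0.5)
        assert out1.loc[out1.subject_id == "c2", "pc_imputed"].iloc[0] == "parent"
        pd.testing.assert_frame_equal(out1, out2)

    def test_no_relatives_flagged_not_dropped(self):
        cov, ped = self._toy()
        out = impute_ancestry_pcs(cov, ped, seed=0)
        row = out[out.subject_id == "lone"]
        assert row["pc_imputed"].iloc[0] == "missing"
        assert np.isnan(row["PC1"].iloc[0])
        assert len(out) == len(cov)


class TestRandomInterceptML:
    def test_matches_statsmodels_mixedlm(self):
        from statsmodels.regression.mixed_linear_model import MixedLM
        rng = np.random.default_rng(4)
        for _ in range(5):
            n, nfam = 150, 40
            fam = rng.integers(0, nfam, n)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            y = rng.normal(0, 0.8, nfam)[fam] + rng.normal(0, 1, n) + 0.4 * X[:, 1]
            ours = fit_random_intercept_ml(y, X, fam)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = MixedLM(y, X, groups=fam).fit(reml=False, maxiter=500)
            # exact profiled optimum can only be at least as good
            assert ours.llf >= ref.llf - 1e-8
            if abs(ours.llf - ref.llf) < 1e-6:
                assert np.allclose(ours.params, ref.fe_params, atol=1e-4)

    def test_matches_lme4_ml_fit(self, tmp_path):
        # the reference mixed-model implementation in R, fitted by ML
        import subprocess
        import textwrap
        rng = np.random.default_rng(3)
        n, nfam = 150, 40
        fam = rng.integers(0, nfam, n)
        x = rng.normal(size=n)
        y = rng.normal(0, 0.8, nfam)[fam] + 0.5 * x + rng.normal(0, 1, n)
        pd.DataFrame({"y": y, "x": x, "fam": fam}).to_csv(
            tmp_path / "d.csv", index=False)
        rcode = textwrap.dedent(f'''
            suppressMessages(library(lme4))
            d <- read.csv("{tmp_path / 'd.csv'}")
            m <- lmer(y ~ x + (1|fam), data=d, REML=FALSE)
            cat(sprintf("%.10f %.10f %.10f\\n",
                        logLik(m), fixef(m)[1], fixef(m)[2]))
        ''')
        out = subprocess.run(["Rscript", "-e", rcode],
                             capture_output=True, text=True, check=True)
        llf_r, b0, b1 = map(float, out.stdout.split())
        ours = fit_random_intercept_ml(y, np.column_stack([np.ones(n), x]), fam)
        assert ours.llf == pytest.approx(llf_r, abs=1e-6)
        assert ours.params == pytest.approx([b0, b1], abs=1e-6)

    def test_zero_family_variance_matches_ols(self):
        rng = np.random.default_rng(5)
        n = 120
        fam = rng.integers(0, 30, n)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 0.5, -0.2] + rng.normal(0, 1, n)  # no family effect
        ours = fit_random_intercept_ml(y, X, fam)
        ols = sm.OLS(y, X).fit()
        assert np.allclose(ours.params, ols.params, atol=1e-6)
        assert ours.llf >= ols.llf - 1e-10

    def test_variance_components_recovered_within_20pct(self):
        rng = np.random.default_rng(6)
        n, nfam = 500, 150
        fam = np.repeat(np.arange(nfam), np.diff(np.linspace(0, n, nfam + 1).astype(int)))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        sd_fam, sd_res = 0.8, 1.0
        y = rng.normal(0, sd_fam, nfam)[fam] + rng.normal(0, sd_res, n)
        ours = fit_random_intercept_ml(y, X, fam)
        assert ours.sigma2_group == pytest.approx(sd_fam ** 2, rel=0.2)
        assert ours.sigma2_resid == pytest.approx(sd_res ** 2, rel=0.2)


class TestFeatureModel:
    def test_degenerate_family_variance_matches_ols_oracle(self):
        rng = np.random.default_rng(7)
        cov, fam = synthetic_covariates(rng, n=200, n_fam=60)
        # response independent of family
        y = pd.Series(0.05 * (cov["genotype"] == "DEL") + rng.normal(0, 0.02, 200))
        row = fit_feature_model(y, cov, "DEL", sex_interaction="never")
        X = np.column_stack([
            np.ones(200), cov["age"], cov["head_circumference"], cov["bmi"],
            (cov["sex"] == "M").astype(float), cov["PC1"], cov["PC2"],
            (cov["genotype"] == "DEL").astype(float),
        ])
        ols = sm.OLS(y.to_numpy(), X).fit()
        assert row.coef == pytest.approx(ols.params[-1], abs=1e-4)

    def test_random_intercept_continuity_near_zero_variance(self):
        # with ~zero family variance, including or dropping the random
        # intercept moves the genotype coefficient by < 1e-4
        rng = np.random.default_rng(8)
        cov, fam = synthetic_covariates(rng, n=200, n_fam=60)
        y = pd.Series(rng.normal(0, 1, 200))
        mixed = fit_feature_model(y, cov, "DEL", sex_interaction="never")
        single_fam = cov.copy()
        single_fam["family_id"] = "F0"  # forces fixed-effects fallback
        with pytest.warns(UserWarning, match="fewer than 2 families"):
            fixed = fit_feature_model(y, single_fam, "DEL", sex_interaction="never")
        assert mixed.coef == pytest.approx(fixed.coef, abs=1e-4)

    def test_sex_interaction_screening_detects_planted_interaction(self):
        rng = np.random.default_rng(9)
        cov, fam = synthetic_covariates(rng, n=400, n_fam=100)
        male = (cov["sex"] == "M").astype(float)
        geno = (cov["genotype"] == "DEL").astype(float)
        y = pd.Series(1.0 * geno * male + rng.normal(0, 0.5, 400))
        row = fit_feature_model(y, cov, "DEL", sex_interaction="screen")
        assert row.interaction_included
        assert row.df == 2

    def test_parameter_recovery_coverage(self):
        # planted genotype effect recovered within its 95% CI at the
        # nominal rate (n=200 subjects, 60 families)
        rng = np.random.default_rng(10)
        beta = 0.05
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            cov, fam = synthetic_covariates(rng, n=200, n_fam=60)
            fam_eff = rng.normal(0, 0.01, 60)[fam]
            y = pd.Series(beta * (cov["genotype"] == "DEL")
                          + fam_eff + rng.normal(0, 0.02, 200))
            row = fit_feature_model(y, cov, "DEL", sex_interaction="never")
            hits += abs(row.coef - beta) <= 1.96 * row.se
        assert hits / n_rep >= 0.93

    def test_missing_rows_dropped_and_counted(self):
        rng = np.random.default_rng(11)
        cov, fam = synthetic_covariates(rng, n=100, n_fam=30)
        cov.loc[:9, "PC1"] = np.nan
        y = pd.Series(rng.normal(0, 1, 100))
        row = fit_feature_model(y, cov, "DEL", sex_interaction="never")
        assert row.n_used + row.n_dropped == (cov["genotype"] != "DUP").sum()
        assert row.n_dropped >= (cov.loc[:9, "genotype"] != "DUP").sum()


class TestEffectTables:
    def test_mixed_table_shape_and_adjustment_invariants(self, human_features,
                                                         human_cohort):
        cov = human_cohort.covariates.set_index("subject_id")
        cols = list(human_cohort.truth["effect_map"])[:6]
        tab = effect_table(human_features[cols], cov)
        assert len(tab) == 12  # 6 features x 2 contrasts
        ok = tab["p_holm"].notna()
        assert (tab.loc[ok, "p_holm"] >= tab.loc[ok, "p"] - 1e-12).all()
        assert (tab.loc[ok, "q_bh"] <= tab.loc[ok, "p_holm"] + 1e-12).all()
        assert tab["p"].dropna().between(0, 1).all()

    def test_univariate_table_runs_per_contrast(self):
        rng = np.random.default_rng(12)
        feats = pd.DataFrame(rng.normal(size=(60, 4)),
                             columns=list("abcd"),
                             index=[f"r{i}" for i in range(60)])
        geno = pd.Series(["DEL"] * 20 + ["DUP"] * 20 + ["CTRL"] * 20,
                         index=feats.index)
        tab = univariate_effect_table(feats, geno)
        assert set(tab["contrast"]) == {"DEL", "DUP"}
        assert len(tab) == 8
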