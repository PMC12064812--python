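"""Mixed models, LRTs, permutation tests, bootstrap, post hocs, FDR."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from insightrc.stats import (
    ModelSpec,
    bootstrap_odds_ratio,
    fdr_correct,
    fit_mixed_model,
    likelihood_ratio_test,
    permutation_lrt,
    posthoc_slopes,
)


def simulate_lmm(rng, n_subj=15, n_item=20, beta_x=0.5, subj_sd=0.7,
                 item_sd=0.4, sigma=1.0, family="gaussian", extra_cols=()):
    """Crossed-design generator used across the model tests."""
    b_s = subj_sd * rng.standard_normal(n_subj)
    b_i = item_sd * rng.standard_normal(n_item)
    rows = []
    for s in range(n_subj):
        for i in range(n_item):
            x = rng.standard_normal()
            eta = 0.3 + beta_x * x + b_s[s] + b_i[i]
            if family == "gaussian":
                y = eta + sigma * rng.standard_normal()
            else:
                y = int(rng.random() < expit(eta))
            row = {"subject_id": f"s{s}", "item_id": f"i{i}", "x": x, "y": y}
            for c in extra_cols:
                row[c] = rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitMixedModel:
    def test_gaussian_matches_statsmodels_ml(self, rng):
        """Independent oracle: statsmodels MixedLM with two variance
        components fitted by ML on the same data."""
        import statsmodels.formula.api as smf

        df = simulate_lmm(rng)
        fit = fit_mixed_model(ModelSpec("y", "x"), df)
        oracle = smf.mixedlm(
            "y ~ x", df, groups=np.ones(len(df)),
            vc_formula={"subject_id": "0 + C(subject_id)",
                        "item_id": "0 + C(item_id)"},
        ).fit(reml=False)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        for name in ("Intercept", "x"):
            assert fit.params[name] == pytest.approx(oracle.fe_params[name],
                                                     abs=1e-5)

    def test_against_lme4_via_rscript(self, rng, tmp_path):
        """Cross-language oracle: lmer (REML=FALSE) and glmer (nAGQ=0) on
        identical data must reproduce our log-likelihoods and
        coefficients."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available in the environment")
        df = simulate_lmm(rng, family="binomial")
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            g <- glmer(y ~ x + (1|subject_id) + (1|item_id), data=d,
                       family=binomial, nAGQ=0)
            m <- lmer(x ~ y + (1|subject_id) + (1|item_id), data=d, REML=FALSE)
            cat(fixef(g), as.numeric(logLik(g)),
                fixef(m), as.numeric(logLik(m)), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        gi, gx, gll, mi, my, mll = map(float, out.stdout.strip().splitlines())

        fit_b = fit_mixed_model(ModelSpec("y", "x", family="binomial"), df)
        assert fit_b.params["Intercept"] == pytest.approx(gi, abs=2e-3)
        assert fit_b.params["x"] == pytest.approx(gx, abs=2e-3)
        assert fit_b.loglik == pytest.approx(gll, abs=5e-2)

        fit_g = fit_mixed_model(ModelSpec("x", "y"), df)
        assert fit_g.params["Intercept"] == pytest.approx(mi, abs=1e-4)
        assert fit_g.params["y"] == pytest.approx(my, abs=1e-4)
        assert fit_g.loglik == pytest.approx(mll, abs=1e-3)

    def test_zero_variance_components_match_plain_glm(self, rng):
        import statsmodels.api as sm

        df = simulate_lmm(rng, subj_sd=0.0, item_sd=0.0, family="binomial",
                          n_subj=25, n_item=25)
        fit = fit_mixed_model(ModelSpec("y", "x", family="binomial"), df)
        X = sm.add_constant(df["x"])
        glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
        assert fit.params["x"] == pytest.approx(glm.params["x"], abs=0.03)
        assert fit.singular  # variance components collapse to ~0

    def test_variance_components_recovered(self, rng):
        # averaged over replicates: a single draw of 40 subject effects has
        # ~11% sampling noise in its own SD
        ests = []
        for _ in range(4):
            df = simulate_lmm(rng, n_subj=40, n_item=40, subj_sd=1.0,
                              item_sd=0.5)
            fit = fit_mixed_model(ModelSpec("y", "x"), df)
            ests.append([fit.random_effect_sd["subject_id"],
                         fit.random_effect_sd["item_id"], fit.sigma])
        mean = np.mean(ests, axis=0)
        assert mean[0] == pytest.approx(1.0, rel=0.2)
        assert mean[1] == pytest.approx(0.5, rel=0.2)
        assert mean[2] == pytest.approx(1.0, rel=0.1)

    def test_standardization_yields_standardized_betas(self, rng):
        df = simulate_lmm(rng)
        df["x"] = 3.0 * df["x"] + 10.0
        raw = fit_mixed_model(ModelSpec("y", "x"), df)
        std = fit_mixed_model(ModelSpec("y", "x"), df, standardize=True)
        # standardized slope = raw slope * sd(x) / sd(y)
        expected = raw.params["x"] * df.x.std(ddof=0) / df.y.std(ddof=0)
        assert std.params["x"] == pytest.approx(expected, rel=1e-3)

    def test_binomial_requires_binary_response(self, rng):
        df = simulate_lmm(rng)
        with pytest.raises(ValueError, match="0/1"):
            fit_mixed_model(ModelSpec("y", "x", family="binomial"), df)

    def test_missing_group_column_rejected(self, rng):
        df = simulate_lmm(rng).drop(columns=["item_id"])
        with pytest.raises(ValueError, match="item_id"):
            fit_mixed_model(ModelSpec("y", "x"), df)


class TestLikelihoodRatioTest:
    def test_identical_specs_give_null_result(self, rng):
        df = simulate_lmm(rng)
        fit = fit_mixed_model(ModelSpec("y", "x"), df)
        out = likelihood_ratio_test(fit, fit)
        assert out.chi2 == 0.0 and out.p == 1.0

    def test_non_nested_models_rejected(self, rng):
        df = simulate_lmm(rng, extra_cols=("w",))
        a = fit_mixed_model(ModelSpec("y", "x"), df)
        b = fit_mixed_model(ModelSpec("y", "w"), df)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)

    def test_different_rows_rejected(self, rng):
        df = simulate_lmm(rng)
        a = fit_mixed_model(ModelSpec("y", "x"), df)
        b = fit_mixed_model(ModelSpec("y", "x"), df.iloc[:-10])
        with pytest.raises(ValueError, match="identical rows"):
            likelihood_ratio_test(b, a)

    def test_detects_strong_effect_with_or_estimate(self, rng):
        df = simulate_lmm(rng, beta_x=0.9, family="binomial",
                          n_subj=25, n_item=25)
        base = fit_mixed_model(ModelSpec("y", "1", family="binomial"), df)
        full = fit_mixed_model(ModelSpec("y", "x", family="binomial"), df)
        out = likelihood_ratio_test(base, full)
        assert out.p < 1e-6 and out.df == 1
        assert out.effect_name == "x"
        assert out.ci[0] < np.exp(0.9) < out.ci[1]

    def test_type_one_error_calibrated_under_null(self, rng):
        """Wilks calibration: with no true effect, df=1 LRT rejects at
        the nominal 5% rate (binomial tolerance)."""
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            df = simulate_lmm(rng, beta_x=0.0, n_subj=10, n_item=10)
            base = fit_mixed_model(ModelSpec("y", "1"), df)
            full = fit_mixed_model(ModelSpec("y", "x"), df)
            rejections += likelihood_ratio_test(base, full).p < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / n_sims) + 0.01


class TestPermutationLrt:
    def test_strong_effect_attains_lower_bound(self, rng):
        df = simulate_lmm(rng, beta_x=2.0, n_subj=12, n_item=12)
        out = permutation_lrt(
            ModelSpec("y", "1"), ModelSpec("y", "x"), df, term="x",
            n_perm=99, seed=3,
        )
        assert out["p"] == pytest.approx(1.0 / 100.0)

    def test_seeded_reproducibility(self, rng):
        df = simulate_lmm(rng, beta_x=0.3, n_subj=8, n_item=8)
        kw = dict(term="x", n_perm=29, seed=11)
        a = permutation_lrt(ModelSpec("y", "1"), ModelSpec("y", "x"), df, **kw)
        b = permutation_lrt(ModelSpec("y", "1"), ModelSpec("y", "x"), df, **kw)
        assert a["p"] == b["p"]

    def test_unknown_term_rejected(self, rng):
        df = simulate_lmm(rng)
        with pytest.raises(ValueError, match="tested term"):
            permutation_lrt(ModelSpec("y", "1"), ModelSpec("y", "x"), df,
                            term="zz", n_perm=9, seed=0)


class TestBootstrapOddsRatio:
    def test_point_estimate_matches_full_data_fit(self, rng):
        df = simulate_lmm(rng, beta_x=0.7, family="binomial",
                          n_subj=20, n_item=15)
        full = fit_mixed_model(ModelSpec("y", "x", family="binomial"), df)
        out = bootstrap_odds_ratio(
            ModelSpec("y", "x", family="binomial"), df, term="x",
            n_boot=30, seed=5,
        )
        assert out.odds_ratio == pytest.approx(np.exp(full.params["x"]))
        assert out.ci[0] < out.odds_ratio < out.ci[1]

    def test_null_generator_ci_covers_one(self, rng):
        covered = 0
        n_rep = 8
        for rep in range(n_rep):
            df = simulate_lmm(rng, beta_x=0.0, family="binomial",
                              n_subj=10, n_item=10, subj_sd=0.3, item_sd=0.3)
            out = bootstrap_odds_ratio(
                ModelSpec("y", "x", family="binomial"), df, term="x",
                n_boot=49, seed=rep,
            )
            covered += out.ci[0] <= 1.0 <= out.ci[1]
        assert covered >= 6  # ~95% coverage, small-sample binomial slack

    def test_gaussian_spec_rejected(self, rng):
        df = simulate_lmm(rng)
        with pytest.raises(ValueError, match="binomial"):
            bootstrap_odds_ratio(ModelSpec("y", "x"), df, term="x")


class TestPosthocSlopes:
    @staticmethod
    def _factor_data(rng, slopes, n=400):
        levels = list(slopes)
        rows = []
        for i in range(n):
            lev = levels[i % len(levels)]
            x = rng.standard_normal()
            y = 1.0 + slopes[lev] * x + 0.3 * rng.standard_normal()
            rows.append({"subject_id": f"s{i % 10}", "item_id": f"i{i % 20}",
                         "roi": lev, "x": x, "y": y})
        return pd.DataFrame(rows)

    def test_slopes_match_per_level_refits(self, rng):
        """Contrast-algebra oracle: on a balanced design the simple slope
        per factor level equals an independent per-level fit."""
        slopes = {"A": 0.5, "B": -0.2, "C": 1.1}
        df = self._factor_data(rng, slopes)
        fit = fit_mixed_model(ModelSpec("y", "roi * x"), df)
        out = posthoc_slopes(fit, by="roi", term="x").set_index("level")
        for lev in slopes:
            sub = df[df.roi == lev]
            ref = fit_mixed_model(ModelSpec("y", "x"), sub)
            assert out.loc[lev, "slope"] == pytest.approx(
                ref.params["x"], abs=0.02
            )

    def test_bonferroni_scales_p_capped_at_one(self, rng):
        df = self._factor_data(rng, {"A": 0.02, "B": 0.01})
        fit = fit_mixed_model(ModelSpec("y", "roi * x"), df)
        raw = posthoc_slopes(fit, by="roi", term="x", correction="none")
        cor = posthoc_slopes(fit, by="roi", term="x", correction="bonferroni")
        np.testing.assert_allclose(
            cor.p_corrected, np.minimum(1.0, raw.p * 2), atol=1e-12
        )

    def test_missing_factor_rejected(self, rng):
        df = self._factor_data(rng, {"A": 0.5, "B": 0.1})
        fit = fit_mixed_model(ModelSpec("y", "roi * x"), df)
        with pytest.raises(ValueError):
            posthoc_slopes(fit, by="hemisphere", term="x")


class TestFdrCorrect:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.03])[0] == pytest.approx(0.03)

    def test_bh_arithmetic(self):
        q = fdr_correct([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_all_ones_stay_one(self):
        assert (fdr_correct([1.0, 1.0, 1.0]) == 1.0).all()

    def test_monotone_in_input_ranks(self, rng):
        p = rng.uniform(0.001, 1.0, 30)
        q = fdr_correct(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @pytest.mark.parametrize("bad", [[], [0.0, 0.5], [0.5, 1.2]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fdr_correct(bad)
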