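"""Binomial stage models: GLM/GLMM estimation, AICc, profile intervals."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from seedshadow import stage_glms
from seedshadow.stage_glms import (
    aicc,
    fit_binomial_glm,
    fit_binomial_glmm,
    fit_field_germination,
    fit_germination_glm,
    fit_ingestion_distance,
    fit_ingestion_island,
    fit_seedling_survival,
    profile_ci,
)


class TestAicc:
    def test_formula_value(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(20 + 4 + 12 / 7)

    def test_zero_parameters_reduces_to_aic(self):
        assert aicc(-5.0, 0, 20) == pytest.approx(10.0)

    def test_correction_positive(self):
        for k in (1, 3, 5):
            assert aicc(-5.0, k, 30) > -2 * -5.0 + 2 * k

    def test_undefined_small_n(self):
        with pytest.raises(ValueError):
            aicc(-1.0, 3, 4)


class TestGerminationGlm:
    @staticmethod
    def _records(n_whole, g_whole, n_ing, g_ing):
        rows = [{"treatment": "whole_fruit", "germinated": int(i < g_whole)}
                for i in range(n_whole)]
        rows += [{"treatment": "ingested", "germinated": int(i < g_ing)}
                 for i in range(n_ing)]
        return pd.DataFrame(rows)

    def test_saturated_fit_reproduces_cell_proportions(self):
        # 20/100 whole vs 60/150 ingested; binomial MLE = cell proportions
        fit = fit_germination_glm(self._records(100, 20, 150, 60))
        c = fit.coef_dict()
        assert expit(c["intercept"]) == pytest.approx(0.20, abs=1e-6)
        assert expit(c["intercept"] + c["treatment[ingested]"]) == pytest.approx(
            0.40, abs=1e-6
        )
        assert c["treatment[ingested]"] == pytest.approx(math.log(8 / 3), abs=1e-6)

    def test_no_effect_favours_null(self):
        fit = fit_germination_glm(self._records(100, 30, 100, 30))
        assert fit.extras["best_tag"] == "null"
        assert abs(fit.coef_dict()["treatment[ingested]"]) < 1e-6

    def test_both_reference_levels_reported(self, world):
        fit = fit_germination_glm(world.germination)
        assert "treatment[ingested]" in fit.profile_cis
        assert "treatment[ingested]|ref=depulped" in fit.profile_cis
        # contrast identity: (ingested - whole) - (depulped - whole) = ingested - depulped
        c = fit.coef_dict()
        alt = fit.extras["alt_coefs"]
        assert alt["treatment[ingested]"] == pytest.approx(
            c["treatment[ingested]"] - c["treatment[depulped]"], abs=1e-5
        )

    def test_effect_direction_matches_generator(self, world):
        """Ingestion raises germination severalfold by construction; the
        fitted odds ratio must be positive with a CI excluding zero."""
        fit = fit_germination_glm(world.germination)
        lo, hi, includes_zero = fit.profile_cis["treatment[ingested]"]
        assert fit.coef_dict()["treatment[ingested]"] > 0
        assert not includes_zero and lo > 0


class TestProfileCi:
    def test_single_proportion_matches_deviance_scan(self):
        """Intercept-only model: the profile interval can be computed by a
        direct scan of the binomial deviance."""
        y, n = 14, 40
        X = np.ones((1, 1))
        fit = fit_binomial_glm(X, np.array([y]), np.array([n]), ["intercept"])
        lo, hi, _ = profile_ci(fit, "intercept")

        def loglik(b):
            return y * b - n * math.log1p(math.exp(b)) + math.log(math.comb(n, y))

        b_hat = math.log(y / (n - y))
        target = loglik(b_hat) - 3.841459 / 2

        lo_scan = optimize.brentq(lambda b: loglik(b) - target, b_hat - 4, b_hat)
        hi_scan = optimize.brentq(lambda b: loglik(b) - target, b_hat, b_hat + 4)
        assert lo == pytest.approx(lo_scan, abs=1e-4)
        assert hi == pytest.approx(hi_scan, abs=1e-4)

    def test_large_n_agrees_with_wald(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        p = expit(-0.3 + 0.5 * x)
        y = (rng.uniform(size=n) < p).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_binomial_glm(X, y, np.ones(n), ["intercept", "x"])
        lo, hi, _ = profile_ci(fit, "x")
        se = fit.se()[1]
        wald_lo = fit.coef[1] - 1.959964 * se
        wald_hi = fit.coef[1] + 1.959964 * se
        assert lo == pytest.approx(wald_lo, abs=0.05 * (wald_hi - wald_lo))
        assert hi == pytest.approx(wald_hi, abs=0.05 * (wald_hi - wald_lo))

    def test_null_predictor_ci_includes_zero(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 0.4).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_binomial_glm(X, y, np.ones(n), ["intercept", "x"])
        assert profile_ci(fit, "x")[2] is True


class TestGlmm:
    def test_matches_lme4_on_fixture(self, tmp_path):
        """Independent oracle: lme4::glmer with 25-node adaptive quadrature
        on a small two-column fixture."""
        rng = np.random.default_rng(42)
        rows = []
        for g in range(10):
            u = rng.normal(0, 0.6)
            for _ in range(8):
                x = rng.normal()
                p = expit(-0.4 + 0.7 * x + u)
                rows.append({"g": f"g{g}", "x": x, "n": 20,
                             "y": int(rng.binomial(20, p))})
        df = pd.DataFrame(rows)
        X = np.column_stack([np.ones(len(df)), df.x])
        fit = fit_binomial_glmm(X, df.y, df.n, df.g, ["intercept", "x"])

        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        rcode = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            'm <- glmer(cbind(y, n-y) ~ x + (1|g), data=d, family=binomial, nAGQ=25);'
            'cat(fixef(m), sqrt(unlist(VarCorr(m))), '
            'summary(m)$coefficients[,2], sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        b0, b1, sigma, se0, se1 = map(float, out.stdout.strip().split("\n"))
        assert fit.coef[0] == pytest.approx(b0, abs=2e-3)
        assert fit.coef[1] == pytest.approx(b1, abs=2e-3)
        assert fit.sigma_group == pytest.approx(sigma, abs=5e-3)
        assert fit.se()[0] == pytest.approx(se0, rel=0.02)
        assert fit.se()[1] == pytest.approx(se1, rel=0.02)

    def test_binomial_weighting_leave_one_out(self):
        """A 20-seed trap moves the estimate more than a 1-seed trap."""
        rng = np.random.default_rng(5)
        n_obs = 30
        x = rng.normal(size=n_obs)
        trials = np.full(n_obs, 5.0)
        trials[0], trials[1] = 20.0, 1.0
        p = expit(0.2 + 0.6 * x)
        y = rng.binomial(trials.astype(int), p).astype(float)
        # make the two focal traps identical except for their weight
        x[1] = x[0]
        y[0] = round(0.9 * trials[0])
        y[1] = round(0.9 * trials[1])
        X = np.column_stack([np.ones(n_obs), x])
        full = fit_binomial_glm(X, y, trials, ["intercept", "x"]).coef
        drop_heavy = fit_binomial_glm(
            np.delete(X, 0, 0), np.delete(y, 0), np.delete(trials, 0),
            ["intercept", "x"],
        ).coef
        drop_light = fit_binomial_glm(
            np.delete(X, 1, 0), np.delete(y, 1), np.delete(trials, 1),
            ["intercept", "x"],
        ).coef
        assert np.linalg.norm(full - drop_heavy) > np.linalg.norm(full - drop_light)


class TestIngestionModels:
    def test_guam_zero_arm_handled(self, world):
        fit = fit_ingestion_island(world.traps)
        assert "Guam" in fit.extras["excluded_islands"]
        assert np.all(np.isfinite(fit.coef))

    def test_distance_slope_recovered(self, world):
        fit = fit_ingestion_distance(world.traps)
        assert "distance" in fit.terms
        lo, hi, includes_zero = fit.profile_cis["distance"]
        true_slope = world.config.ingestion_distance_slope
        assert lo <= true_slope <= hi
        assert not includes_zero  # positive distance effect is detected

    def test_island_offsets_covered_by_profile_cis(self):
        """Island contrasts fall inside their 95% profile intervals at
        close to the nominal rate across replicates."""
        from seedshadow.synthetic import WorldConfig, simulate_world

        covered = total = 0
        for rep in range(10):
            cfg = WorldConfig(
                seed=2100 + rep,
                ingestion_island_offsets={"Rota": 0.0, "Saipan": 1.0, "Tinian": 2.0},
                ingestion_distance_slope=0.0,
            )
            w = simulate_world(cfg)
            fit = fit_ingestion_island(w.traps)
            for name, truth in (("island[Saipan]", 1.0), ("island[Tinian]", 2.0)):
                lo, hi, _ = fit.profile_cis[name]
                covered += lo <= truth <= hi
                total += 1
        assert total == 20
        assert covered >= 17


class TestSurvivalModels:
    def test_far_advantage_recovered(self, world):
        fit = fit_seedling_survival(world.survival_plots)
        assert "far" in fit.terms
        lo, hi, includes_zero = fit.profile_cis["far"]
        assert lo <= world.config.survival_far_effect <= hi
        assert not includes_zero
        # generator default has no birds-by-distance interaction
        assert "birds_present:far" not in fit.terms

    def test_equal_survival_selects_null(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(6):
            for d in ("near", "far"):
                for _ in range(4):
                    rows.append({
                        "site_id": f"s{s}", "island": "Guam", "birds_present": 0,
                        "distance_class": d, "n_planted": 10,
                        "n_survived": int(rng.binomial(10, 0.4)),
                        "canopy_openness": rng.normal(10, 3),
                    })
        fit = fit_seedling_survival(pd.DataFrame(rows))
        assert fit.tag == "null"

    def test_field_distance_effect_feeds_integral(self, world):
        fit = fit_field_germination(world.seed_addition)
        assert "far" in fit.terms
        true_far = math.log(
            world.config.addition_germ_p_far / (1 - world.config.addition_germ_p_far)
        ) - math.log(
            world.config.addition_germ_p_near / (1 - world.config.addition_germ_p_near)
        )
        lo, hi, _ = fit.profile_cis["far"]
        assert lo <= true_far <= hi

    def test_no_distance_effect_dropped(self):
        from seedshadow.synthetic import WorldConfig, simulate_world

        cfg = WorldConfig(
            seed=31,
            addition_germ_p_near=0.3, addition_germ_p_far=0.3,
        )
        w = simulate_world(cfg)
        fit = fit_field_germination(w.seed_addition)
        assert "far" not in fit.terms

    def test_aicc_ranking_invariant_to_row_order(self, world):
        f1 = fit_seedling_survival(world.survival_plots)
        shuffled = world.survival_plots.sample(frac=1.0, random_state=9)
        f2 = fit_seedling_survival(shuffled)
        assert f1.tag == f2.tag
        assert list(f1.table.tag) == list(f2.table.tag)


class TestSeparation:
    def test_all_zero_arm_flagged_finite(self):
        X = np.column_stack([np.ones(20), np.repeat([0.0, 1.0], 10)])
        y = np.concatenate([np.zeros(10), np.full(10, 5.0)])
        fit = fit_binomial_glm(X, y, np.full(20, 10.0), ["intercept", "arm"])
        assert fit.extras["separation"] is True
        assert np.all(np.isfinite(fit.coef))
        assert np.all(np.isfinite(fit.cov))
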