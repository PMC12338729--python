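"""Penalized-smooth trajectory model: analytic limits, oracles, mgcv cross-check."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from cofluct import (
    SmoothConfig,
    SyntheticCohortSpec,
    age_effect,
    fit_all_regions,
    fit_trajectory,
    generate_cohort,
    score_scan,
    trajectory_similarity,
)


def obs_frame(x, y, sex=0.0, fd=0.0):
    return pd.DataFrame({"score": y, "global_amplitude": x, "sex": sex, "mean_fd": fd})


class TestFitTrajectory:
    def test_noiseless_linear_limit(self):
        """A line must be reproduced exactly: full partial R^2, no curvature."""
        x = np.linspace(0, 1, 40)
        fit = fit_trajectory(obs_frame(x, 2 * x))
        assert fit.partial_r2 > 0.999
        assert abs(fit.mean_second_derivative) < 1e-3
        assert fit.primary_effect > 0

    def test_constant_response_is_null(self):
        x = np.linspace(0, 1, 40)
        fit = fit_trajectory(obs_frame(x, np.full(40, 0.7)))
        assert fit.partial_r2 < 1e-6
        assert fit.p_smooth > 0.9

    def test_noiseless_quadratic_second_derivative(self):
        """-(x - 0.5)^2 has second derivative -2 everywhere."""
        x = np.linspace(0, 1, 40)
        fit = fit_trajectory(obs_frame(x, -(x - 0.5) ** 2))
        assert fit.mean_second_derivative == pytest.approx(-2.0, abs=0.05)

    def test_derivative_grid_convergence(self):
        """Halving the grid step changes mean derivatives by < 1%."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 120)
        y = np.sin(2.5 * x) + 0.05 * rng.standard_normal(120)
        coarse = fit_trajectory(obs_frame(x, y), SmoothConfig(grid_size=200))
        fine = fit_trajectory(obs_frame(x, y), SmoothConfig(grid_size=400))
        for attr in ("mean_first_derivative", "mean_second_derivative"):
            a, b = getattr(coarse, attr), getattr(fine, attr)
            assert abs(a - b) <= 0.01 * max(abs(a), abs(b))

    def test_score_offset_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 80)
        y = np.cos(3 * x) + 0.1 * rng.standard_normal(80)
        sex = rng.integers(0, 2, 80).astype(float)
        fd = rng.uniform(0, 0.3, 80)
        f1 = fit_trajectory(obs_frame(x, y, sex, fd))
        f2 = fit_trajectory(obs_frame(x, y + 4.2, sex, fd))
        assert f1.partial_r2 == pytest.approx(f2.partial_r2, abs=1e-6)
        assert f1.mean_second_derivative == pytest.approx(
            f2.mean_second_derivative, abs=1e-6)
        assert np.allclose(f1.fitted_curve[:, 1] + 4.2, f2.fitted_curve[:, 1], atol=1e-6)

    def test_reduced_model_never_beats_full(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = rng.uniform(0, 1, 60)
            y = rng.standard_normal(60)
            fit = fit_trajectory(obs_frame(x, y))
            assert 0.0 <= fit.partial_r2 <= 1.0

    def test_preconditions(self):
        x = np.linspace(0, 1, 5)
        with pytest.raises(ValueError, match="10 observations"):
            fit_trajectory(obs_frame(x, x))
        x = np.repeat([0.0, 1.0], 10)
        with pytest.raises(ValueError, match="3 distinct"):
            fit_trajectory(obs_frame(x, x))

    def test_matches_mgcv_reml_fit(self, tmp_path):
        """Independent GAM route (mgcv thin-plate REML) agrees with the P-spline."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(42)
        n = 300
        x = rng.uniform(0, 1, n)
        sex = rng.integers(0, 2, n).astype(float)
        fd = rng.uniform(0, 0.3, n)
        y = np.sin(3 * x) + 0.3 * sex - 0.5 * fd + 0.1 * rng.standard_normal(n)
        data = tmp_path / "d.csv"
        pd.DataFrame({"score": y, "x": x, "sex": sex, "fd": fd}).to_csv(data, index=False)
        rscript = tmp_path / "check.R"
        rscript.write_text(f"""
            library(mgcv)
            d <- read.csv("{data}")
            full <- gam(score ~ s(x, k=10) + sex + fd, data=d, method="REML")
            red <- lm(score ~ sex + fd, data=d)
            pr2 <- (sum(residuals(red)^2) - sum(residuals(full)^2)) / sum(residuals(red)^2)
            grid <- data.frame(x=seq(min(d$x), max(d$x), length.out=200),
                               sex=mean(d$sex), fd=mean(d$fd))
            out <- data.frame(x=grid$x, pred=predict(full, grid))
            write.csv(out, "{tmp_path / 'pred.csv'}", row.names=FALSE)
            cat(sprintf("%.8f", pr2))
        """)
        res = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        pr2_mgcv = float(res.stdout.strip().splitlines()[-1])
        pred_mgcv = pd.read_csv(tmp_path / "pred.csv")["pred"].to_numpy()
        fit = fit_trajectory(obs_frame(x, y, sex, fd))
        assert fit.partial_r2 == pytest.approx(pr2_mgcv, abs=0.02)
        rmse = np.sqrt(np.mean((fit.fitted_curve[:, 1] - pred_mgcv) ** 2))
        assert rmse < 0.05 * np.ptp(pred_mgcv)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SyntheticCohortSpec(
        n_subjects=16, n_regions_per_class=(6, 6, 6), n_frames=1200, seed=21))


@pytest.fixture(scope="module")
def scores(cohort):
    return [score_scan(s) for s in cohort.scans]


class TestBatchAndAge:
    def test_regime_recovery(self, cohort, scores):
        fits, failures = fit_all_regions(scores, cohort.covariates)
        assert not failures
        cls = dict(zip(cohort.geometry["region_id"], cohort.geometry["region_class"]))
        regimes = {f.region_id: f.regime for f in fits}
        s_ok = np.mean([regimes[r] == "increasing" for r in regimes if cls[r] == "S"])
        l_ok = np.mean([regimes[r] == "decreasing" for r in regimes if cls[r] == "L"])
        assert s_ok >= 0.9 and l_ok >= 0.9

    def test_shuffled_scores_control_type_one_error(self, cohort, scores):
        """Destroying the amplitude-score link leaves few significant smooths."""
        rng = np.random.default_rng(0)
        shuffled = []
        for m in scores:
            s = m.scores.copy()
            for i in range(s.shape[0]):
                rng.shuffle(s[i])
            shuffled.append(type(m)(
                scores=s, bin_mean_global=m.bin_mean_global, n_bins=m.n_bins,
                region_ids=m.region_ids, subject_id=m.subject_id))
        fits, _ = fit_all_regions(shuffled, cohort.covariates)
        frac_sig = np.mean([f.p_smooth < 0.05 for f in fits])
        assert frac_sig <= 0.10

    def test_single_region_batch(self, cohort, scores):
        from cofluct.scoring import ScoreMatrix

        one = [ScoreMatrix(
            scores=m.scores[:1], bin_mean_global=m.bin_mean_global,
            n_bins=m.n_bins, region_ids=m.region_ids[:1],
            subject_id=m.subject_id) for m in scores]
        fits, failures = fit_all_regions(one, cohort.covariates)
        assert len(fits) == 1 and not failures

    def test_age_effect_null_when_development_off(self, cohort, scores):
        res = age_effect(scores, cohort.covariates, (0.9, 1.0))
        assert (res["p_value"] < 0.05).mean() <= 0.10

    def test_age_effect_recovers_development(self):
        spec = SyntheticCohortSpec(
            n_subjects=24, n_regions_per_class=(6, 6, 6), n_frames=1200,
            age_range=(6.0, 18.0), dev_sharpening=0.08, seed=5)
        cohort = generate_cohort(spec)
        scores = [score_scan(s) for s in cohort.scans]
        res = age_effect(scores, cohort.covariates, (0.9, 1.0))
        cls = dict(zip(cohort.geometry["region_id"], cohort.geometry["region_class"]))
        s_effects = res[res["region_id"].map(cls) == "S"]["age_effect"]
        assert (s_effects > 0).mean() > 0.5

    def test_age_effect_degenerate_ages(self, cohort, scores):
        cov = cohort.covariates.copy()
        cov["age"] = 30.0
        with pytest.raises(ValueError, match="distinct ages"):
            age_effect(scores, cov, (0.9, 1.0))


class TestTrajectorySimilarity:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 2, 3, 5), (1, 2, 3, 5), 1.0),
        ((1, 2, 3, 5), (5, 3, 2, 1), -1.0),
        ((1, 2, 3, 5), (1, 3, 2, 5), 0.8),
    ])
    def test_known_rank_correlations(self, a, b, expected):
        assert trajectory_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(trajectory_similarity((1, 1, 1, 1), (1, 2, 3, 4)))
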