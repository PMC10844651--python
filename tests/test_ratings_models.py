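import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyadsync.ratings_models import (
    ModelConfig,
    RatingsError,
    compute_accuracy,
    compute_waic,
    fit_accuracy_model,
    fit_enjoyment_model,
    hpd_interval,
    posterior_mass_beyond_zero,
    zscore_predictors,
)

# fast sampler settings for unit-level fits (diagnostics gate relaxed)
FAST = dict(chains=2, draws=400, warmup=300, check_convergence=False)


class TestComputeAccuracy:
    @pytest.mark.parametrize(
        "sim,est,expected",
        [(0.50, 50, 0.0), (0.78, 50, 28.0), (0.20, 80, -60.0)],
    )
    def test_values(self, sim, est, expected):
        assert compute_accuracy(sim, est) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(RatingsError):
            compute_accuracy(1.2, 50)
        with pytest.raises(RatingsError):
            compute_accuracy(0.5, 101)

    def test_antisymmetric_in_estimate(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            sim = rng.uniform(0, 1)
            est = rng.uniform(0, 90)
            d = rng.uniform(0, 10)
            assert compute_accuracy(sim, est + d) == pytest.approx(
                compute_accuracy(sim, est) - d)


class TestZscore:
    def test_symmetric_case(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = zscore_predictors(df, ["x"])
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        once = zscore_predictors(df, ["x"])
        twice = zscore_predictors(once, ["x"])
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-9)

    def test_constant_errors(self):
        with pytest.raises(RatingsError, match="x"):
            zscore_predictors(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])

    def test_moments(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.exponential(size=500)})
        out = zscore_predictors(df, ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestHpdInterval:
    def test_degenerate(self):
        lo, hi = hpd_interval(np.full(200, 3.3))
        assert (lo, hi) == (3.3, 3.3)

    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_exponential_skew(self):
        draws = np.random.default_rng(1).exponential(1.0, 100_000)
        lo, hi = hpd_interval(draws, 0.95)
        eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
        assert lo < 0.02
        assert (hi - lo) < (eq_hi - eq_lo)

    def test_width_never_exceeds_equal_tailed(self):
        for seed, dist in enumerate((stats.norm, stats.expon, stats.gamma(2),
                                     stats.lognorm(0.8), stats.t(3))):
            draws = dist.rvs(size=20_000, random_state=seed)
            lo, hi = hpd_interval(draws, 0.95)
            eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
            assert (hi - lo) <= (eq_hi - eq_lo) + 1e-12

    def test_too_few_draws(self):
        with pytest.raises(RatingsError):
            hpd_interval(np.arange(50.0))


class TestMassBeyondZero:
    def test_all_negative(self):
        assert posterior_mass_beyond_zero(-np.arange(1.0, 200.0)) == 1.0

    def test_symmetric(self):
        draws = np.random.default_rng(2).standard_normal(100_000)
        assert posterior_mass_beyond_zero(draws) == pytest.approx(0.5, abs=0.01)

    def test_shifted_normal(self):
        draws = np.random.default_rng(3).normal(-1.17, 1.0, 100_000)
        expected = stats.norm.cdf(0, loc=-1.17)  # ~0.879
        assert posterior_mass_beyond_zero(draws) == pytest.approx(expected, abs=0.01)


class TestWaic:
    def test_zero_variance_single_obs(self):
        ll = np.full((500, 1), -2.5)
        assert compute_waic(ll) == pytest.approx(5.0, abs=1e-12)

    def test_duplication_doubles(self):
        rng = np.random.default_rng(4)
        ll = rng.normal(-1.0, 0.1, size=(400, 30))
        doubled = np.hstack([ll, ll])
        assert compute_waic(doubled) == pytest.approx(2 * compute_waic(ll), abs=1e-9)

    def test_nonfinite_rejected(self):
        ll = np.zeros((200, 3))
        ll[0, 0] = np.inf
        with pytest.raises(RatingsError):
            compute_waic(ll)


def _accuracy_data(seed, n_participants=30, n_clips=20, alpha_high=28.0, alpha_low=28.0,
                   slope_low_bc=0.0, sigma=5.0):
    """Direct simulation from the accuracy likelihood (no kinematics)."""
    rng = np.random.default_rng(seed)
    bc = rng.standard_normal(n_participants)
    rows = []
    conditions = ["high" if i % 4 else "low" for i in range(n_clips)]
    for p in range(n_participants):
        for c in range(n_clips):
            is_high = conditions[c] == "high"
            mu = (alpha_high if is_high else alpha_low) + (
                0.0 if is_high else slope_low_bc * bc[p])
            rows.append({
                "participant_id": f"P{p}",
                "clip_id": f"c{c}",
                "condition": conditions[c],
                "body_competence": bc[p],
                "difference": mu + sigma * rng.standard_normal(),
            })
    return pd.DataFrame(rows)


class TestAccuracyModel:
    def test_null_slopes_recovered(self):
        df = _accuracy_data(0)
        fit = fit_accuracy_model(df, ["body_competence"], ModelConfig(seed=0, **FAST))
        s = fit.summary.set_index("parameter")
        for cond in ("high", "low"):
            row = s.loc[f"beta[{cond},body_competence]"]
            assert row["hpd_lo"] <= 0.0 <= row["hpd_hi"]
        assert s.loc["alpha[high]", "hpd_lo"] <= 28.0 <= s.loc["alpha[high]", "hpd_hi"]

    def test_targeted_low_condition_slope(self):
        df = _accuracy_data(1, slope_low_bc=-2.0)
        fit = fit_accuracy_model(df, ["body_competence"], ModelConfig(seed=1, **FAST))
        s = fit.summary.set_index("parameter")
        low = s.loc["beta[low,body_competence]"]
        high = s.loc["beta[high,body_competence]"]
        assert low["hpd_lo"] <= -2.0 <= low["hpd_hi"]
        assert high["hpd_lo"] <= 0.0 <= high["hpd_hi"]

    def test_distributional_sigmas(self):
        # different residual SD per condition must be recovered separately
        rng = np.random.default_rng(2)
        rows = []
        for p in range(25):
            for c in range(24):
                cond = "high" if c % 2 else "low"
                sd = 3.0 if cond == "high" else 9.0
                rows.append({"participant_id": f"P{p}", "clip_id": f"c{c}",
                             "condition": cond,
                             "difference": 20.0 + sd * rng.standard_normal()})
        fit = fit_accuracy_model(pd.DataFrame(rows), [], ModelConfig(seed=2, **FAST))
        s = fit.summary.set_index("parameter")
        assert s.loc["sigma[high]", "hpd_lo"] <= 3.0 <= s.loc["sigma[high]", "hpd_hi"]
        assert s.loc["sigma[low]", "hpd_lo"] <= 9.0 <= s.loc["sigma[low]", "hpd_hi"]

    def test_missing_condition_errors(self):
        df = _accuracy_data(3)
        df["condition"] = "high"
        with pytest.raises(RatingsError):
            fit_accuracy_model(df, [], ModelConfig(seed=0, **FAST))

    def test_summary_schema(self):
        fit = fit_accuracy_model(_accuracy_data(4), ["body_competence"],
                                 ModelConfig(seed=3, **FAST))
        assert list(fit.summary.columns) == [
            "parameter", "part", "condition", "mean", "hpd_lo", "hpd_hi",
            "mass_beyond_zero", "rhat", "ess"]
        assert ((fit.summary["mass_beyond_zero"] >= 0.5)
                & (fit.summary["mass_beyond_zero"] <= 1.0)).all()
        assert (fit.summary["hpd_lo"] <= fit.summary["mean"]).all()
        assert (fit.summary["mean"] <= fit.summary["hpd_hi"]).all()

    def test_waic_model_comparison(self):
        # true sloped model should beat intercept-only on sloped data
        wins = 0
        for seed in range(5):
            df = _accuracy_data(seed + 10, n_participants=20, n_clips=12,
                                slope_low_bc=-4.0, sigma=3.0)
            cfg = ModelConfig(seed=seed, chains=2, draws=300, warmup=250,
                              check_convergence=False)
            full = fit_accuracy_model(df, ["body_competence"], cfg)
            null = fit_accuracy_model(df, [], cfg)
            if compute_waic(full.pointwise_loglik()) < compute_waic(null.pointwise_loglik()):
                wins += 1
        assert wins >= 4


def _enjoyment_data(seed, n_participants=40, n_clips=25, p_low=0.2, mu=55.0,
                    empathy_slope=0.0, sigma=8.0):
    rng = np.random.default_rng(seed)
    empathy = rng.standard_normal(n_participants)
    rows = []
    for p in range(n_participants):
        for c in range(n_clips):
            if rng.random() < p_low:
                value = rng.uniform(0, 10)
            else:
                value = np.clip(mu + empathy_slope * empathy[p]
                                + sigma * rng.standard_normal(), 11, 100)
            rows.append({"participant_id": f"P{p}", "clip_id": f"c{c}",
                         "empathy": empathy[p], "value": value})
    return pd.DataFrame(rows)


class TestEnjoymentModel:
    def test_no_low_ratings_degenerate(self):
        df = _enjoyment_data(0, p_low=0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_enjoyment_model(df, ["empathy"], ModelConfig(seed=0, **FAST))
        g0 = fit.draws["inflation_gamma"][:, :, 0].ravel()
        p = 1.0 / (1.0 + np.exp(-g0))
        assert np.quantile(p, 0.95) < 0.01

    def test_constant_inflation_probability(self):
        # ~6,000 trials at true p=0.2 -> posterior mean within binomial error
        df = _enjoyment_data(1, n_participants=100, n_clips=60, p_low=0.2)
        fit = fit_enjoyment_model(df, [], ModelConfig(seed=1, **FAST))
        g0 = fit.draws["inflation_gamma"][:, :, 0].ravel()
        p = float(np.mean(1.0 / (1.0 + np.exp(-g0))))
        assert 0.17 < p < 0.23

    def test_empathy_slope_on_continuous_part(self):
        df = _enjoyment_data(2, empathy_slope=3.0)
        fit = fit_enjoyment_model(df, ["empathy"], ModelConfig(seed=2, **FAST))
        s = fit.summary.set_index("parameter")
        row = s.loc["delta[empathy]"]
        assert row["hpd_lo"] <= 3.0 <= row["hpd_hi"]
        assert row["part"] == "continuous"

    def test_parts_are_independent(self):
        # perturbing only ratings > 10 must leave inflation draws unchanged
        df = _enjoyment_data(3)
        cfg = ModelConfig(seed=5, **FAST)
        fit1 = fit_enjoyment_model(df, ["empathy"], cfg)
        df2 = df.copy()
        high = df2["value"] > 10
        df2.loc[high, "value"] = np.clip(df2.loc[high, "value"] + 7.0, 11, 100)
        fit2 = fit_enjoyment_model(df2, ["empathy"], cfg)
        np.testing.assert_allclose(fit1.draws["inflation_gamma"],
                                   fit2.draws["inflation_gamma"], atol=1e-12)

    def test_missing_column(self):
        with pytest.raises(RatingsError, match="value"):
            fit_enjoyment_model(pd.DataFrame({"participant_id": [], "clip_id": []}),
                                [], ModelConfig(seed=0, **FAST))


class TestModelConfig:
    def test_reported_fit_floor(self):
        with pytest.raises(RatingsError):
            ModelConfig(chains=1, draws=500)

    def test_exploratory_allowed(self):
        ModelConfig(chains=1, draws=500, check_convergence=False)
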