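import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sackcog.instances import load_trial_difficulty_profiles
from sackcog.stats import (
    MixedModelResults,
    ModelSpec,
    default_ladder,
    difficulty_correlations,
    dominance_check,
    ecdf_band,
    effect_reversal_analysis,
    fit_logistic_intercept,
    fit_mixed_model,
    model_selection,
    wilcoxon_squared_effects,
)


# ---------------------------------------------------------------------------
# ECDF bands (Greenwood, uncensored)
# ---------------------------------------------------------------------------

class TestECDFBand:
    def test_degenerate_sample_jumps_and_clips(self):
        band = ecdf_band(np.full(50, 3.0))
        assert band.grid.tolist() == [3.0]
        assert band.F[0] == 1.0
        assert band.lower[0] <= 1.0 and band.upper[0] == 1.0

    def test_band_width_matches_closed_form(self):
        rng = np.random.default_rng(1)
        n = 10_000
        band = ecdf_band(rng.uniform(size=n))
        i = np.argmin(np.abs(band.F - 0.5))
        width = band.upper[i] - band.lower[i]
        expected = 2 * 1.959963985 * np.sqrt(0.25 / n)
        assert width == pytest.approx(expected, rel=0.10)

    def test_bounds_within_unit_interval_and_F_monotone(self):
        rng = np.random.default_rng(2)
        band = ecdf_band(rng.normal(size=500))
        assert (band.lower >= 0).all() and (band.upper <= 1).all()
        assert (band.lower <= band.F).all() and (band.F <= band.upper).all()
        assert (np.diff(band.F) >= 0).all()

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ecdf_band([1.0])

    def test_pointwise_coverage_at_median(self):
        """95% Greenwood bands contain the true CDF value at the median in
        ~95% of replicates (uniform samples, n=100)."""
        rng = np.random.default_rng(3)
        n, reps, hit = 100, 1000, 0
        for _ in range(reps):
            band = ecdf_band(rng.uniform(size=n))
            _, lo, hi = band.evaluate(np.array([0.5]))
            hit += lo[0] <= 0.5 <= hi[0]
        assert 0.92 <= hit / reps <= 0.98


class TestPlot:
    def test_band_plot_renders(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from sackcog.stats import plot_ecdf_bands

        rng = np.random.default_rng(40)
        ax = plot_ecdf_bands(
            {"PLC": ecdf_band(rng.normal(size=100)),
             "drug": ecdf_band(rng.normal(0.5, 1, 100))},
            title="value fraction",
        )
        fig = ax.get_figure()
        out = tmp_path / "ecdf.png"
        fig.savefig(out)
        assert out.stat().st_size > 0


class TestDominance:
    def test_identical_samples_no_separation(self):
        x = np.random.default_rng(4).normal(size=300)
        rep = dominance_check(ecdf_band(x), ecdf_band(x))
        assert rep.frac_separated == 0.0
        assert rep.direction == "none"

    def test_clear_shift_separates_majority_of_grid(self):
        rng = np.random.default_rng(5)
        a = rng.normal(2, 1, 500)      # larger values: CDF of A lies below
        b = rng.normal(0, 1, 500)
        rep = dominance_check(ecdf_band(a), ecdf_band(b))
        assert rep.frac_a_below > 0.5
        assert rep.direction == "A"

    def test_null_shift_rarely_separates(self):
        rng = np.random.default_rng(6)
        fracs = [
            dominance_check(
                ecdf_band(rng.normal(size=200)), ecdf_band(rng.normal(size=200))
            ).frac_separated
            for _ in range(50)
        ]
        assert np.mean(fracs) < 0.02


# ---------------------------------------------------------------------------
# Wilcoxon on squared effects
# ---------------------------------------------------------------------------

def wilcoxon_exact_enumeration(d):
    """Full 2^n sign-flip enumeration of the signed-rank null; oracle."""
    d = np.asarray(d, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    # two-sided: distance from the mean of the null distribution
    mu = n * (n + 1) / 4
    p = np.mean(np.abs(stats - mu) >= np.abs(w_obs - mu) - 1e-12)
    return min(1.0, p)


class TestWilcoxonSquaredEffects:
    def test_shrunken_effects_detected(self):
        rng = np.random.default_rng(7)
        plc = rng.normal(0, 1, 10)
        drug = plc * 0.1
        stat, p = wilcoxon_squared_effects(plc, drug)
        assert p < 0.01

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(0, 1, 9)
            b = rng.normal(0, 1, 9)
            d = a**2 - b**2
            _, p = wilcoxon_squared_effects(a, b)
            assert p == pytest.approx(wilcoxon_exact_enumeration(d), abs=1e-12)

    def test_degenerate_identical_squares_raise(self):
        a = np.array([1.0, -2.0, 3.0, -1.0, 2.0, -3.0])
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_squared_effects(a, -a)   # squares identical pairwise

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="6"):
            wilcoxon_squared_effects([1, 2, 3], [1, 2, 4])

    def test_null_p_values_approximately_uniform(self):
        """Exchangeable pairs give ~Uniform(0,1) p-values (KS check)."""
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(500):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            ps.append(wilcoxon_squared_effects(a, b)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# difficulty-metric correlations
# ---------------------------------------------------------------------------

class TestDifficultyCorrelations:
    def test_published_fixture_reproduces_published_matrix(self):
        rep = difficulty_correlations(load_trial_difficulty_profiles())
        r = rep.rounded(2)
        assert r.loc["sahni_k", "dp_complexity"] == 0.08
        assert r.loc["sahni_k", "minizinc_props"] == 0.20
        assert r.loc["dp_complexity", "minizinc_props"] == 0.52

    def test_self_correlation_is_one(self):
        rep = difficulty_correlations(load_trial_difficulty_profiles())
        assert np.allclose(np.diag(rep.corr.values), 1.0)

    def test_fisher_se(self):
        rep = difficulty_correlations(load_trial_difficulty_profiles())
        assert rep.se_z == pytest.approx(1 / np.sqrt(8 - 3))

    def test_constant_metric_rejected(self):
        from sackcog.instances import DifficultyProfile

        profiles = [
            DifficultyProfile(f"i{k}", sahni_k=2, dp_complexity=100 + k,
                              minizinc_props=1000 + k)
            for k in range(5)
        ]
        with pytest.raises(ValueError, match="sahni_k"):
            difficulty_correlations(profiles)


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def simulate_logistic_cohort(rng, n_g=40, n_per=16, b0=-0.5, b1=0.8, sd=0.5):
    b = rng.normal(0, sd, n_g)
    g = np.repeat(np.arange(n_g), n_per)
    x = rng.normal(size=n_g * n_per)
    eta = b0 + b1 * x + b[g]
    y = (rng.random(len(eta)) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame(
        {"correct": y, "sahni_k": x, "participant_id": [f"P{i:03d}" for i in g],
         "condition": "PLC"}
    )


class TestMixedModels:
    def test_gaussian_without_random_terms_equals_ols(self, cohort_metrics):
        import statsmodels.formula.api as smf

        fit = fit_mixed_model(ModelSpec("time_s", ("sahni_k",), "none"), cohort_metrics)
        ols = smf.ols("time_s ~ sahni_k", cohort_metrics).fit()
        pd.testing.assert_series_equal(fit.params, ols.params, rtol=1e-10)
        assert fit.llf == pytest.approx(ols.llf)

    def test_aic_bic_recomputable_identity(self, cohort_metrics):
        for spec in (ModelSpec("time_s", ("sahni_k", "drug"), "intercept"),
                     ModelSpec("correct", ("sahni_k", "drug"), "intercept")):
            fit = fit_mixed_model(spec, cohort_metrics)
            assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.n_params)
            assert fit.bic == pytest.approx(
                -2 * fit.llf + np.log(fit.nobs) * fit.n_params
            )

    def test_logistic_random_intercept_recovers_truth(self):
        rng = np.random.default_rng(11)
        data = simulate_logistic_cohort(rng)
        fit = fit_mixed_model(ModelSpec("correct", ("sahni_k",), "intercept"), data)
        est, se = fit.params, fit.bse
        assert abs(est["Intercept"] - (-0.5)) < 3 * se["Intercept"]
        assert abs(est["sahni_k"] - 0.8) < 3 * se["sahni_k"]
        assert 0.1 < np.sqrt(fit.cov_re.iloc[0, 0]) < 1.2

    def test_logistic_fitter_agrees_with_lme4(self, tmp_path):
        """Independent cross-check of the quadrature ML fit against glmer."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the lme4 cross-check")
        rng = np.random.default_rng(12)
        data = simulate_logistic_cohort(rng, n_g=30, n_per=12)
        csv = tmp_path / "d.csv"
        data.rename(columns={"correct": "y", "sahni_k": "x",
                             "participant_id": "g"}).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15)\n"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep=',')\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        b0, b1, sd, llf = map(float, out.stdout.strip().split(","))
        fit = fit_mixed_model(ModelSpec("correct", ("sahni_k",), "intercept"), data)
        assert fit.params["Intercept"] == pytest.approx(b0, abs=1e-3)
        assert fit.params["sahni_k"] == pytest.approx(b1, abs=1e-3)
        assert np.sqrt(fit.cov_re.iloc[0, 0]) == pytest.approx(sd, abs=2e-3)
        assert fit.llf == pytest.approx(llf, abs=1e-3)

    def test_missing_column_rejected(self, cohort_metrics):
        with pytest.raises(ValueError, match="nonexistent"):
            fit_mixed_model(
                ModelSpec("time_s", ("nonexistent",), "none"), cohort_metrics
            )


class TestModelSelection:
    def test_single_candidate_returned(self, cohort_metrics):
        spec = ModelSpec("time_s", ("sahni_k",), "intercept")
        best, ladder = model_selection([spec], cohort_metrics)
        assert best.spec == spec
        assert len(ladder) == 1

    def test_bic_prefers_smaller_model_when_extra_term_is_noise(self):
        """Consistency: with a pure-noise regressor and plenty of data, BIC
        picks the nested smaller model in the vast majority of replicates."""
        rng = np.random.default_rng(13)
        wins = 0
        for _ in range(30):
            n = 2000
            g = np.repeat(np.arange(20), n // 20)
            x = rng.normal(size=n)
            noise_reg = rng.normal(size=n)
            y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
            df = pd.DataFrame(
                {"time_s": y, "sahni_k": x, "dp_complexity": noise_reg,
                 "participant_id": [f"P{i}" for i in g], "condition": "PLC"}
            )
            cands = [ModelSpec("time_s", ("sahni_k",), "none"),
                     ModelSpec("time_s", ("sahni_k", "dp_complexity"), "none")]
            best, _ = model_selection(cands, df, "BIC")
            wins += best.spec == cands[0]
        assert wins >= 27

    def test_ladder_reports_failures_and_proceeds(self, cohort_metrics):
        # a constant-outcome model fails; selection proceeds over survivors
        broken = cohort_metrics.copy()
        specs = default_ladder("time_s")
        best, ladder = model_selection(specs, broken)
        assert not ladder.iloc[0]["failed"]
        assert best.llf == pytest.approx(ladder.iloc[0]["loglik"])

    def test_per_condition_random_structure_recovered(self, instance_bank):
        """When the generator injects condition-dependent heterogeneity, the
        criterion prefers per-condition random effects for most cohorts."""
        from sackcog.behavior import score_dataset
        from sackcog.simulate import CohortDesign, ConditionEffects, simulate_cohort

        design = CohortDesign(n_participants=16, n_instances=8)
        wins = 0
        reps = 6
        for s in range(reps):
            logs = simulate_cohort(design, ConditionEffects(), instance_bank,
                                   seed=3000 + s)
            m, _ = score_dataset(logs, instance_bank)
            cands = [ModelSpec("productivity", ("sahni_k", "drug"), "intercept"),
                     ModelSpec("productivity", ("sahni_k", "drug"), "condition")]
            best, _ = model_selection(cands, m, "AIC")
            wins += best.spec.random == "condition"
        assert wins >= reps // 2 + 1


class TestReversalAnalysis:
    @staticmethod
    def _fake_fit(re_df, cov):
        spec = ModelSpec("productivity", ("sahni_k", "condition"), "condition")
        return MixedModelResults(
            spec=spec, params=pd.Series({"Intercept": 0.0}),
            bse=pd.Series({"Intercept": 1.0}), llf=0.0, n_params=1,
            nobs=len(re_df) * 4, n_groups=len(re_df),
            random_effects=re_df,
            cov_re=pd.DataFrame(cov, index=re_df.columns, columns=re_df.columns),
        )

    def test_identity_map(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 12)
        re_df = pd.DataFrame({"PLC": a, "MPH": a})
        rep = effect_reversal_analysis(
            self._fake_fit(re_df, [[1.0, 1.0], [1.0, 1.0]]), "PLC", "MPH")
        assert rep.range_ratio == pytest.approx(1.0)
        assert rep.ols_slope == pytest.approx(1.0)
        assert rep.corr == pytest.approx(1.0, abs=1e-4)

    def test_exact_negative_half_map(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 12)
        re_df = pd.DataFrame({"PLC": a, "MPH": -0.5 * a})
        cov = [[1.0, -0.5], [-0.5, 0.25]]
        rep = effect_reversal_analysis(self._fake_fit(re_df, cov), "PLC", "MPH")
        assert rep.ols_slope == pytest.approx(-0.5)
        assert rep.range_ratio == pytest.approx(0.5)
        assert rep.corr == pytest.approx(-1.0, abs=1e-4)

    def test_injected_cross_condition_correlation_recovered(self):
        """Gaussian per-condition model recovers a negative cross-condition
        random-effect correlation from data simulated with it."""
        rng = np.random.default_rng(16)
        rho_true = -0.4
        errs = []
        for _ in range(5):
            n_g, n_per = 40, 16
            cov = np.array([[1.0, rho_true], [rho_true, 1.0]]) * 0.25
            b = rng.multivariate_normal([0, 0], cov, n_g)
            rows = []
            for i in range(n_g):
                for c, cond in enumerate(["PLC", "MPH"]):
                    for _ in range(n_per):
                        rows.append(
                            {"participant_id": f"P{i:02d}", "condition": cond,
                             "time_s": 1.0 + b[i, c] + rng.normal(0, 0.5),
                             "sahni_k": 0.0}
                        )
            df = pd.DataFrame(rows)
            fit = fit_mixed_model(ModelSpec("time_s", ("condition",), "condition"), df)
            corr = fit.random_effect_correlations().iloc[0]["corr"]
            errs.append(corr - rho_true)
        assert np.mean(np.abs(errs)) < 0.15
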