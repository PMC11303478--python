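"""Plot-level phenotype generation: environment means, errors, MET assembly."""
import numpy as np
import pytest

import gxesim as g
from gxesim import phenotype as ph
from gxesim.errors import ParameterError, ShapeError


class TestEnvironmentMeans:
    def test_zero_variance_gives_zeros(self):
        tau = ph.simulate_environment_means(6, g.EnvironmentalEffects(sigma2_e=0.0), seed=1)
        np.testing.assert_array_equal(tau, 0.0)

    def test_iid_variance_matches(self):
        n = 100_000
        tau = ph.simulate_environment_means(n, g.EnvironmentalEffects(sigma2_e=1.0), seed=2)
        assert abs(tau.var(ddof=1) - 1.0) < 3 * np.sqrt(2 / n)

    def test_regression_mode_deterministic(self, low_terms):
        eff = g.EnvironmentalEffects(mode="covariate_regression", tau_s=np.zeros(7))
        tau = ph.simulate_environment_means(5, eff, covariates=low_terms.covariates[:5])
        np.testing.assert_array_equal(tau, 0.0)
        eff2 = g.EnvironmentalEffects(mode="covariate_regression", tau_s=np.ones(7))
        tau2 = ph.simulate_environment_means(5, eff2, covariates=low_terms.covariates[:5])
        np.testing.assert_allclose(tau2, low_terms.covariates[:5].sum(axis=1))

    def test_regression_mode_needs_covariates(self):
        eff = g.EnvironmentalEffects(mode="covariate_regression", tau_s=np.zeros(3))
        with pytest.raises(ParameterError):
            ph.simulate_environment_means(5, eff)


class TestPlotErrors:
    def test_zero_variance(self):
        design = g.TrialDesign(10, 2, 2)
        err = g.simulate_plot_errors(design, g.PlotErrorSpec(0.0), seed=1)
        np.testing.assert_array_equal(err, 0.0)

    def test_independent_variance_matches(self):
        design = g.TrialDesign(5000, 10, 2)  # 10^5 plots
        spec = g.PlotErrorSpec(4.0, heterogeneous=False)
        err = g.simulate_plot_errors(design, spec, seed=3)
        n = err.size
        assert abs(err.var(ddof=1) - 4.0) < 3 * 4.0 * np.sqrt(2 / n)

    def test_heterogeneous_variances_average_to_mean(self):
        spec = g.PlotErrorSpec(4.0, het_shape=10.0)
        v = ph.per_environment_error_variances(spec, 5000, seed=4)
        assert np.all(v > 0)
        # gamma with shape 10 rescaled to mean 4: SE of mean = 4/sqrt(10*p)
        assert abs(v.mean() - 4.0) < 3 * 4.0 / np.sqrt(10 * 5000)

    def test_ar1_lag_one_correlation(self):
        design = g.TrialDesign(n_genotypes=500, n_envs=1, n_blocks=2,
                               n_rows=10, n_cols=100)
        spec = g.PlotErrorSpec(1.0, heterogeneous=False, correlation="ar1",
                               ar1_row=0.5, ar1_col=0.0)
        err = g.simulate_plot_errors(design, spec, seed=5).reshape(10, 100)
        lag1 = np.corrcoef(err[:-1].ravel(), err[1:].ravel())[0, 1]
        assert lag1 == pytest.approx(0.5, abs=3 / np.sqrt(900))

    def test_spatial_mode_needs_grid(self):
        design = g.TrialDesign(10, 2, 2)
        spec = g.PlotErrorSpec(1.0, correlation="ar1", ar1_row=0.5)
        with pytest.raises(ParameterError):
            g.simulate_plot_errors(design, spec, seed=0)


class TestErrorVarianceFromHeritability:
    def test_symmetric_point(self):
        assert g.error_variance_from_heritability(1.0, 0.5) == pytest.approx(1.0)

    def test_low_heritability_example(self):
        assert g.error_variance_from_heritability(1.73, 0.3) == pytest.approx(4.03, abs=0.01)

    def test_limits_and_validation(self):
        assert g.error_variance_from_heritability(1.0, 1 - 1e-9) == pytest.approx(0.0, abs=1e-8)
        with pytest.raises(ParameterError):
            g.error_variance_from_heritability(1.0, 0.0)


def _small_met(v=20, p_m=4, r=2, mu=4.0, seed=11):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(v, p_m))
    tau = rng.normal(size=p_m)
    design = g.TrialDesign(v, p_m, r, trait_mean=mu)
    env_vars = np.full(p_m, 2.0)
    errors = g.simulate_plot_errors(design, g.PlotErrorSpec(2.0, heterogeneous=False),
                                    seed=seed + 1, env_variances=env_vars)
    met = g.build_met_dataset(u, tau, errors, design, mu=mu, seed=seed + 2,
                              metadata={"error_variances": env_vars})
    return met, u, tau, errors


class TestMETDataset:
    def test_row_count_matches_design(self):
        met, *_ = _small_met(v=400, p_m=10, r=2)
        assert met.n_plots == 8000

    def test_single_plot_trivial_case(self):
        design = g.TrialDesign(1, 1, 1, trait_mean=4.0)
        met = g.build_met_dataset(np.zeros((1, 1)), np.zeros(1), np.zeros(1), design,
                                  metadata={"error_variances": np.zeros(1)})
        assert met.data["phenotype"].iloc[0] == pytest.approx(4.0)

    def test_rcbd_completeness(self):
        met, *_ = _small_met()
        counts = met.data.groupby(["env_id", "block"])["genotype_id"].nunique()
        assert (counts == 20).all()
        assert len(met.data) == met.data.groupby(["env_id", "block"]).size().sum()

    def test_phenotype_decomposition_exact(self):
        # the stored truth columns reproduce the phenotype bit-for-bit and
        # the plot-error column is the generated error vector in plot order
        met, u, tau, errors = _small_met()
        df = met.data
        env_idx = (df["env_id"].str.lstrip("E").astype(int) - 1).to_numpy()
        rebuilt = (4.0 + tau[env_idx] + df["true_ge_effect"].to_numpy()) + df["plot_error"].to_numpy()
        np.testing.assert_array_equal(rebuilt, df["phenotype"].to_numpy())
        np.testing.assert_array_equal(df["plot_error"].to_numpy(), errors)

    def test_environment_means_recovered(self):
        met, u, tau, _ = _small_met(v=2000, p_m=3, r=2, seed=21)
        for j, env in enumerate(["E1", "E2", "E3"]):
            got = met.data[met.data["env_id"] == env]["phenotype"].mean()
            se = np.sqrt((u[:, j].var() + 2.0) / 4000)
            assert abs(got - (4.0 + tau[j] + u[:, j].mean())) < 3 * se

    def test_dimension_mismatch(self):
        design = g.TrialDesign(3, 2, 1)
        with pytest.raises(ShapeError):
            g.build_met_dataset(np.zeros((4, 2)), np.zeros(2), np.zeros(6), design)


class TestSummary:
    def test_heritability_from_truth(self):
        met, u, tau, _ = _small_met()
        out = g.summarise_met(met)
        env_rows = out[out["env_id"] != "Overall"]
        s2g = u.var(axis=0, ddof=1)
        np.testing.assert_allclose(env_rows["sigma2_g"], s2g, atol=1e-12)
        np.testing.assert_allclose(env_rows["H2"], s2g / (s2g + 2.0), atol=1e-12)
        overall = out[out["env_id"] == "Overall"].iloc[0]
        assert overall["n_plots"] == met.n_plots
        assert overall["H2"] == pytest.approx(env_rows["H2"].mean())

    @pytest.mark.parametrize(
        "s2g, s2e, h2", [(4.81, 3.94, 0.55), (0.07, 3.96, 0.02), (1.0, 0.0, 1.0)]
    )
    def test_heritability_ratio(self, s2g, s2e, h2):
        assert s2g / (s2g + s2e) == pytest.approx(h2, abs=0.005)

    def test_missing_truth_rejected(self):
        design = g.TrialDesign(2, 1, 1)
        met = g.build_met_dataset(np.zeros((2, 1)), np.zeros(1), np.zeros(2), design)
        met.metadata.pop("error_variances", None)
        with pytest.raises(ParameterError):
            g.summarise_met(met)


def test_per_environment_genetic_variance_tracks_ge_diagonal(low_ge, low_terms):
    # variance budget: empirical per-environment genetic variance matches
    # the sampled Ge diagonal at large v
    v = 20_000
    slopes = g.simulate_slopes(low_terms, v, seed=33)
    u = g.construct_ge_effects(low_terms, slopes).values[:, :5]
    emp = u.var(axis=0, ddof=1)
    target = low_ge.variances[:5]
    assert np.all(np.abs(emp - target) < 3 * target * np.sqrt(2 / v))
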