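import math

import numpy as np
import pandas as pd
import pytest

from psireg.inference import (
    FitConfig,
    PosteriorDraws,
    compute_bayes_r2,
    compute_loo,
    compute_loo_r2,
    compute_rhat,
    diagnostics_report,
    fit_posterior,
    ppc_coverage,
    residual_summaries,
)
from psireg.simulate import SimulationConfig, simulate_daily_records


def _toy_draws(mu, sigma, y, n_draws=400, n_chains=2, jitter=0.0, seed=0, mu_vec=None):
    """Hand-built PosteriorDraws with a controlled predictive mean.

    Every draw predicts ``mu`` (optionally jittered across draws); with
    ``mu_vec`` given, per-record level offsets are set so draw ``s``
    predicts ``mu_vec[i] * theta0_s / mu`` at record ``i``.  The stem of the
    construction is a saturated curve (huge VPD) so the prediction equals
    the level-specific asymptote.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if mu_vec is None:
        levels = ["L0"]
        labels = ["L0"] * n
        rel = np.ones(1)
        level_idx = np.zeros(n, dtype=int)
    else:
        levels = [f"L{i}" for i in range(n)]
        labels = levels
        rel = np.asarray(mu_vec, dtype=float) / mu
        level_idx = np.arange(n)
    records = pd.DataFrame(
        {
            "plant_id": "p1",
            "date": pd.date_range("2022-01-01", periods=n).date,
            "season_label": labels,
            "delta_psi_max": y,
            "vpd_max_day": 1e9,  # saturates the curve: mu == asymptote
            "psi_soil_day": 0.0,
        }
    )
    shape = (n_chains, n_draws)
    theta0 = np.full(shape, mu) + jitter * rng.standard_normal(shape)
    posterior = {
        "theta0": theta0,
        "lambda0": np.full(shape, 1.0),
        "alpha": np.zeros(shape),
        "beta": np.zeros(shape),
        "psi_threshold": np.full(shape, -1.0),
        "sigma": np.full(shape, sigma),
        "sd_log_theta0": np.full(shape, 0.01),
        "sd_log_lambda0": np.full(shape, 0.01),
        "correlation": np.zeros(shape),
        "offset_log_theta0": np.broadcast_to(np.log(rel), shape + (len(levels),)).copy(),
        "offset_log_lambda0": np.zeros(shape + (len(levels),)),
    }
    mu_arr = theta0[..., None] * rel[level_idx][None, None, :]
    ll = (
        -0.5 * math.log(2 * math.pi)
        - math.log(sigma)
        - 0.5 * ((y[None, None, :] - mu_arr) / sigma) ** 2
    )
    return PosteriorDraws(
        posterior=posterior,
        log_likelihood=ll,
        levels=levels,
        records=records,
        config=FitConfig(n_chains=n_chains, n_iterations=2 * n_draws),
    )


class TestFitConfig:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            FitConfig(n_chains=1)

    def test_warmup_fraction_bounds(self):
        with pytest.raises(ValueError):
            FitConfig(warmup_fraction=1.0)


class TestComputeRhat:
    def test_constant_chains_flagged(self):
        draws = _toy_draws(0.8, 0.1, np.array([0.8, 0.7]))
        rhat = compute_rhat(draws, params=["alpha"])  # identically zero draws
        assert math.isnan(rhat["alpha"])

    def test_iid_normal_chains_converged(self):
        rng = np.random.default_rng(0)
        draws = _toy_draws(0.0, 0.1, np.array([0.0]), n_draws=1000, n_chains=4)
        draws.posterior["theta0"] = rng.standard_normal((4, 1000))
        rhat = compute_rhat(draws, params=["theta0"])
        assert rhat["theta0"] < 1.01

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(0)
        draws = _toy_draws(0.0, 0.1, np.array([0.0]), n_draws=500, n_chains=2)
        arr = rng.standard_normal((2, 500))
        arr[1] += 5.0
        draws.posterior["theta0"] = arr
        rhat = compute_rhat(draws, params=["theta0"])
        assert rhat["theta0"] > 1.5

    def test_single_chain_rejected(self):
        draws = _toy_draws(0.8, 0.1, np.array([0.8]), n_chains=2)
        draws.posterior = {k: v[:1] for k, v in draws.posterior.items()}
        with pytest.raises(ValueError, match="2 chains"):
            compute_rhat(draws, params=["theta0"])


class TestLooR2:
    def test_near_perfect_prediction(self):
        # per-point predictions exactly equal the observations (sigma -> 0)
        rng = np.random.default_rng(1)
        y = rng.uniform(0.2, 1.4, 60)
        draws = _toy_draws(0.8, 1e-4, y, mu_vec=y, jitter=1e-7)
        r2, _ci = compute_loo_r2(draws)
        assert r2 > 0.999

    def test_pure_noise_response_near_zero(self):
        rng = np.random.default_rng(2)
        y = 0.8 + 0.2 * rng.standard_normal(120)
        # model predicts the constant mean: explains nothing
        draws = _toy_draws(0.8, 0.2, y, jitter=0.002)
        r2, ci = compute_loo_r2(draws)
        assert abs(r2) < 0.1
        assert ci[0] < r2 < ci[1]

    def test_informative_prediction(self, small_fit):
        _study, draws = small_fit
        r2, ci = compute_loo_r2(draws)
        assert 0.5 < r2 < 1.0
        assert ci[0] < r2 < ci[1]

    def test_loo_r2_close_to_and_below_bayes_r2(self, small_fit):
        """LOO R2 shows the mild optimism gap of the ordinary Bayesian R2."""
        _study, draws = small_fit
        loo_r2, _ = compute_loo_r2(draws)
        bayes_r2, _ = compute_bayes_r2(draws)
        assert loo_r2 <= bayes_r2 + 0.005
        assert abs(bayes_r2 - loo_r2) < 0.03


class TestPpcCoverage:
    def test_tiny_intervals_give_zero(self):
        y = np.array([0.5, 0.6, 0.7, 0.8])
        draws = _toy_draws(1.2, 1e-6, y)  # predictions far off, widths ~0
        assert ppc_coverage(draws) == 0.0

    def test_huge_intervals_give_one(self):
        y = np.array([0.5, 0.6, 0.7, 0.8])
        draws = _toy_draws(0.65, 50.0, y)
        assert ppc_coverage(draws) == 1.0

    def test_well_specified_near_nominal(self):
        rng = np.random.default_rng(3)
        y = 0.9 + 0.1 * rng.standard_normal(600)
        draws = _toy_draws(0.9, 0.1, y, jitter=0.003)
        assert 0.92 <= ppc_coverage(draws) <= 0.98


class TestFitPosterior:
    def test_recovery_and_diagnostics(self, small_fit):
        study, draws = small_fit
        s = draws.summary().set_index("parameter")
        truth = study.params
        for name, val in [
            ("theta0", truth.theta0),
            ("lambda0", truth.lambda0),
            ("sigma", truth.sigma),
        ]:
            assert s.loc[name, "q2.5"] <= val <= s.loc[name, "q97.5"], name
        assert draws.log_likelihood.shape[-1] == len(study.records)
        assert not np.isnan(draws.log_likelihood).any()

    def test_pointwise_loglik_matches_brute_force(self, small_fit):
        """Stored pointwise log-likelihood equals an independent Gaussian
        density evaluation at the posterior draws."""
        study, draws = small_fit
        mu = draws.mu_draws()
        sigma = draws.stacked("sigma")[:, None]
        y = draws.records["delta_psi_max"].to_numpy()
        expected = (
            -0.5 * np.log(2 * np.pi)
            - np.log(sigma)
            - 0.5 * ((y[None, :] - mu) / sigma) ** 2
        )
        stored = draws.log_likelihood.reshape(-1, len(y))
        np.testing.assert_allclose(stored, expected, atol=1e-10)

    def test_seeded_reproducibility(self):
        cfg = SimulationConfig(
            n_plants=2, seasons_per_plant=(1, 1), days_per_season=30, seed=17
        )
        study = simulate_daily_records(cfg)
        fc = FitConfig(n_chains=2, n_iterations=200, seed=99)
        a = fit_posterior(study.records, fc)
        b = fit_posterior(study.records, fc)
        np.testing.assert_array_equal(a.posterior["theta0"], b.posterior["theta0"])
        np.testing.assert_array_equal(a.log_likelihood, b.log_likelihood)

    def test_single_level_warns_and_fits(self, caplog):
        import logging

        cfg = SimulationConfig(
            n_plants=1, seasons_per_plant=(1,), days_per_season=40, seed=23
        )
        study = simulate_daily_records(cfg)
        with caplog.at_level(logging.WARNING):
            draws = fit_posterior(study.records, FitConfig(n_chains=2, n_iterations=200, seed=1))
        assert "fixed effects" in caplog.text
        assert draws.n_draws == 100

    def test_no_threshold_data_recovers_limiting_case(self):
        """On data generated without a changepoint the fitted changepoint
        has no effect: the implied suppression of the asymptote at the
        driest observed soil concentrates at 1 (alpha itself is unidentified
        once the threshold drifts below the observed range)."""
        from dataclasses import replace

        base = SimulationConfig(seed=31, n_plants=3, seasons_per_plant=(1, 1, 1), days_per_season=60)
        cfg = replace(
            base, params=replace(base.params, alpha=0.0, beta=0.0)
        )
        study = simulate_daily_records(cfg)
        draws = fit_posterior(study.records, FitConfig(n_chains=2, n_iterations=600, seed=31))
        psi_min = study.records["psi_soil_day"].min()
        alpha = draws.stacked("alpha")
        thr = draws.stacked("psi_threshold")
        suppression = np.exp(-alpha * np.maximum(thr - psi_min, 0.0))
        assert np.quantile(suppression, 0.5) > 0.99
        assert np.quantile(suppression, 0.05) > 0.9

    def test_reduced_model_has_worse_loo_on_threshold_data(self, small_fit):
        study, full = small_fit
        reduced = fit_posterior(
            study.records,
            FitConfig(n_chains=2, n_iterations=700, seed=21, no_threshold=True),
        )
        assert (reduced.stacked("alpha") == 0).all()
        loo_full = compute_loo(full)
        loo_reduced = compute_loo(reduced)
        assert loo_full.elpd_loo > loo_reduced.elpd_loo + 2 * loo_reduced.se


class TestReportAndPersistence:
    def test_diagnostics_report_fields(self, small_fit):
        _study, draws = small_fit
        report = diagnostics_report(draws)
        d = report.to_dict()
        assert 0.0 <= d["ppc_coverage"] <= 1.0
        assert d["loo_elpd"] < 0 or d["loo_elpd"] > 0  # finite
        assert set(d["rhat"]) >= {"theta0", "alpha", "psi_threshold"}
        assert all(v is None or v >= 0.99 for v in d["rhat"].values())

    def test_residual_summaries_no_plant_shift(self, small_fit):
        _study, draws = small_fit
        res = residual_summaries(draws)
        assert res["residual"].abs().max() < 0.05
        assert res["abs_residual"].max() < 0.2

    def test_netcdf_round_trip(self, small_fit, tmp_path):
        _study, draws = small_fit
        import arviz as az

        path = tmp_path / "posterior.nc"
        draws.to_netcdf(path)
        idata = az.from_netcdf(path)
        np.testing.assert_allclose(
            idata.posterior["theta0"].values, draws.posterior["theta0"]
        )
        np.testing.assert_allclose(
            idata.log_likelihood["delta_psi"].values, draws.log_likelihood
        )
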