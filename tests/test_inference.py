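import numpy as np
import pytest
from scipy import stats

from vfbayes.inference import (
    EstimateConfig,
    PosteriorSummary,
    PriorSpec,
    TotalFailureError,
    estimate,
    importance_weights,
    log_likelihood,
    props_from_sample,
    props_to_sample,
    resample,
    sample_prior,
    sensitivity_sweep,
    welch_t,
)
from vfbayes.observation import GAWSeries


def _series(area, fps=2000.0):
    area = np.asarray(area, float)
    return GAWSeries(t=np.arange(len(area)) / fps, area=area, fps=fps)


class TestPrior:
    def test_default_bounds_layout(self):
        spec = PriorSpec()
        assert spec.bounds["e_bdy_kpa"] == (9.0, 15.0)
        assert spec.bounds["e_cvr_pa"] == (250.0, 950.0)
        assert spec.bounds["e_lig_kpa"] == (0.5, 3.0)
        assert spec.bounds["p_sub_pa"] == (400.0, 1800.0)
        assert spec.bounds["rho_kgm3"] == (950.0, 1200.0)
        assert spec.bounds["eta_poise"] == (1.0, 7.0)
        assert spec.bounds["x0_mm"] == (7.4, 8.4)
        assert "x0_mm" not in spec.param_names
        assert "x0_mm" in PriorSpec(include_x0=True).param_names

    def test_degenerate_bounds_give_point_mass(self):
        spec = PriorSpec(bounds={**PriorSpec().bounds, "e_cvr_pa": (600.0, 600.0)})
        s = sample_prior(spec, 5, 0)
        assert np.all(s[:, 1] == 600.0)

    def test_sample_mean_matches_uniform_clt(self):
        spec = PriorSpec()
        s = sample_prior(spec, 10_000, 123)
        mean = s[:, 1].mean()  # cover modulus, U(250, 950)
        tol = 3 * (700.0 / np.sqrt(12.0)) / 100.0
        assert abs(mean - 600.0) < tol

    def test_seed_reproducibility(self):
        spec = PriorSpec()
        assert np.array_equal(sample_prior(spec, 64, 9), sample_prior(spec, 64, 9))

    def test_props_roundtrip(self):
        spec = PriorSpec(include_x0=True)
        row = np.array([11.8, 600.0, 2.0, 1000.0, 1049.75, 3.0, 8.27])
        props = props_from_sample(row, spec)
        assert props.e_bdy == 11.8e3 and props.e_cvr == 600.0
        assert props.x0_mm == 8.27 and props.nu == 0.4995
        assert np.allclose(props_to_sample(props, spec), row)


class TestLikelihood:
    def test_perfect_match_is_zero(self):
        a = _series(np.arange(10.0))
        assert log_likelihood(a, a) == 0.0

    def test_unit_offset_over_600_samples(self):
        meas = _series(np.ones(600))
        sim = _series(np.zeros(600))
        assert log_likelihood(meas, sim, sigma_e=1.0) == pytest.approx(-300.0)

    def test_sigma_scaling(self):
        meas = _series(np.ones(100))
        sim = _series(np.zeros(100))
        c = 2.5
        assert log_likelihood(meas, sim, sigma_e=c) == pytest.approx(
            log_likelihood(meas, sim, sigma_e=1.0) / c**2
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(_series(np.ones(5)), _series(np.ones(6)))


class TestWeights:
    def test_uniform_when_equal(self):
        w = importance_weights(np.full(8, -3.0))
        assert np.allclose(w, 1.0 / 8.0)

    def test_hand_normalisation(self):
        w = importance_weights([0.0, -np.log(3.0)])
        assert np.allclose(w, [0.75, 0.25])

    def test_failed_samples_zero_weight_and_sum_one(self):
        rng = np.random.default_rng(5)
        ll = rng.normal(-100, 5, 50)
        ll[[3, 7]] = -np.inf
        w = importance_weights(ll)
        assert w[3] == 0.0 and w[7] == 0.0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0)

    def test_total_failure_raises(self):
        with pytest.raises(TotalFailureError):
            importance_weights([-np.inf, -np.inf])


class TestResample:
    def test_point_mass(self):
        idx = resample(np.zeros((4, 1)), np.array([0.0, 1.0, 0.0, 0.0]), 0)
        assert np.all(idx == 1)

    def test_binomial_counts(self):
        n = 10_000
        idx = resample(np.zeros((2, 1)), np.array([0.75, 0.25]), 11, size=n)
        count0 = np.sum(idx == 0)
        sd = np.sqrt(n * 0.75 * 0.25)
        assert abs(count0 - 7500) < 3 * sd

    def test_resampled_mean_matches_weighted_mean(self):
        rng = np.random.default_rng(21)
        samples = rng.normal(size=(100_000, 1))
        ll = -0.5 * (samples[:, 0] - 0.3) ** 2
        w = importance_weights(ll)
        idx = resample(samples, w, 3)
        weighted = float(w @ samples[:, 0])
        resampled = samples[idx, 0].mean()
        ess = 1.0 / np.sum(w**2)
        sd = np.sqrt(w @ (samples[:, 0] - weighted) ** 2)
        assert abs(resampled - weighted) < 3 * sd / np.sqrt(ess)


class TestImportanceSamplingOracle:
    def test_linear_gaussian_toy_matches_truncated_normal(self):
        """Scalar forward model y = chi + eps with a wide uniform prior: the
        importance-sampling posterior mean must match the analytic truncated
        normal within 3 Monte-Carlo standard errors (N = 10^4)."""
        rng = np.random.default_rng(77)
        a, b, sigma, y = -5.0, 9.0, 1.3, 2.1
        n = 10_000
        chi = rng.uniform(a, b, n)
        ll = -0.5 * ((y - chi) / sigma) ** 2
        w = importance_weights(ll)
        idx = resample(chi.reshape(-1, 1), w, 78)
        post = chi[idx]
        analytic = stats.truncnorm.mean((a - y) / sigma, (b - y) / sigma, loc=y, scale=sigma)
        mc_se = post.std() / np.sqrt(1.0 / np.sum(w**2))
        assert abs(post.mean() - analytic) < 3 * mc_se


class TestWelchT:
    def _summary(self, mean, sd):
        return PosteriorSummary(
            mean={"x0_mm": mean},
            sd={"x0_mm": sd},
            relative_uncertainty={"x0_mm": sd / mean},
            ess=100.0,
            failures=0,
            n_ens=100,
            config={},
        )

    def test_identical_summaries_zero(self):
        s = self._summary(8.39, 0.03)
        assert welch_t(s, s, "x0_mm")["t"] == 0.0

    def test_medial_compression_hand_value(self):
        # printed means 8.39 / 8.27 mm with SDs 0.38% and 0.30% of the means
        a = self._summary(8.39, 8.39 * 0.0038)
        b = self._summary(8.27, 8.27 * 0.0030)
        out = welch_t(a, b, "x0_mm")
        assert out["t"] == pytest.approx(2.97, abs=0.03)
        assert out["significant_95"] is True

    def test_scale_invariance(self):
        a, b = self._summary(8.39, 0.032), self._summary(8.27, 0.025)
        t1 = welch_t(a, b, "x0_mm")["t"]
        a2, b2 = self._summary(83.9, 0.32), self._summary(82.7, 0.25)
        assert welch_t(a2, b2, "x0_mm")["t"] == pytest.approx(t1, rel=1e-12)

    def test_zero_spread_rejected(self):
        with pytest.raises(ZeroDivisionError):
            welch_t(self._summary(1.0, 0.0), self._summary(2.0, 0.0), "x0_mm")

    def test_missing_parameter_rejected(self):
        with pytest.raises(KeyError):
            welch_t(self._summary(1.0, 0.1), self._summary(1.0, 0.1), "e_cvr_pa")


def _short_observation(mesh, props, noise_sd=0.5, seed=4, duration_ms=380.0, trim_ms=250.0):
    """Small synthetic measurement for pipeline tests (130 ms window)."""
    from vfbayes.dynamics import simulate
    from vfbayes.observation import compute_gaw, downsample, trim_transient

    res = simulate(props, mesh, duration_ms=duration_ms, h_ms=0.05)
    gaw = trim_transient(downsample(compute_gaw(res), 2000.0), trim_ms)
    rng = np.random.default_rng(seed)
    noisy = np.maximum(0.0, gaw.area + rng.normal(0.0, noise_sd, len(gaw)))
    return GAWSeries(t=gaw.t, area=noisy, fps=gaw.fps)


class TestEstimatePipeline:
    def test_single_parameter_contraction(self, mesh120, ref_props):
        """With every prior collapsed to truth except the cover modulus and a
        noise-free observation, the posterior contracts: SD below the prior
        SD and the mean within one prior SD of truth."""
        meas = _short_observation(mesh120, ref_props, noise_sd=0.0)
        bounds = {
            "e_bdy_kpa": (11.8, 11.8),
            "e_cvr_pa": (250.0, 950.0),
            "e_lig_kpa": (2.0, 2.0),
            "p_sub_pa": (1000.0, 1000.0),
            "rho_kgm3": (1049.75, 1049.75),
            "eta_poise": (3.0, 3.0),
            "x0_mm": (7.4, 8.4),
        }
        spec = PriorSpec(bounds=bounds)
        cfg = EstimateConfig(n_ens=48, seed=12, mesh_target=120, duration_ms=380.0, trim_ms=250.0)
        summary = estimate(meas, spec, cfg, mesh=mesh120)
        prior_sd = spec.prior_sd()["e_cvr_pa"]
        assert summary.sd["e_cvr_pa"] < prior_sd
        assert abs(summary.mean["e_cvr_pa"] - 600.0) < prior_sd

    def test_worker_count_invariance_and_determinism(self, mesh120, ref_props):
        meas = _short_observation(mesh120, ref_props)
        spec = PriorSpec()
        base = dict(n_ens=8, seed=5, mesh_target=120, duration_ms=380.0, trim_ms=250.0)
        s1 = estimate(meas, spec, EstimateConfig(**base, workers=1), mesh=mesh120)
        s2 = estimate(meas, spec, EstimateConfig(**base, workers=2), mesh=mesh120)
        s3 = estimate(meas, spec, EstimateConfig(**base, workers=1), mesh=mesh120)
        assert s1.mean == s2.mean and s1.sd == s2.sd
        assert s1.mean == s3.mean
        assert np.array_equal(s1.ensemble.log_likelihoods, s2.ensemble.log_likelihoods)

    def test_failures_reported_not_fatal(self, mesh120, ref_props):
        meas = _short_observation(mesh120, ref_props)
        cfg = EstimateConfig(n_ens=24, seed=3, mesh_target=120, duration_ms=380.0, trim_ms=250.0)
        summary = estimate(meas, PriorSpec(), cfg, mesh=mesh120)
        assert 0 <= summary.failures < summary.n_ens
        assert np.isfinite(summary.ess)

    def test_adding_x0_does_not_shrink_other_uncertainties(self, mesh120, ref_props):
        """Estimating the medial-compression offset alongside the material
        properties adds a pathway to explain the data, so the posterior SDs
        of the other parameters must not decrease (within Monte-Carlo
        tolerance) on the same observation."""
        meas = _short_observation(mesh120, ref_props)
        base = dict(n_ens=60, seed=31, mesh_target=120, duration_ms=380.0, trim_ms=250.0)
        s_without = estimate(meas, PriorSpec(), EstimateConfig(**base), mesh=mesh120)
        s_with = estimate(meas, PriorSpec(include_x0=True), EstimateConfig(**base), mesh=mesh120)
        spread = PriorSpec().prior_sd()
        for name in s_without.sd:
            tol = 0.05 * spread[name]  # MC slack relative to the prior scale
            assert s_with.sd[name] >= s_without.sd[name] - tol

    def test_degenerate_sweep_matches_single_estimate(self, mesh120, ref_props):
        meas = _short_observation(mesh120, ref_props)
        spec = PriorSpec()
        cfg = EstimateConfig(n_ens=12, seed=6, mesh_target=120, duration_ms=380.0, trim_ms=250.0)
        rows = sensitivity_sweep(meas, spec, "ensemble_size", [12], cfg, ref_props)
        direct = estimate(meas, spec, cfg)
        assert rows[0]["summary"].mean == direct.mean
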