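"""Diauxic simulation, likelihood, sampler plumbing and AIC comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from adaptivecrm import DiauxicParams, GrowthCurve
from adaptivecrm.fitting import (
    ChainConfig,
    DiauxicCurveModel,
    NOISE_SIGMA_5PCT,
    SYNTHETIC_TRUTH,
    compare_models,
    default_priors,
    default_sampling_times,
    fit_mcmc,
    identifiable_parameters,
    log_likelihood,
    simulate_diauxic,
    synthesize_growth_curve,
)


@pytest.fixture(scope="module")
def truth():
    return SYNTHETIC_TRUTH


@pytest.fixture(scope="module")
def short_times():
    return default_sampling_times(duration_h=40.0)


class TestSimulateDiauxic:
    def test_budget_constraint_holds_at_all_output_times(self, truth):
        pred = simulate_diauxic(truth, default_sampling_times())
        total = pred["alpha_gal"] + pred["alpha_eth"]
        assert np.all(total <= truth.Q * truth.delta * (1 + 1e-6))

    def test_biphasic_shape_with_intermediate_slowdown(self, truth):
        pred = simulate_diauxic(truth, default_sampling_times())
        n = pred["density"].to_numpy()
        t = pred["time_h"].to_numpy()
        gr = np.gradient(np.log(n), t)
        fast = gr > 0.05
        # two separated growth phases ...
        switches = np.diff(fast.astype(int))
        assert (switches == 1).sum() >= 2 or (fast[0] and (switches == 1).sum() >= 1)
        # ... with a slowdown between them in which the galactose phase has
        # ended and ethanol accumulated
        i_end1 = int(np.argmax(~fast[np.argmax(fast):])) + int(np.argmax(fast))
        assert pred["c_eth"].iloc[i_end1] > 0.5 * truth.Y * truth.c_gal0

    def test_zero_ethanol_pathway_is_single_phase(self, truth):
        p0 = dataclasses.replace(truth, Y=1e-300, alpha_eth0=1e-300)
        pred = simulate_diauxic(p0, default_sampling_times())
        assert np.all(pred["c_eth"] <= 1e-15)
        # growth rate decays monotonically once galactose is depleted:
        # exactly one switch from fast growth to non-growth
        gr = np.gradient(np.log(pred["density"].to_numpy()), pred["time_h"].to_numpy())
        fast = gr > 0.05
        assert (np.diff(fast.astype(int)) == 1).sum() == (1 if not fast[0] else 0)

    def test_mass_balance_with_ethanol_uptake_disabled(self, truth, short_times):
        # alpha_eth = 0 throughout: c_eth(t) = Y * (c_gal(0) - c_gal(t))
        p0 = dataclasses.replace(truth, alpha_eth0=1e-300)
        pred = simulate_diauxic(p0, short_times)
        np.testing.assert_allclose(
            pred["c_eth"], p0.Y * (p0.c_gal0 - pred["c_gal"]), rtol=1e-6,
            atol=1e-9 * p0.c_gal0,
        )

    def test_galactose_monotone_nonincreasing(self, truth, short_times):
        pred = simulate_diauxic(truth, short_times)
        assert np.all(np.diff(pred["c_gal"]) <= 1e-12 * truth.c_gal0)

    def test_fixed_variant_matches_vanishing_adaptation_velocity(self, truth, short_times):
        frozen = simulate_diauxic(truth, short_times, variant="fixed")
        slow = simulate_diauxic(
            dataclasses.replace(truth, d=1e-30), short_times, variant="adaptive"
        )
        np.testing.assert_allclose(
            frozen["density"], slow["density"], rtol=1e-5
        )


class TestLogLikelihood:
    def test_two_point_closed_form(self):
        # residuals (0, log10 2) with sigma = 1:
        # ll = -log(2 pi) - 0.5 log10(2)^2
        curve = GrowthCurve([0.0, 1.0], [1.0, 2.0])
        pred = np.array([1.0, 1.0])
        resid = np.log10(curve.densities) - np.log10(pred)
        expected = -np.log(2 * np.pi) - 0.5 * resid[1] ** 2
        ll = (
            -0.5 * 2 * np.log(2 * np.pi * 1.0**2)
            - 0.5 * np.sum(resid**2)
        )
        assert ll == pytest.approx(expected)
        assert ll == pytest.approx(-1.8831876056573326)

    def test_perfect_fit_attains_noise_only_maximum(self, truth, short_times):
        pred = simulate_diauxic(truth, short_times)
        curve = GrowthCurve(short_times, pred["density"].to_numpy())
        sigma = 0.02
        ll = log_likelihood(truth, curve, sigma)
        # integration tolerance only: essentially the zero-residual maximum
        assert ll == pytest.approx(
            -0.5 * len(curve) * np.log(2 * np.pi * sigma**2), rel=1e-4
        )

    def test_larger_residuals_lower_likelihood(self, truth, short_times):
        pred = simulate_diauxic(truth, short_times)["density"].to_numpy()
        near = GrowthCurve(short_times, pred * 1.05)
        far = GrowthCurve(short_times, pred * 1.10)
        assert log_likelihood(truth, near, 0.02) > log_likelihood(truth, far, 0.02)

    def test_sigma_must_be_positive(self, truth, short_times):
        curve = GrowthCurve(short_times, np.full(short_times.size, 1e5))
        with pytest.raises(ValueError):
            log_likelihood(truth, curve, 0.0)


class TestSynthesize:
    def test_noise_free_curve_is_exact_model_output(self, truth, short_times):
        curve = synthesize_growth_curve(truth, short_times, noise_sigma=0.0)
        pred = simulate_diauxic(truth, short_times)["density"].to_numpy()
        np.testing.assert_allclose(curve.densities, pred)

    def test_seed_determinism(self, truth, short_times):
        c1 = synthesize_growth_curve(truth, short_times, NOISE_SIGMA_5PCT, seed=4)
        c2 = synthesize_growth_curve(truth, short_times, NOISE_SIGMA_5PCT, seed=4)
        np.testing.assert_array_equal(c1.densities, c2.densities)
        c3 = synthesize_growth_curve(truth, short_times, NOISE_SIGMA_5PCT, seed=5)
        assert not np.array_equal(c1.densities, c3.densities)

    def test_default_schedule_has_421_samples_over_70_hours(self, truth):
        curve = synthesize_growth_curve(truth, noise_sigma=0.0)
        assert len(curve) == 421
        assert curve.times[-1] == pytest.approx(70.0)
        assert np.allclose(np.diff(curve.times), 1 / 6)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            GrowthCurve([0.0, 0.0], [1.0, 2.0])  # non-increasing times
        with pytest.raises(ValueError):
            GrowthCurve([0.0, 1.0], [1.0, 0.0])  # non-positive density

    def test_csv_round_trip(self, truth, short_times, tmp_path):
        curve = synthesize_growth_curve(truth, short_times, NOISE_SIGMA_5PCT, seed=1)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = GrowthCurve.from_csv(path)
        np.testing.assert_allclose(back.densities, curve.densities)


@pytest.fixture(scope="module")
def tiny_setup(truth):
    times = default_sampling_times(duration_h=30.0, interval_h=1.0)
    curve = synthesize_growth_curve(truth, times, NOISE_SIGMA_5PCT, seed=2)
    centers = {
        n: getattr(truth, n)
        for n in ("v_gal", "v_eth", "K_gal", "K_eth", "delta", "Q", "d",
                  "Y", "alpha_gal0", "alpha_eth0")
    }
    centers["sigma"] = NOISE_SIGMA_5PCT
    fixed_inputs = {"n0": truth.n0, "c_gal0": truth.c_gal0, "c_eth0": truth.c_eth0}
    return curve, centers, fixed_inputs


class TestSamplerPlumbing:
    def test_same_seed_gives_identical_posteriors(self, tiny_setup):
        curve, centers, fixed_inputs = tiny_setup
        priors = default_priors(centers, decades=0.5)
        cfg = ChainConfig(seed=9, nwalkers=24, nsteps=12, nburn=4)
        r1 = fit_mcmc("adaptive", curve, priors, cfg, fixed_inputs)
        r2 = fit_mcmc("adaptive", curve, priors, cfg, fixed_inputs)
        pd.testing.assert_frame_equal(r1.posterior, r2.posterior)

    def test_aic_identity_and_parameter_count(self, tiny_setup):
        curve, centers, fixed_inputs = tiny_setup
        priors = default_priors(centers, decades=0.5)
        res = fit_mcmc(
            "adaptive", curve, priors, ChainConfig(seed=9, nwalkers=24, nsteps=12),
            fixed_inputs,
        )
        assert res.k == 11  # 10 model parameters + noise sigma
        assert res.aic == pytest.approx(2 * res.k - 2 * res.max_log_likelihood)
        # posterior respects the prior box
        for name, (lo, hi) in priors.items():
            assert res.posterior[name].between(lo * 0.999, hi * 1.001).all()

    def test_priors_excluding_truth_flagged_at_boundary(self, tiny_setup):
        curve, centers, fixed_inputs = tiny_setup
        bad_centers = dict(centers)
        # the galactose yield sets the first plateau directly; a prior box
        # excluding it drives the posterior onto the lower bound
        bad_centers["v_gal"] = centers["v_gal"] * 3.0
        priors = default_priors(bad_centers, decades=0.25)
        res = fit_mcmc(
            "adaptive", curve, priors, ChainConfig(seed=9, nwalkers=24, nsteps=150),
            fixed_inputs,
        )
        assert res.boundary_flags["v_gal"]
        assert not res.converged

    def test_missing_prior_is_an_error(self, tiny_setup):
        curve, centers, fixed_inputs = tiny_setup
        priors = default_priors(centers, decades=0.5)
        priors.pop("Y")
        with pytest.raises(ValueError, match="Y"):
            DiauxicCurveModel(curve, "adaptive", priors, fixed_inputs)


class TestCompareModels:
    def _result(self, aic, times, dens):
        from adaptivecrm.fitting import FitResult

        return FitResult(
            variant="adaptive", param_names=("x",),
            posterior=pd.DataFrame({"x": [1.0]}), ml_params={"x": 1.0},
            max_log_likelihood=0.0, k=1, aic=aic, converged=True,
            rhat={"x": 1.0}, boundary_flags={"x": False}, acceptance_fraction=0.5,
            data_times=times, data_densities=dens,
        )

    def test_equal_aics(self):
        t, d = np.array([0.0, 1.0]), np.array([1.0, 2.0])
        delta, rel = compare_models(self._result(10.0, t, d), self._result(10.0, t, d))
        assert delta == 0.0 and rel == 1.0

    def test_delta_minus_two(self):
        t, d = np.array([0.0, 1.0]), np.array([1.0, 2.0])
        delta, rel = compare_models(self._result(8.0, t, d), self._result(10.0, t, d))
        assert delta == -2.0
        assert rel == pytest.approx(np.exp(-1.0))

    def test_mismatched_data_rejected(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            compare_models(
                self._result(1.0, t, np.array([1.0, 2.0])),
                self._result(1.0, t, np.array([1.0, 3.0])),
            )


class TestIdentifiability:
    def test_core_parameters_identifiable_from_full_curve(self, truth):
        names = identifiable_parameters(
            truth, default_sampling_times(), NOISE_SIGMA_5PCT
        )
        # the galactose yield and the death rate shape the curve directly
        assert "v_gal" in names
        assert "delta" in names

    def test_short_window_identifies_fewer_parameters(self, truth):
        full = identifiable_parameters(
            truth, default_sampling_times(), NOISE_SIGMA_5PCT
        )
        early = identifiable_parameters(
            truth, default_sampling_times(duration_h=6.0), NOISE_SIGMA_5PCT
        )
        assert set(early) <= set(full)
        assert len(early) < len(full)
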