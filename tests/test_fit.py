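"""Chi-squared criterion, forward model, Metropolis chain, phase check."""

import numpy as np
import pytest
from scipy import stats as sps

from dropclock.fit import (
    FitCriterion,
    chi2_criterion,
    metropolis_fit,
    model_expected_periodogram,
    validate_phase_distribution,
)
from dropclock.gillespie import ClockParamVector, default_clock_params
from dropclock.spectral import AveragePeriodogram
from dropclock.stats import chi2_sf


class TestChi2Criterion:
    def test_identical_periodograms(self):
        m = np.array([0.2, 0.5, 0.3])
        chi2, df = chi2_criterion(m, m, np.ones(3))
        assert chi2 == 0.0
        assert df == 3

    def test_unit_residual_construction(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(0.1, 1.0, size=12)
        var = rng.uniform(0.5, 2.0, size=12)
        model = obs + np.sqrt(var)
        chi2, _ = chi2_criterion(obs, model, var)
        assert chi2 == pytest.approx(12.0, rel=1e-12)

    def test_goodness_of_fit_p_value(self):
        assert chi2_sf(130.231, 137) == pytest.approx(0.65, abs=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            chi2_criterion(np.ones(3), np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestForwardModel:
    def test_same_theta_same_seed_identical(self):
        theta = default_clock_params()
        a = model_expected_periodogram(theta, n_sim=8, t_end=96.0, seed=4)
        b = model_expected_periodogram(theta, n_sim=8, t_end=96.0, seed=4)
        assert np.array_equal(a.mean, b.mean)

    def test_monte_carlo_error_shrinks_with_ensemble_size(self):
        theta = default_clock_params()
        small = model_expected_periodogram(theta, n_sim=24, t_end=120.0, seed=5)
        large = model_expected_periodogram(theta, n_sim=48, t_end=120.0, seed=6)
        # SE^2 of the mean = var/n: doubling n halves it (within MC scatter)
        se2_small = (small.var / small.n_cells).sum()
        se2_large = (large.var / large.n_cells).sum()
        assert se2_large < se2_small
        assert se2_small / se2_large == pytest.approx(2.0, rel=0.5)

    def test_calibrated_peak_period(self, ccg_trajectories_64):
        from dropclock.preprocess import moving_average_detrend
        from dropclock.spectral import average_periodogram, periodogram_set

        avg = average_periodogram(
            periodogram_set(moving_average_detrend(ccg_trajectories_64))
        )
        peak = 1.0 / avg.freqs[int(np.argmax(avg.mean))]
        assert peak == pytest.approx(21.0, abs=1.0)


def quadratic_criterion(mu=5.0, s=0.5):
    """1-parameter toy target: chi2(theta) = ((theta-mu)/s)^2, so the
    Metropolis stationary law at T=1 is Normal(mu, s^2)."""
    obs = AveragePeriodogram(
        freqs=np.array([1.0]), mean=np.array([0.0]), var=np.array([1.0]), n_cells=2
    )
    crit = FitCriterion(observed=obs, total_variance=np.array([1.0]))

    def model_fn(theta, seed):
        return np.array([(theta.theta["x"] - mu) / s])

    return crit, model_fn


class TestMetropolis:
    def test_downhill_always_accepted(self):
        crit, model_fn = quadratic_criterion()
        theta0 = ClockParamVector(theta={"x": 20.0}, log_scale_mask={})
        chain = metropolis_fit(
            theta0, crit, n_steps=200, proposal_scales={"x": 0.5}, seed=0,
            free_params=["x"], model_fn=model_fn,
        )
        # chain walks downhill towards mu and chi2 never jumps above start
        assert chain.chi2[-1] < chain.chi2[0]
        assert chain.chi2.max() == chain.chi2[0]

    def test_acceptance_probability_closed_form(self):
        # delta chi2 = 2 at T=1 accepts with probability e^-1
        assert np.exp(-2.0 / 2.0) == pytest.approx(0.3679, abs=1e-4)
        crit, model_fn = quadratic_criterion(mu=0.0, s=1.0)
        theta0 = ClockParamVector(theta={"x": 1.0}, log_scale_mask={})
        rng_up = 0
        n = 4000
        chain = metropolis_fit(
            theta0, crit, n_steps=n, proposal_scales={"x": 1.3}, seed=7,
            free_params=["x"], model_fn=model_fn,
        )
        # acceptance rate of a well-mixed chain on a unit Gaussian with this
        # proposal is far from 0 and 1 (sanity of the accept rule)
        assert 0.2 < chain.acceptance_rate < 0.9

    def test_detailed_balance_on_toy_target(self):
        mu, s = 5.0, 0.5
        crit, model_fn = quadratic_criterion(mu, s)
        theta0 = ClockParamVector(theta={"x": mu}, log_scale_mask={})
        chain = metropolis_fit(
            theta0, crit, n_steps=20_000, proposal_scales={"x": 0.6}, seed=11,
            free_params=["x"], model_fn=model_fn,
        )
        # thin to roughly independent draws before the KS comparison
        samples = chain.params[2000::10, 0]
        _, p = sps.kstest(samples, lambda q: sps.norm.cdf(q, mu, s))
        assert p > 0.01
        assert samples.mean() == pytest.approx(mu, abs=0.05)
        assert samples.std(ddof=1) == pytest.approx(s, rel=0.1)

    def test_chain_reproducible(self):
        crit, model_fn = quadratic_criterion()
        theta0 = ClockParamVector(theta={"x": 6.0}, log_scale_mask={})
        kw = dict(n_steps=100, proposal_scales={"x": 0.5}, seed=3,
                  free_params=["x"], model_fn=model_fn)
        a = metropolis_fit(theta0, crit, **kw)
        b = metropolis_fit(theta0, crit, **kw)
        assert np.array_equal(a.params, b.params)

    def test_failed_forward_model_rejects_proposal(self):
        crit, _ = quadratic_criterion()

        calls = {"n": 0}

        def flaky(theta, seed):
            calls["n"] += 1
            if theta.theta["x"] > 6.0:
                raise RuntimeError("simulation blew up")
            return np.array([(theta.theta["x"] - 5.0) / 0.5])

        theta0 = ClockParamVector(theta={"x": 5.9}, log_scale_mask={})
        chain = metropolis_fit(
            theta0, crit, n_steps=300, proposal_scales={"x": 0.5}, seed=5,
            free_params=["x"], model_fn=flaky,
        )
        assert chain.params[:, 0].max() <= 6.0


class TestPhaseValidation:
    def test_identical_samples(self):
        x = np.linspace(0, 4, 50)
        d, p = validate_phase_distribution(x, x)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_mean_shift_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 400)
        y = rng.uniform(0.5, 1.5, 400)
        d, p = validate_phase_distribution(x, y)
        assert d < 0.08  # only sampling noise remains after centering

    def test_width_difference_detected(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 500)
        y = rng.uniform(0, 2, 500)
        d, _ = validate_phase_distribution(x, y)
        assert d == pytest.approx(0.25, abs=0.05)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            validate_phase_distribution(np.ones(5), np.ones(30))
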