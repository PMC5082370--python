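"""Metropolis MCMC ensemble fitting of the stochastic clock.

The figure of merit compares the observed cell-averaged normalized
periodogram with the average periodogram of an ensemble simulated under a
parameter vector Theta:

    chi^2(Theta) = sum_l ( Pbar_obs(f_l) - Pbar_model(f_l; Theta) )^2
                   / (sigma_l,tot)^2

summed over the observable frequencies, with (sigma_l,tot)^2 the total
per-frequency variance of the observed average periodogram. A Metropolis
random walk proposes log-scale Gaussian updates of the free parameters and
accepts with probability min(1, exp(-delta chi^2 / (2 T))). Because the
model periodogram is itself a Monte-Carlo estimate, proposals within a
block share common random numbers (one simulation seed per block,
refreshed every ``crn_refresh`` steps) — a pragmatic variance-reduction
deviating from exact pseudo-marginal MCMC, at the desk scales used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gillespie import (
    ClockParamVector,
    build_default_clock,
    ensemble_species_matrix,
    gillespie_ensemble,
)
from .preprocess import moving_average_detrend
from .spectral import AveragePeriodogram, average_periodogram, periodogram_set
from .stats import chi2_sf, ks_2sample
from .tables import FRAME_DT_H, TrajectorySet

__all__ = [
    "FitCriterion",
    "EnsembleChain",
    "chi2_criterion",
    "model_expected_periodogram",
    "metropolis_fit",
    "validate_phase_distribution",
]


@dataclass
class FitCriterion:
    """Observed average periodogram and its per-frequency total variance."""

    observed: AveragePeriodogram
    total_variance: np.ndarray
    n_constraints: int = 0  # fitted-constraint count subtracted from df

    def __post_init__(self):
        self.total_variance = np.asarray(self.total_variance, dtype=float)
        if self.total_variance.size != self.observed.freqs.size:
            raise ValueError("variance grid does not match the periodogram grid")
        if np.any(self.total_variance <= 0):
            raise ValueError("total variance must be positive at every included frequency")

    @property
    def df(self) -> int:
        return self.observed.freqs.size - self.n_constraints


def chi2_criterion(
    observed_mean: np.ndarray, model_mean: np.ndarray, variances: np.ndarray,
    n_constraints: int = 0,
) -> tuple[float, int]:
    """Chi-squared distance between two average periodograms.

    Returns (chi2, df) with df the number of included frequencies minus
    ``n_constraints``.
    """
    observed_mean = np.asarray(observed_mean, dtype=float)
    model_mean = np.asarray(model_mean, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if not (observed_mean.size == model_mean.size == variances.size):
        raise ValueError("mismatched frequency grids")
    if np.any(variances <= 0):
        raise ValueError("zero variance at an included frequency")
    chi2 = float(np.sum((observed_mean - model_mean) ** 2 / variances))
    return chi2, observed_mean.size - n_constraints


def model_expected_periodogram(
    theta: ClockParamVector,
    n_sim: int = 128,
    t_end: float = 240.0,
    frame_dt: float = FRAME_DT_H,
    seed: int = 0,
    window_h: float = 24.0,
) -> AveragePeriodogram:
    """Average normalized periodogram of a detection-free simulated
    ensemble under Theta (Gillespie -> detrend -> periodogram -> average)."""
    net = build_default_clock(theta)
    trajs = gillespie_ensemble(net, n_sim, t_end, frame_dt, seed=seed)
    sig = ensemble_species_matrix(trajs, "CCG2").astype(float)
    ts = TrajectorySet(
        values=sig,
        cell_ids=[f"sim{i}" for i in range(n_sim)],
        droplet_ids=[f"simd{i}" for i in range(n_sim)],
    )
    det = moving_average_detrend(ts, window_h=window_h)
    return average_periodogram(periodogram_set(det, frame_dt=frame_dt))


@dataclass
class EnsembleChain:
    """Metropolis chain over Theta with per-step chi-squared values."""

    param_names: list
    params: np.ndarray  # (n_steps+1, n_free): includes the initial state
    chi2: np.ndarray
    accepted: np.ndarray
    proposal_scales: dict
    temperature: float
    seed: int

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def posterior_median(self, burn_frac: float = 0.25) -> dict:
        lo = int(self.params.shape[0] * burn_frac)
        med = np.median(self.params[lo:], axis=0)
        return dict(zip(self.param_names, med))


def metropolis_fit(
    init_theta: ClockParamVector,
    criterion: FitCriterion,
    n_steps: int = 2000,
    proposal_scales: dict | None = None,
    temperature: float = 1.0,
    seed: int = 0,
    free_params: list | None = None,
    n_sim: int = 128,
    t_end: float = 240.0,
    crn_refresh: int = 50,
    model_fn=None,
) -> EnsembleChain:
    """Metropolis MCMC over the clock parameters.

    ``free_params`` restricts the walk to a parameter subset (defaults to
    every log-scale entry). Parameters in the log-scale mask receive
    multiplicative exp(Normal) proposals, others additive Gaussian ones.
    ``model_fn(theta, sim_seed) -> mean periodogram`` can replace the
    Gillespie forward model (used for closed-form targets in testing).
    A failed forward simulation rejects the proposal with a diagnostic
    count rather than aborting the chain.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(free_params or init_theta.log_scale_mask.keys())
    if not names:
        raise ValueError("no free parameters")
    scales = {k: 0.05 for k in names}
    if proposal_scales:
        scales.update(proposal_scales)
    if model_fn is None:
        def model_fn(theta, sim_seed):
            return model_expected_periodogram(
                theta, n_sim=n_sim, t_end=t_end, seed=sim_seed
            ).mean

    def sim_seed_for(step):
        block = step // max(crn_refresh, 1)
        return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(block,))
                   .generate_state(1)[0] % (2**31 - 1))

    theta = init_theta
    cur = np.array([theta.theta[k] for k in names], dtype=float)
    model = np.asarray(model_fn(theta, sim_seed_for(0)))
    chi2_cur, _ = chi2_criterion(criterion.observed.mean, model, criterion.total_variance)

    hist = np.empty((n_steps + 1, len(names)))
    chi2s = np.empty(n_steps + 1)
    acc = np.zeros(n_steps, dtype=bool)
    hist[0] = cur
    chi2s[0] = chi2_cur
    n_failed = 0
    for step in range(n_steps):
        prop = cur.copy()
        for i, k in enumerate(names):
            if theta.log_scale_mask.get(k, False):
                prop[i] = cur[i] * np.exp(rng.normal(0.0, scales[k]))
            else:
                prop[i] = cur[i] + rng.normal(0.0, scales[k])
        ss = sim_seed_for(step)
        if ss != sim_seed_for(max(step - 1, 0)):
            # CRN block boundary: re-evaluate the current state under the
            # refreshed seed so both sides of the ratio share randomness
            model = np.asarray(model_fn(theta.replace(**dict(zip(names, cur))), ss))
            chi2_cur, _ = chi2_criterion(
                criterion.observed.mean, model, criterion.total_variance
            )
        try:
            theta_prop = theta.replace(**dict(zip(names, prop)))
            model_prop = np.asarray(model_fn(theta_prop, ss))
            chi2_prop, _ = chi2_criterion(
                criterion.observed.mean, model_prop, criterion.total_variance
            )
        except Exception:
            n_failed += 1
            chi2_prop = np.inf
        delta = chi2_prop - chi2_cur
        if delta <= 0 or rng.random() < np.exp(-delta / (2.0 * temperature)):
            cur = prop
            chi2_cur = chi2_prop
            acc[step] = True
        hist[step + 1] = cur
        chi2s[step + 1] = chi2_cur
    return EnsembleChain(
        param_names=names, params=hist, chi2=chi2s, accepted=acc,
        proposal_scales=scales, temperature=temperature, seed=seed,
    )


def validate_phase_distribution(data_phases, model_phases) -> tuple[float, float]:
    """Two-sample KS test of phase distributions after mean subtraction.

    The phase (cycles completed over a fixed window) is functionally
    independent of the periodogram used in fitting, so this is an
    independent check of the fitted stochastic model.
    """
    x = np.asarray(data_phases, dtype=float)
    y = np.asarray(model_phases, dtype=float)
    if x.size < 20 or y.size < 20:
        raise ValueError("need at least 20 phases per sample")
    return ks_2sample(x - x.mean(), y - y.mean())
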