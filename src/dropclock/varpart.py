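"""Partitioning periodogram variance into stochastic and detector parts.

A cell's recorded series is signal plus additive detector noise; both pass
through the same linear detrending operator Q before the periodogram is
taken. For white detector noise of variance sigma_det^2 the noise
contribution to the *bare* (un-normalized) periodogram variance at
frequency f_l follows from Gaussian moment algebra on E_l = (F Q eps)_l:

    (sigma_l^e)^2 = gamma_Q(l) * sigma_det^2 * <|S_l|^2>
                  + beta_Q(l)  * sigma_det^4

where gamma_Q(l) = 2 ||r_l||^2 and beta_Q(l) collects the fourth-moment
terms of the real and imaginary parts of the filtered-noise transform row
r_l = (F Q)_l — both pure functions of the moving-average detrending
weights. The population mean <|S_l|^2> of the clean-signal power is
replaced by the sample mean of the observed bare periodogram minus its
noise bias ||r_l||^2 sigma_det^2 (first-approximation plug-in). Subtracting
the detector part from the total per-frequency variance across cells gives
the stochastic component: (sigma_l^c)^2 = (sigma_l)^2 - (sigma_l^e)^2.

The same module provides the cell-resampling bootstrap of the total
variance and a harmonic (per-frequency, 2 df) analysis of variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .preprocess import detrend_matrix
from .tables import FRAME_DT_H

__all__ = [
    "propagation_coefficients",
    "detector_variance_to_periodogram",
    "detector_variance_from_noise_model",
    "bootstrap_total_variance",
    "VariancePartition",
    "partition",
    "partition_fraction_ci",
    "HarmonicAnovaTable",
    "harmonic_anova",
    "anova_from_sums_of_squares",
]


def _filtered_dft_rows(n_frames_raw: int, window_h: float | None,
                       frame_dt: float = FRAME_DT_H):
    """Rows r_l of F·Q for l = 1..floor(L/2); Q = identity when window_h is
    None (no detrending), else the moving-average detrend operator."""
    if window_h is None:
        L = n_frames_raw
        Q = np.eye(L)
    else:
        Q = detrend_matrix(n_frames_raw, window_h)
        L = Q.shape[0]
    n = L // 2
    j = np.arange(L)
    ell = np.arange(1, n + 1)
    F = np.exp(-2j * np.pi * np.outer(ell, j) / L)
    return F @ Q, L


def propagation_coefficients(
    n_frames_raw: int, window_h: float | None = 24.0, frame_dt: float = FRAME_DT_H
):
    """gamma_Q(l), beta_Q(l) and the noise-bias row norms ||r_l||^2.

    Derived exactly from the detrending weights: with a = Re r_l,
    b = Im r_l and white noise of unit variance,
    Var(|E_l|^2) = 2||a||^4 + 2||b||^4 + 4(a.b)^2  (= beta_Q)
    and the signal cross term carries gamma_Q = 2(||a||^2 + ||b||^2).
    """
    R, L = _filtered_dft_rows(n_frames_raw, window_h, frame_dt)
    a = R.real
    b = R.imag
    na = np.sum(a * a, axis=1)
    nb = np.sum(b * b, axis=1)
    ab = np.sum(a * b, axis=1)
    g1 = na + nb  # ||r_l||^2: noise power gain (bias of the bare periodogram)
    gamma = 2.0 * g1
    beta = 2.0 * na**2 + 2.0 * nb**2 + 4.0 * ab**2
    return gamma, beta, g1, L


def detector_variance_to_periodogram(
    sigma_det2: float,
    mean_bare_pgram: np.ndarray,
    n_frames_raw: int,
    window_h: float | None = 24.0,
    frame_dt: float = FRAME_DT_H,
) -> np.ndarray:
    """Detector-noise contribution (sigma_l^e)^2 to the bare periodogram
    variance at each observable frequency.

    ``mean_bare_pgram`` is the cell-averaged bare periodogram of the
    normalized, detrended series (length floor(L/2) on the detrended
    grid); ``sigma_det2`` the detector variance on the same (normalized)
    intensity scale.
    """
    if sigma_det2 < 0:
        raise ValueError("sigma_det2 must be >= 0")
    gamma, beta, g1, L = propagation_coefficients(n_frames_raw, window_h, frame_dt)
    mean_bare_pgram = np.asarray(mean_bare_pgram, dtype=float)
    if mean_bare_pgram.size != gamma.size:
        raise ValueError(
            f"periodogram grid ({mean_bare_pgram.size}) does not match the "
            f"observable grid of the detrended window ({gamma.size})"
        )
    signal_power = np.maximum(mean_bare_pgram - g1 * sigma_det2, 0.0)
    return gamma * sigma_det2 * signal_power + beta * sigma_det2**2


def detector_variance_from_noise_model(noise_model, raw_intensity, rhodamine) -> float:
    """Average detector variance on the normalized-fluorescence scale.

    sigma_det^2 = mean over cells and frames of sigma^2(I_jt) / R_t^2, with
    I the raw intensity and R the shared reference series.
    """
    I = np.atleast_2d(np.asarray(raw_intensity, dtype=float))
    R = np.asarray(rhodamine, dtype=float)
    return float(np.mean(noise_model.variance(I) / R[None, :] ** 2))


@dataclass
class BootstrapVariance:
    """Cell-resampling bootstrap of the average periodogram."""

    var_of_mean: np.ndarray  # per-frequency variance of the resampled mean
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    n_cells: int
    degenerate: bool = False

    @property
    def per_cell_scale(self) -> np.ndarray:
        """Total per-cell variance implied by the bootstrap (x n_cells)."""
        return self.var_of_mean * self.n_cells


def bootstrap_total_variance(
    power: np.ndarray, n_boot: int = 5000, seed: int = 0, ci: float = 0.95
) -> BootstrapVariance:
    """Bootstrap the per-frequency variance of the cell-averaged
    periodogram by resampling cells with replacement."""
    power = np.asarray(power, dtype=float)
    if power.shape[0] < 10:
        raise ValueError("need at least 10 cells to bootstrap")
    rng = np.random.default_rng(seed)
    K = power.shape[0]
    means = np.empty((n_boot, power.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, K, size=K)
        means[b] = power[idx].mean(axis=0)
    alpha = (1 - ci) / 2
    return BootstrapVariance(
        var_of_mean=means.var(axis=0, ddof=1) if n_boot > 1 else np.zeros(power.shape[1]),
        ci_low=np.quantile(means, alpha, axis=0),
        ci_high=np.quantile(means, 1 - alpha, axis=0),
        n_boot=n_boot,
        n_cells=K,
        degenerate=n_boot < 2,
    )


@dataclass
class VariancePartition:
    """Per-frequency split of periodogram variance."""

    freqs: np.ndarray
    total: np.ndarray
    detector: np.ndarray
    stochastic: np.ndarray
    detector_fraction: np.ndarray
    n_floored: int  # frequencies where detector > total (floored at 0)

    @property
    def max_detector_fraction(self) -> float:
        return float(np.nanmax(self.detector_fraction))

    @property
    def stochastic_share(self) -> float:
        """Fraction of summed variance that is stochastic."""
        return float(self.stochastic.sum() / self.total.sum())


def partition(freqs, total, detector) -> VariancePartition:
    """Subtract the detector contribution per frequency.

    Negative stochastic components (subtraction artifacts where the
    detector estimate exceeds the total) are floored at 0 and counted.
    """
    freqs = np.asarray(freqs, dtype=float)
    total = np.asarray(total, dtype=float)
    detector = np.asarray(detector, dtype=float)
    if not (freqs.size == total.size == detector.size):
        raise ValueError("mismatched frequency grids")
    stoch = total - detector
    n_floor = int((stoch < 0).sum())
    stoch = np.maximum(stoch, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, np.minimum(detector / total, 1.0), np.nan)
    return VariancePartition(
        freqs=freqs, total=total, detector=detector, stochastic=stoch,
        detector_fraction=frac, n_floored=n_floor,
    )


def partition_fraction_ci(
    bare_power: np.ndarray,
    freqs: np.ndarray,
    sigma_det2: float,
    n_frames_raw: int,
    window_h: float | None = 24.0,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
):
    """Partition with a bootstrap CI on the summary detector fraction.

    Resamples cells with replacement; for each replicate recomputes the
    total per-cell variance, the detector propagation (which depends on the
    replicate's mean bare periodogram), and the max-over-frequency detector
    fraction. Returns (partition_at_full_sample, (lo, hi)).
    """
    bare_power = np.asarray(bare_power, dtype=float)
    K = bare_power.shape[0]
    rng = np.random.default_rng(seed)

    def max_frac(p):
        tot = p.var(axis=0, ddof=1)
        det = detector_variance_to_periodogram(
            sigma_det2, p.mean(axis=0), n_frames_raw, window_h
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            fr = np.where(tot > 0, det / tot, np.nan)
        return float(np.nanmax(fr))

    full = partition(
        freqs,
        bare_power.var(axis=0, ddof=1),
        detector_variance_to_periodogram(
            sigma_det2, bare_power.mean(axis=0), n_frames_raw, window_h
        ),
    )
    reps = np.array([max_frac(bare_power[rng.integers(0, K, K)]) for _ in range(n_boot)])
    alpha = (1 - ci) / 2
    return full, (float(np.quantile(reps, alpha)), float(np.quantile(reps, 1 - alpha)))


def detector_share_ci(
    bare_power: np.ndarray,
    sigma_det2: float,
    n_frames_raw: int,
    window_h: float | None = 24.0,
    n_boot: int = 400,
    seed: int = 0,
    ci: float = 0.95,
):
    """Summed-over-frequency detector share of periodogram variance with a
    cell-resampling bootstrap CI.

    share = sum_l (sigma_l^e)^2 / sum_l (sigma_l)^2. Aggregating over the
    frequency axis gives a stable summary of how much of the cell-to-cell
    periodogram variation is measurement noise (the per-frequency maximum
    reported by :func:`partition` is noisier, especially at high shares).
    """
    bare_power = np.asarray(bare_power, dtype=float)
    K = bare_power.shape[0]
    rng = np.random.default_rng(seed)

    def share(p):
        det = detector_variance_to_periodogram(
            sigma_det2, p.mean(axis=0), n_frames_raw, window_h
        )
        return float(det.sum() / p.var(axis=0, ddof=1).sum())

    full = share(bare_power)
    reps = np.array([share(bare_power[rng.integers(0, K, K)]) for _ in range(n_boot)])
    alpha = (1 - ci) / 2
    return full, (float(np.quantile(reps, alpha)), float(np.quantile(reps, 1 - alpha)))


@dataclass
class HarmonicAnovaTable:
    """Per-frequency (2 df) harmonic analysis of variance, SS-scaled to 1."""

    freqs: np.ndarray
    ss_model: np.ndarray  # scaled, one per model frequency
    ss_error: float
    df_model: np.ndarray
    df_error: int
    ems_model: np.ndarray
    ems_error: float
    f_values: np.ndarray
    p_values: np.ndarray
    model_share: float  # sum of model SS (scaled): fraction of total

    def __post_init__(self):
        if np.any(self.ss_model < 0) or self.ss_error < -1e-12:
            raise ValueError("sums of squares must be nonnegative")


def anova_from_sums_of_squares(freqs, ss_model, ss_error, df_error,
                               df_per_freq: int = 2) -> HarmonicAnovaTable:
    """Assemble the ANOVA table from (possibly already scaled) SS values.

    All SS are rescaled so they sum to 1; EMS = SS/df on the *input* scale
    is preserved up to the common factor, so F ratios are scale-free.
    """
    freqs = np.asarray(freqs, dtype=float)
    ss_model = np.asarray(ss_model, dtype=float)
    total = ss_model.sum() + ss_error
    ss_model_s = ss_model / total
    ss_error_s = ss_error / total
    dfm = np.full(freqs.size, df_per_freq)
    ems_model = ss_model_s / dfm
    ems_error = ss_error_s / df_error
    with np.errstate(divide="ignore"):
        f_vals = np.where(ems_error > 0, ems_model / ems_error, np.inf)
    p_vals = np.array([
        float(_sps.f.sf(f, df_per_freq, df_error)) if np.isfinite(f) else 0.0
        for f in f_vals
    ])
    return HarmonicAnovaTable(
        freqs=freqs, ss_model=ss_model_s, ss_error=float(ss_error_s),
        df_model=dfm, df_error=int(df_error), ems_model=ems_model,
        ems_error=float(ems_error), f_values=f_vals, p_values=p_vals,
        model_share=float(ss_model_s.sum()),
    )


def harmonic_anova(
    series: np.ndarray,
    model_freqs,
    frame_dt: float = FRAME_DT_H,
    df_error: int | None = None,
) -> HarmonicAnovaTable:
    """Harmonic regression ANOVA of a time series.

    Each model frequency contributes a sine and a cosine regressor (2 df);
    the residual forms the error row. Model frequencies must lie on the
    observable grid l/(L*dt) and be distinct. SS are scaled to sum to 1.
    ``df_error`` defaults to n_points - 2*n_freqs - 1 (mean removed).
    """
    y = np.asarray(series, dtype=float)
    L = y.size
    model_freqs = np.asarray(model_freqs, dtype=float)
    if np.unique(np.round(model_freqs, 12)).size != model_freqs.size:
        raise ValueError("duplicate model frequencies")
    grid_l = model_freqs * L * frame_dt
    if not np.allclose(grid_l, np.round(grid_l), atol=1e-6):
        raise ValueError("model frequencies must lie on the observable grid")
    t = np.arange(L)
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    ss_model = np.empty(model_freqs.size)
    for i, f in enumerate(model_freqs):
        c = np.cos(2 * np.pi * f * t * frame_dt)
        s = np.sin(2 * np.pi * f * t * frame_dt)
        c -= c.mean()
        s -= s.mean()
        # grid frequencies: sine and cosine are orthogonal to each other
        ss_model[i] = (yc @ c) ** 2 / (c @ c) + ((yc @ s) ** 2 / (s @ s) if s @ s > 0 else 0.0)
    ss_error = max(ss_total - ss_model.sum(), 0.0)
    if df_error is None:
        df_error = L - 2 * model_freqs.size - 1
    return anova_from_sums_of_squares(model_freqs, ss_model, ss_error, df_error)
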