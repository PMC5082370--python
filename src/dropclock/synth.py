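"""Synthetic droplet experiments: cells, droplets, detection noise, beads.

Emulates the statistical structure of a ten-day droplet-microfluidics
acquisition: droplets load 1..max_a cells (truncated Poisson, as expected
for flow-focusing encapsulation), each cell carries an oscillatory clock
signal from one of three sources (stochastic Gillespie clock, deterministic
quorum-sensing droplet model, or Kuramoto phase oscillators), and the
recorded fluorescence adds the measurement chain on top:

    raw(t) = E(t) * B(t) * (gain * signal(t) + background) + eps(t)

with E(t) the shared excitation-lamp fluctuation (also multiplying the
Rhodamine-B reference channel), B(t) = exp(-bleach_rate * t) the
photobleaching trend, and eps(t) ~ Normal(0, sigma^2(I)) additive detection
noise whose variance is quadratic in the noise-free intensity I:
sigma^2(I) = c0 + c1*I + c2*I^2, the empirical bead-calibrated error model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gillespie import (
    ReactionNetwork,
    build_default_clock,
    ensemble_species_matrix,
    gillespie_ensemble,
)
from .tables import FRAME_DT_H

__all__ = [
    "DropletLayout",
    "NoiseModel",
    "make_layout",
    "synthesize_experiment",
    "synthesize_beads",
    "fit_noise_model",
    "truncated_poisson_pmf",
]

#: default photobleaching rate: total decay over 240 h is ~15% (<= 20%)
DEFAULT_BLEACH_RATE = 6.8e-4


@dataclass
class DropletLayout:
    """Droplet identities and occupancies for one acquisition."""

    droplet_ids: list
    cells_per_droplet: np.ndarray
    genotype: str = "reference"

    def __post_init__(self):
        self.cells_per_droplet = np.asarray(self.cells_per_droplet, dtype=int)
        if (self.cells_per_droplet < 1).any():
            raise ValueError("every droplet must hold at least one cell")
        if len(set(self.droplet_ids)) != len(self.droplet_ids):
            raise ValueError("droplet ids must be unique")

    @property
    def n_droplets(self) -> int:
        return len(self.droplet_ids)

    @property
    def n_cells(self) -> int:
        return int(self.cells_per_droplet.sum())

    def cell_assignments(self) -> tuple[list, list]:
        """Parallel lists (droplet_id, cell_id) for every cell."""
        dids, cids = [], []
        for d, a in zip(self.droplet_ids, self.cells_per_droplet):
            for j in range(a):
                dids.append(d)
                cids.append(f"{d}_c{j}")
        return dids, cids


@dataclass
class NoiseModel:
    """Detection-noise and trend parameters of the measurement chain."""

    c0: float = 1.0
    c1: float = 0.01
    c2: float = 1e-5
    bleach_rate: float = DEFAULT_BLEACH_RATE
    excitation_cv: float = 0.05

    def __post_init__(self):
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")

    def variance(self, intensity: np.ndarray) -> np.ndarray:
        v = self.c0 + self.c1 * np.asarray(intensity, float) + self.c2 * np.asarray(intensity, float) ** 2
        if np.any(v < 0):
            raise ValueError("noise variance negative on the operating range")
        return v


def truncated_poisson_pmf(loading_mean: float, max_a: int) -> np.ndarray:
    """pmf of Poisson(loading_mean) truncated to {1, ..., max_a}."""
    k = np.arange(1, max_a + 1)
    logp = k * np.log(loading_mean) - loading_mean - np.cumsum(np.log(k))
    p = np.exp(logp - logp.max())
    return p / p.sum()


def make_layout(
    n_droplets: int,
    loading_mean: float = 0.8,
    max_a: int = 20,
    seed: int = 0,
    genotype: str = "reference",
) -> DropletLayout:
    """Draw droplet occupancies from a truncated Poisson law."""
    if loading_mean <= 0:
        raise ValueError("loading_mean must be positive")
    rng = np.random.default_rng(seed)
    pmf = truncated_poisson_pmf(loading_mean, max_a)
    a = rng.choice(np.arange(1, max_a + 1), size=n_droplets, p=pmf)
    ids = [f"d{i:05d}" for i in range(n_droplets)]
    return DropletLayout(droplet_ids=ids, cells_per_droplet=a, genotype=genotype)


def _excitation_series(n_frames: int, cv: float, rng) -> np.ndarray:
    """Mean-1, positive, frame-wise excitation factor with the given CV."""
    if cv == 0:
        return np.ones(n_frames)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_frames))


def _gillespie_signals(layout, t_end, frame_dt, seed, net: ReactionNetwork | None,
                       phase_burnin_h: float = 24.0) -> np.ndarray:
    """CCG-2 protein counts per cell, with a per-cell random burn-in offset
    so initial phases are dispersed across cells (as after ten days in the
    dark)."""
    net = net or build_default_clock()
    n_cells = layout.n_cells
    burn_frames = int(round(phase_burnin_h / frame_dt))
    trajs = gillespie_ensemble(net, n_cells, t_end + phase_burnin_h, frame_dt, seed=seed)
    M = ensemble_species_matrix(trajs, "CCG2").astype(float)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(10**6,)))
    offsets = rng.integers(0, burn_frames + 1, size=n_cells)
    n_frames = int(round(t_end / frame_dt))
    return np.vstack([M[i, o : o + n_frames] for i, o in enumerate(offsets)])


def _quorum_signals(layout, t_end, frame_dt, seed, params=None) -> np.ndarray:
    from .quorum import QuorumParams, simulate_droplet_ensemble

    params = params or QuorumParams()
    return simulate_droplet_ensemble(layout, params, t_end, frame_dt, seed=seed)


def _kuramoto_signals(layout, t_end, frame_dt, seed, params=None) -> np.ndarray:
    from .quorum import KuramotoParams, kuramoto_signal_matrix

    params = params or KuramotoParams()
    return kuramoto_signal_matrix(layout, params, t_end, frame_dt, seed=seed)


_SOURCES = {
    "gillespie": _gillespie_signals,
    "quorum": _quorum_signals,
    "kuramoto": _kuramoto_signals,
}


def synthesize_experiment(
    layout: DropletLayout,
    source: str = "gillespie",
    noise: NoiseModel | None = None,
    t_end: float = 240.0,
    frame_dt: float = FRAME_DT_H,
    seed: int = 0,
    gain: float = 1.0,
    background: float = 50.0,
    rhodamine_level: float = 1000.0,
    source_params=None,
    return_truth: bool = False,
):
    """Generate a raw long-format trajectory table for a droplet layout.

    ``source`` selects the clock signal generator; ``noise`` the measurement
    chain. With all noise coefficients, excitation CV and bleach rate at
    zero the table equals ``gain*signal + background`` exactly. Negative
    intensities after adding detection noise are clipped at a small floor
    and counted (reported via the truth dict when requested).
    """
    if source not in _SOURCES:
        raise ValueError(f"unknown source {source!r}; choose from {sorted(_SOURCES)}")
    noise = noise or NoiseModel()
    n_frames = int(round(t_end / frame_dt))
    signals = _SOURCES[source](layout, t_end, frame_dt, seed, source_params)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(2 * 10**6,)))
    E = _excitation_series(n_frames, noise.excitation_cv, rng)
    times = np.arange(n_frames) * frame_dt
    B = np.exp(-noise.bleach_rate * times)
    clean = E[None, :] * B[None, :] * (gain * signals + background)
    eps = rng.normal(0.0, np.sqrt(noise.variance(clean)))
    raw = clean + eps
    floor = 1e-6
    n_clipped = int((raw < floor).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} negative intensities clipped at the floor")
        raw = np.maximum(raw, floor)
    dids, cids = layout.cell_assignments()
    table = pd.DataFrame(
        {
            "droplet_id": np.repeat(dids, n_frames),
            "cell_id": np.repeat(cids, n_frames),
            "frame": np.tile(np.arange(n_frames), layout.n_cells),
            "fluorescence": raw.ravel(),
            "rhodamine": np.tile(rhodamine_level * E, layout.n_cells),
            "is_bead": False,
        }
    )
    if return_truth:
        truth = {
            "signals": signals,
            "excitation": E,
            "bleach": B,
            "clean_intensity": clean,
            "n_clipped": n_clipped,
        }
        return table, truth
    return table


def synthesize_beads(
    n_beads: int,
    intensity_levels,
    noise: NoiseModel | None = None,
    t_end: float = 240.0,
    frame_dt: float = FRAME_DT_H,
    seed: int = 0,
    rhodamine_level: float = 1000.0,
) -> pd.DataFrame:
    """Constant-intensity bead control run through the same detection chain.

    Beads cycle through ``intensity_levels``; doped beads do not bleach.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    noise = noise or NoiseModel(bleach_rate=0.0)
    levels = np.asarray(intensity_levels, dtype=float)
    n_frames = int(round(t_end / frame_dt))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(3 * 10**6,)))
    E = _excitation_series(n_frames, noise.excitation_cv, rng)
    frames = np.arange(n_frames)
    recs = []
    for b in range(n_beads):
        level = levels[b % levels.size]
        clean = E * level
        raw = clean + rng.normal(0.0, np.sqrt(noise.variance(clean)))
        raw = np.maximum(raw, 1e-6)
        recs.append(
            pd.DataFrame(
                {
                    "droplet_id": f"bead_d{b:04d}",
                    "cell_id": f"bead{b:04d}",
                    "frame": frames,
                    "fluorescence": raw,
                    "rhodamine": rhodamine_level * E,
                    "is_bead": True,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


@dataclass
class NoiseFit:
    """Quadratic error-model fit with residual diagnostics."""

    model: NoiseModel
    coef_se: np.ndarray
    t_values: np.ndarray
    residuals: np.ndarray
    means: np.ndarray
    variances: np.ndarray


def fit_noise_model(bead_table: pd.DataFrame) -> NoiseFit:
    """Least-squares quadratic fit of per-bead variance on mean intensity.

    Each bead contributes one (mean intensity, sample variance) point; the
    variance function sigma^2(I) = c0 + c1 I + c2 I^2 is fit by ordinary
    least squares. Requires >= 3 distinct intensity levels, otherwise the
    quadratic is unidentifiable.
    """
    g = bead_table.groupby("cell_id")["fluorescence"]
    means = g.mean().to_numpy()
    variances = g.var(ddof=1).to_numpy()
    if np.unique(np.round(means / means.max(), 2)).size < 3:
        raise ValueError("need beads at >= 3 distinct intensity levels")
    X = np.column_stack([np.ones_like(means), means, means**2])
    coef, res_ss, *_ = np.linalg.lstsq(X, variances, rcond=None)
    fitted = X @ coef
    resid = variances - fitted
    dof = max(means.size - 3, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = coef / np.where(se > 0, se, np.inf)
    model = NoiseModel(c0=float(coef[0]), c1=float(coef[1]), c2=float(coef[2]))
    return NoiseFit(
        model=model, coef_se=se, t_values=t, residuals=resid, means=means,
        variances=variances,
    )
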