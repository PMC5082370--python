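"""Periodograms, period/amplitude extraction, and Hilbert phase.

The periodogram of a detrended cell trajectory of length L frames is the
squared modulus of its discrete Fourier transform on the observable
frequency grid f_l = l / (L * dt), l = 1..floor(L/2); dividing by the sum
over l gives the *normalized* periodogram, interpretable as the fraction of
oscillatory power at each frequency. A cell's period is 1/f at the
periodogram argmax and its amplitude is the square root of the maximum
normalized power. Phase is measured in cycles completed over a fixed window
via the analytic (Hilbert) signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmax, hilbert

from .tables import FRAME_DT_H, TrajectorySet

__all__ = [
    "PeriodogramSet",
    "AveragePeriodogram",
    "PhaseSummary",
    "periodogram",
    "periodogram_set",
    "extract_period_amplitude",
    "secondary_peak",
    "hilbert_phase",
    "average_periodogram",
    "phase_summaries",
]


@dataclass
class PeriodogramSet:
    """Per-cell power on a common observable frequency grid.

    ``power`` has shape (n_cells, n_freq); ``freqs`` are in 1/h.
    """

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool
    cell_ids: list = field(default_factory=list)
    droplet_ids: list = field(default_factory=list)

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.freqs


@dataclass
class AveragePeriodogram:
    """Cell-averaged normalized power with per-frequency sample variance."""

    freqs: np.ndarray
    mean: np.ndarray
    var: np.ndarray  # sample variance across cells (ddof=1)
    n_cells: int


@dataclass
class PhaseSummary:
    """Per-cell oscillator summaries over the analysis window."""

    cell_ids: list
    phase_cycles: np.ndarray
    period_h: np.ndarray
    amplitude: np.ndarray
    tie_flags: np.ndarray


def _freq_grid(L: int, frame_dt: float) -> np.ndarray:
    n = L // 2
    return np.arange(1, n + 1) / (L * frame_dt)


def periodogram(
    series: np.ndarray, frame_dt: float = FRAME_DT_H, normalized: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram of one series on the observable frequency grid.

    Returns ``(freqs, power)``. The DC term is excluded (input is assumed
    detrended); for even L the grid ends at the Nyquist frequency.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("need a 1-D series of at least 8 frames")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    L = x.size
    X = np.fft.rfft(x)
    n = L // 2
    power = np.abs(X[1 : n + 1]) ** 2
    freqs = _freq_grid(L, frame_dt)
    if normalized:
        total = power.sum()
        if total == 0:
            raise ValueError("degenerate (constant) series: no power to normalize")
        power = power / total
    return freqs, power


def periodogram_set(
    ts: TrajectorySet, frame_dt: float = FRAME_DT_H, normalized: bool = True
) -> PeriodogramSet:
    """Periodograms of every cell in a (detrended) trajectory set."""
    rows = []
    freqs = None
    for i in range(ts.n_cells):
        f, p = periodogram(ts.values[i], frame_dt=frame_dt, normalized=normalized)
        freqs = f
        rows.append(p)
    return PeriodogramSet(
        freqs=freqs,
        power=np.vstack(rows),
        normalized=normalized,
        cell_ids=list(ts.cell_ids),
        droplet_ids=list(ts.droplet_ids),
    )


def extract_period_amplitude(
    freqs: np.ndarray, power: np.ndarray
) -> tuple[float, float, bool]:
    """Period (h) and amplitude from a normalized periodogram.

    Period is 1/f at the argmax; amplitude is sqrt(max power). Exact ties
    between maxima break toward the lower frequency (longer period) and set
    the returned flag.
    """
    power = np.asarray(power, dtype=float)
    imax = int(np.argmax(power))  # argmax returns the first (lowest-f) maximum
    tie = bool(np.sum(power == power[imax]) > 1)
    return 1.0 / freqs[imax], float(np.sqrt(power[imax])), tie


def secondary_peak(freqs: np.ndarray, power: np.ndarray) -> tuple[float, float] | None:
    """Second-highest *local* maximum of the periodogram.

    Returns ``(period_h, power)`` or ``None`` when no second local maximum
    exists (e.g. a single tone). Consistent with the primary tie rule: for
    equal twin peaks the secondary is the one not chosen as primary.
    """
    power = np.asarray(power, dtype=float)
    floor = 1e-9 * power.max()  # ignore numerical noise ripple
    interior = argrelmax(power)[0]
    # endpoints can host maxima too
    cand = set(interior.tolist())
    if power.size >= 2:
        if power[0] > power[1]:
            cand.add(0)
        if power[-1] > power[-2]:
            cand.add(power.size - 1)
    # plateau-tied twin peaks: argrelmax misses flat tops, add exact ties of max
    pmax = power.max()
    cand.update(np.flatnonzero(power == pmax).tolist())
    cand = sorted(i for i in cand if power[i] > floor)
    if len(cand) < 2:
        return None
    primary = int(np.argmax(power))
    rest = [i for i in cand if i != primary]
    isec = rest[int(np.argmax(power[rest]))]
    return 1.0 / freqs[isec], float(power[isec])


def hilbert_phase(
    series: np.ndarray,
    t0_frame: int = 60,
    t1_frame: int = 230,
    series_start_frame: int = 0,
) -> float:
    """Phase in cycles completed over the window [t0, t1].

    The analytic signal is computed on the *full* (mean-subtracted) series
    to confine Hilbert edge effects to the ends, then the instantaneous
    phase is unwrapped recursively (each increment adjusted by the multiple
    of 2*pi minimizing its magnitude) and the phase advance over the window
    divided by 2*pi.

    ``series_start_frame`` maps the absolute frame indices ``t0_frame`` and
    ``t1_frame`` to positions in ``series`` (useful after detrending trims
    edges). A constant series degenerately yields 0 cycles.
    """
    x = np.asarray(series, dtype=float)
    i0 = t0_frame - series_start_frame
    i1 = t1_frame - series_start_frame
    if i0 < 0 or i1 >= x.size or i0 >= i1:
        raise ValueError("phase window falls outside the series")
    if np.ptp(x) == 0:
        return 0.0
    analytic = hilbert(x - x.mean())
    phi = np.unwrap(np.angle(analytic))
    return float((phi[i1] - phi[i0]) / (2 * np.pi))


def average_periodogram(pgrams: PeriodogramSet) -> AveragePeriodogram:
    """Cell-averaged periodogram with per-frequency sample variance.

    The mean of normalized rows already sums to 1, so no renormalization is
    applied.
    """
    if pgrams.power.shape[0] < 2:
        raise ValueError("need at least 2 cells to average")
    return AveragePeriodogram(
        freqs=pgrams.freqs.copy(),
        mean=pgrams.power.mean(axis=0),
        var=pgrams.power.var(axis=0, ddof=1),
        n_cells=pgrams.power.shape[0],
    )


def phase_summaries(
    ts: TrajectorySet,
    pgrams: PeriodogramSet | None = None,
    t0_frame: int = 60,
    t1_frame: int = 230,
) -> PhaseSummary:
    """Per-cell phase, period and amplitude for a detrended set."""
    if pgrams is None:
        pgrams = periodogram_set(ts)
    periods = np.empty(ts.n_cells)
    amps = np.empty(ts.n_cells)
    ties = np.zeros(ts.n_cells, dtype=bool)
    phases = np.empty(ts.n_cells)
    start = int(ts.frames[0])
    for i in range(ts.n_cells):
        periods[i], amps[i], ties[i] = extract_period_amplitude(
            pgrams.freqs, pgrams.power[i]
        )
        phases[i] = hilbert_phase(
            ts.values[i], t0_frame=t0_frame, t1_frame=t1_frame, series_start_frame=start
        )
    return PhaseSummary(
        cell_ids=list(ts.cell_ids),
        phase_cycles=phases,
        period_h=periods,
        amplitude=amps,
        tie_flags=ties,
    )
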