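"""Mean-field quorum-sensing droplet model and Kuramoto control model.

Quorum sensing: each cell runs the deterministic mirror of the stochastic
clock network (gene states replaced by their mean occupancy) and secretes a
signaling molecule S_j produced from its clock-controlled gene product
CCG-2. The signal exchanges with a single well-mixed external pool S^e at
rate eta (per cell) and eta_ext (pool side, volume ratio folded in), decays
at D9 inside the cell and D10 in the droplet medium, and feeds back by
slowing WCC formation: the formation rate is multiplied by the zero-clipped
factor max(0, 1 - C4*S_j), and S additionally drains WC-1 and WC-2 at rate
C2*S_j (both terms clipped at zero, keeping all concentrations
nonnegative). High collective CCG-2 output therefore delays every cell's
WCC resurgence — a population-level negative feedback closing through the
shared pool, which is what synchronizes the droplet.

The Kuramoto control replaces the biochemistry with bare phase oscillators
d phi_j/dt = omega_j + (K_c/a) sum_k sin(phi_k - phi_j) (plus optional
white phase noise) and maps phase to pseudo-fluorescence amplitude*sin(phi),
providing a mechanism-free benchmark with the same droplet data structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .gillespie import ClockParamVector, default_clock_params
from .tables import FRAME_DT_H

__all__ = [
    "QuorumParams",
    "QuorumTrajectory",
    "clock_ode_rhs",
    "single_cell_limit_cycle",
    "simulate_droplet",
    "simulate_droplet_ensemble",
    "model_icc_surface",
    "KuramotoParams",
    "kuramoto_simulate",
    "kuramoto_signal_matrix",
]

# per-cell clock state layout in the coupled ODE
_CLOCK_SPECIES = ["frq_mrna", "FRQ", "wc1_mrna", "WC1", "WC2", "WCC", "ccg2_mrna", "CCG2"]
_NS = len(_CLOCK_SPECIES) + 1  # + intracellular signal S_j


@dataclass
class QuorumParams:
    """Coupling and signal parameters of the mean-field droplet model.

    Rates are 1/h. ``k_S1`` is the nominal signal production coefficient;
    ``signal_scale`` is the unit/volume conversion folding molecule counts
    into signal concentration units, so the effective production rate is
    ``k_S1 * signal_scale`` per CCG-2 molecule. ``eta_ext`` absorbs the
    cell-to-droplet volume ratio of the pool-side exchange.
    """

    D2: float = 0.0001
    eta: float = 100.0
    eta_ext: float = 1.44
    D9: float = 26.0
    D10: float = 4.0
    C2: float = 0.002
    C4: float = 0.8
    k_S1: float = 5e9
    signal_scale: float = 1e-10
    clock_params: ClockParamVector | None = None

    def __post_init__(self):
        for name in ("D2", "eta", "eta_ext", "D9", "D10", "C2", "C4", "k_S1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.clock_params is None:
            self.clock_params = default_clock_params()

    @property
    def k_sig(self) -> float:
        return self.k_S1 * self.signal_scale


@dataclass
class QuorumTrajectory:
    """Integrated droplet time series."""

    times: np.ndarray
    cells: np.ndarray  # (a, len(_CLOCK_SPECIES)+1, n_frames)
    external_signal: np.ndarray

    def species(self, name: str) -> np.ndarray:
        idx = (_CLOCK_SPECIES + ["S"]).index(name)
        return self.cells[:, idx, :]

    @property
    def ccg(self) -> np.ndarray:
        return self.species("CCG2")


def clock_ode_rhs(p: dict, coupling=None):
    """Deterministic mirror of the stochastic clock network.

    Gene on/off states are replaced by their stationary occupancy
    p_on = k_on/(k_on+k_off). ``coupling`` optionally supplies
    (S, C2, C4, k_sig, exchange) terms for one cell of the droplet model.
    """
    p_on = p["k_gene_on"] / (p["k_gene_on"] + p["k_gene_off"])

    def rhs(y):
        Mf, Pf, Mw, W1, W2, C, Mc, Pc = [max(v, 0.0) for v in y]
        hA = C ** p["n_act"] / (p["K_act"] ** p["n_act"] + C ** p["n_act"])
        hR = p["K_rep"] ** p["n_rep"] / (p["K_rep"] ** p["n_rep"] + Pf ** p["n_rep"])
        form = p["k_WCC"] * W1 * W2
        return np.array([
            p_on * p["k_tx_frq"] * hA - p["d_mrna_frq"] * Mf,
            p["k_tl_frq"] * Mf - p["d_FRQ"] * Pf,
            p_on * p["k_tx_wc1"] * hR - p["d_mrna_wc1"] * Mw,
            p["k_tl_wc1"] * Mw - p["d_WC1"] * W1 - form,
            p["k_WC2"] - p["d_WC2"] * W2 - form,
            form - p["d_WCC"] * C - p["k_inact"] * Pf * C,
            p_on * p["k_tx_ccg2"] * hA - p["d_mrna_ccg2"] * Mc,
            p["k_tl_ccg2"] * Mc - p["d_CCG2"] * Pc,
        ])

    return rhs


_limit_cycle_cache: dict = {}


def single_cell_limit_cycle(clock_params: ClockParamVector | None = None,
                            n_samples: int = 512) -> np.ndarray:
    """One period of the uncoupled deterministic clock, sampled uniformly.

    Returns an (n_samples, 8) array usable as a bank of initial conditions
    at controlled phases. Cached per parameter set.
    """
    cp = clock_params or default_clock_params()
    key = (tuple(sorted(cp.theta.items())), n_samples)
    if key in _limit_cycle_cache:
        return _limit_cycle_cache[key]
    p = cp.theta
    rhs = clock_ode_rhs(p)
    y0 = np.array([p["init_frq_mrna"], p["init_FRQ"], p["init_wc1_mrna"],
                   p["init_WC1"], p["init_WC2"], p["init_WCC"],
                   p["init_ccg2_mrna"], p["init_CCG2"]], dtype=float)
    sol = solve_ivp(lambda t, y: rhs(y), [0.0, 600.0], y0, method="LSODA",
                    rtol=1e-8, atol=1e-8, dense_output=True)
    # locate the period from late upward mean-crossings of CCG-2
    t = np.linspace(400.0, 600.0, 8000)
    pc = sol.sol(t)[7]
    x = pc - pc.mean()
    cross = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
    if cross.size < 3:
        raise RuntimeError("uncoupled clock shows no limit cycle")
    period = float(np.diff(t[cross]).mean())
    t0 = t[cross[0]]
    phases = t0 + np.linspace(0.0, period, n_samples, endpoint=False)
    cycle = sol.sol(phases).T
    _limit_cycle_cache[key] = cycle
    return cycle


def _droplet_rhs(params: QuorumParams):
    p = params.clock_params.theta
    p_on = p["k_gene_on"] / (p["k_gene_on"] + p["k_gene_off"])
    k_sig = params.k_sig

    def rhs(t, y, a):
        y = np.maximum(y, 0.0)
        cells = y[:-1].reshape(a, _NS)
        Se = y[-1]
        dy = np.empty_like(cells)
        Mf, Pf, Mw, W1, W2, C, Mc, Pc, S = cells.T
        hA = C ** p["n_act"] / (p["K_act"] ** p["n_act"] + C ** p["n_act"])
        hR = p["K_rep"] ** p["n_rep"] / (p["K_rep"] ** p["n_rep"] + Pf ** p["n_rep"])
        # signal slows WCC formation (zero-clipped) and drains WC-1/WC-2
        form = p["k_WCC"] * W1 * W2 * np.maximum(0.0, 1.0 - params.C4 * S)
        dy[:, 0] = p_on * p["k_tx_frq"] * hA - p["d_mrna_frq"] * Mf
        dy[:, 1] = p["k_tl_frq"] * Mf - p["d_FRQ"] * Pf
        dy[:, 2] = p_on * p["k_tx_wc1"] * hR - p["d_mrna_wc1"] * Mw
        dy[:, 3] = p["k_tl_wc1"] * Mw - p["d_WC1"] * W1 - form - params.C2 * S * W1
        dy[:, 4] = p["k_WC2"] - p["d_WC2"] * W2 - form - params.C2 * S * W2
        dy[:, 5] = form - p["d_WCC"] * C - p["k_inact"] * Pf * C
        dy[:, 6] = p_on * p["k_tx_ccg2"] * hA - p["d_mrna_ccg2"] * Mc
        dy[:, 7] = p["k_tl_ccg2"] * Mc - p["d_CCG2"] * Pc - params.D2 * Pc
        dy[:, 8] = k_sig * Pc - params.eta * (S - Se) - params.D9 * S
        dSe = params.eta_ext * np.sum(S - Se) - params.D10 * Se
        return np.append(dy.ravel(), dSe)

    return rhs


def simulate_droplet(
    params: QuorumParams,
    t_end: float,
    frame_dt: float = FRAME_DT_H,
    init: np.ndarray | None = None,
    a: int | None = None,
) -> QuorumTrajectory:
    """Integrate one droplet of coupled deterministic clocks.

    ``init`` is either a full state vector (a*9 + 1, ordered per cell as
    [frq mRNA, FRQ, wc-1 mRNA, WC-1, WC-2, WCC, ccg-2 mRNA, CCG-2, S] then
    S^e), or None, in which case ``a`` cells start on the uncoupled limit
    cycle at evenly spread phases with S = S^e = 0.
    """
    if init is None:
        if a is None:
            raise ValueError("give either init or a")
        cycle = single_cell_limit_cycle(params.clock_params)
        picks = np.linspace(0, cycle.shape[0], a, endpoint=False).astype(int)
        cells = np.hstack([cycle[picks], np.zeros((a, 1))])
        init = np.append(cells.ravel(), 0.0)
    else:
        init = np.asarray(init, dtype=float)
        if (init < 0).any():
            raise ValueError("initial state must be nonnegative")
        a = (init.size - 1) // _NS
        if a * _NS + 1 != init.size:
            raise ValueError("init length must be a*9 + 1")
    n_frames = int(round(t_end / frame_dt))
    times = np.arange(n_frames) * frame_dt
    rhs = _droplet_rhs(params)
    sol = solve_ivp(rhs, [0.0, float(t_end)], init, args=(a,), method="LSODA",
                    rtol=1e-6, atol=1e-9, t_eval=times, dense_output=False)
    if not sol.success:
        raise RuntimeError(
            f"droplet integration failed at t={sol.t[-1] if sol.t.size else 0:.2f} h: "
            f"{sol.message}"
        )
    y = sol.y
    if y.min() < -1e-6:
        raise RuntimeError(f"negative concentration beyond tolerance: {y.min():.3g}")
    y = np.maximum(y, 0.0)
    cells = y[:-1].reshape(a, _NS, n_frames)
    return QuorumTrajectory(times=times, cells=cells, external_signal=y[-1])


def simulate_droplet_ensemble(
    layout,
    params: QuorumParams,
    t_end: float,
    frame_dt: float = FRAME_DT_H,
    seed: int = 0,
    init_jitter: float = 1.0,
) -> np.ndarray:
    """CCG-2 signal matrix (cells x frames) for every droplet of a layout.

    Cells start on the uncoupled limit cycle at phases drawn uniformly over
    ``init_jitter`` of the cycle (1.0 = fully dispersed phases).
    """
    rng = np.random.default_rng(seed)
    cycle = single_cell_limit_cycle(params.clock_params)
    n_frames = int(round(t_end / frame_dt))
    rows = []
    for a in layout.cells_per_droplet:
        picks = rng.integers(0, max(int(cycle.shape[0] * init_jitter), 1), size=a)
        cells = np.hstack([cycle[picks], np.zeros((a, 1))])
        init = np.append(cells.ravel(), 0.0)
        tr = simulate_droplet(params, t_end, frame_dt, init=init)
        rows.append(tr.ccg)
    return np.vstack(rows)[:, :n_frames]


def model_icc_surface(
    a_values,
    n_droplets: int,
    params: QuorumParams | None = None,
    t_end: float = 240.0,
    frame_dt: float = FRAME_DT_H,
    init_jitter: float = 1.0,
    seed: int = 0,
    min_droplets: int = 2,
):
    """ICC surface predicted by the quorum-sensing model.

    Simulates ``n_droplets`` replicate droplets for every a in
    ``a_values`` (a >= 2; ICC is undefined for singletons) with jittered
    initial phases, then evaluates the ICC surface on the CCG-2
    pseudo-fluorescence.
    """
    from .synchrony import icc_surface
    from .synth import DropletLayout
    from .tables import TrajectorySet

    if n_droplets < 2:
        raise ValueError("need >= 2 droplets per size")
    params = params or QuorumParams()
    a_values = [a for a in a_values if a >= 2]
    if not a_values:
        raise ValueError("ICC needs droplet sizes >= 2")
    ids, sizes = [], []
    for a in a_values:
        for i in range(n_droplets):
            ids.append(f"qa{a}_{i}")
            sizes.append(a)
    layout = DropletLayout(droplet_ids=ids, cells_per_droplet=np.array(sizes))
    signals = simulate_droplet_ensemble(
        layout, params, t_end, frame_dt, seed=seed, init_jitter=init_jitter
    )
    dids, cids = layout.cell_assignments()
    ts = TrajectorySet(values=signals, cell_ids=cids, droplet_ids=dids)
    return icc_surface(ts, min_droplets=min_droplets)


@dataclass
class KuramotoParams:
    """Phase-oscillator control model parameters."""

    omega_mean: float = 2 * np.pi / 21.6  # rad/h, matching the clock period
    omega_sd: float = 0.02  # rad/h dispersion of natural frequencies
    K_c: float = 0.2  # rad/h coupling
    noise_sd: float = 0.0  # rad/sqrt(h) white phase noise
    amplitude: float = 40.0
    omegas: np.ndarray | None = None  # explicit per-cell frequencies

    def __post_init__(self):
        if self.K_c < 0:
            raise ValueError("coupling K_c must be >= 0")


def kuramoto_simulate(
    params: KuramotoParams,
    layout,
    t_end: float,
    frame_dt: float = FRAME_DT_H,
    seed: int = 0,
    n_substeps: int = 10,
) -> np.ndarray:
    """Euler-Maruyama phases (n_cells x n_frames, radians, unwrapped).

    Coupling acts within droplets only: d phi_j = omega_j
    + (K_c/a) sum_{k in droplet} sin(phi_k - phi_j), plus optional white
    phase noise.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(t_end / frame_dt))
    dt = frame_dt / n_substeps
    sizes = layout.cells_per_droplet
    n_cells = layout.n_cells
    if params.omegas is not None:
        omegas = np.asarray(params.omegas, dtype=float)
        if omegas.size != n_cells:
            raise ValueError("omegas must have one entry per cell")
    else:
        omegas = rng.normal(params.omega_mean, params.omega_sd, size=n_cells)
    phi = rng.uniform(0, 2 * np.pi, size=n_cells)
    # droplet slices over the cell axis
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    out = np.empty((n_cells, n_frames))
    sq = params.noise_sd * np.sqrt(dt)
    for f in range(n_frames):
        out[:, f] = phi
        for _ in range(n_substeps):
            dphi = omegas.copy()
            for d in range(sizes.size):
                lo, hi = bounds[d], bounds[d + 1]
                a = hi - lo
                if a > 1:
                    block = phi[lo:hi]
                    # sum_k sin(phi_k - phi_j) via the mean phasor
                    z = np.exp(1j * block).sum()
                    dphi[lo:hi] += (params.K_c / a) * np.imag(z * np.exp(-1j * block))
            phi = phi + dphi * dt
            if sq > 0:
                phi = phi + rng.normal(0.0, sq, size=n_cells)
    return out


def kuramoto_signal_matrix(
    layout, params: KuramotoParams, t_end: float, frame_dt: float = FRAME_DT_H,
    seed: int = 0,
) -> np.ndarray:
    """Pseudo-fluorescence amplitude*sin(phi) per cell."""
    phases = kuramoto_simulate(params, layout, t_end, frame_dt, seed=seed)
    return params.amplitude * np.sin(phases)
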