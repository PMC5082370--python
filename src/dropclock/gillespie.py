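"""Stochastic clock network and exact Gillespie (direct-method) simulation.

The model is a transcription-translation negative-feedback clock for
*Neurospora crassa* conidia with bursting gene states: each of the three
loci (*frq*, *wc-1*, *ccg-2*) toggles randomly between a transcriptionally
active and inactive state; the White Collar Complex (WCC, formed from WC-1
and WC-2) activates *frq* and *ccg-2* transcription through Hill activation;
FRQ closes the loop both by Hill-type repression of *wc-1* transcription and
by catalyzing WCC inactivation. CCG-2 (driven by the *ccg-2* promoter) is
the fluorescent observable. Default rate constants are calibrated once so
the detrended CCG-2 ensemble oscillates with a principal period near 21 h
and mean ccg-2 mRNA counts of order 10^2 molecules/cell; they live in
``data/clock_params.yaml``.

Propensities are standard stochastic mass action, optionally multiplied by
a Hill activation x^n/(K^n+x^n) or repression K^n/(K^n+x^n) factor in a
regulator species.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from numba import njit

from .tables import FRAME_DT_H

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ClockParamVector",
    "SSATrajectory",
    "build_default_clock",
    "default_clock_params",
    "gillespie_run",
    "gillespie_ensemble",
    "MASS_ACTION",
    "HILL_ACTIVATION",
    "HILL_REPRESSION",
]

MASS_ACTION = "mass_action"
HILL_ACTIVATION = "hill_activation"
HILL_REPRESSION = "hill_repression"
_KIND_CODES = {MASS_ACTION: 0, HILL_ACTIVATION: 1, HILL_REPRESSION: 2}


@dataclass
class Reaction:
    """One reaction channel.

    ``reactants`` and ``products`` map species name -> stoichiometry
    (nonnegative integers). ``rate`` is the stochastic rate constant in 1/h
    (unimolecular) or 1/(molecule*h) (bimolecular). Hill-kind reactions
    multiply the mass-action propensity by a Hill factor in ``regulator``
    with midpoint ``K`` (molecules) and exponent ``n``.
    """

    reactants: dict
    products: dict
    rate: float
    kind: str = MASS_ACTION
    regulator: str | None = None
    K: float = 1.0
    n: float = 1.0
    name: str = ""

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError(f"negative rate in reaction {self.name!r}")
        for stoich in (*self.reactants.values(), *self.products.values()):
            if stoich < 0 or int(stoich) != stoich:
                raise ValueError("stoichiometries must be nonnegative integers")
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown rate-law kind {self.kind!r}")
        if self.kind != MASS_ACTION and self.regulator is None:
            raise ValueError("Hill rate laws need a regulator species")


@dataclass
class ReactionNetwork:
    species: list
    reactions: list
    initial_counts: np.ndarray

    def __post_init__(self):
        self.initial_counts = np.asarray(self.initial_counts, dtype=np.int64)
        if self.initial_counts.size != len(self.species):
            raise ValueError("initial_counts must match species")
        if (self.initial_counts < 0).any():
            raise ValueError("initial counts must be nonnegative")
        self._index = {s: i for i, s in enumerate(self.species)}

    def species_index(self, name: str) -> int:
        return self._index[name]

    def compiled(self):
        """Arrays consumed by the SSA kernel."""
        ns, nr = len(self.species), len(self.reactions)
        react = np.zeros((nr, ns), dtype=np.int64)
        change = np.zeros((nr, ns), dtype=np.int64)
        kinds = np.zeros(nr, dtype=np.int64)
        rates = np.zeros(nr)
        hill_K = np.ones(nr)
        hill_n = np.ones(nr)
        reg = np.zeros(nr, dtype=np.int64)
        for j, rx in enumerate(self.reactions):
            for s, v in rx.reactants.items():
                react[j, self._index[s]] = v
                change[j, self._index[s]] -= v
            for s, v in rx.products.items():
                change[j, self._index[s]] += v
            kinds[j] = _KIND_CODES[rx.kind]
            rates[j] = rx.rate
            hill_K[j] = rx.K
            hill_n[j] = rx.n
            reg[j] = self._index[rx.regulator] if rx.regulator else 0
        return react, change, kinds, rates, hill_K, hill_n, reg

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        """Propensity of every reaction at a state (reference path)."""
        react, change, kinds, rates, hill_K, hill_n, reg = self.compiled()
        return _propensities_py(
            np.asarray(counts, dtype=np.int64), react, kinds, rates, hill_K, hill_n, reg
        )

    # --- human-readable structured-text round trip ---------------------
    def to_text(self) -> str:
        lines = ["# species: name initial_count"]
        for s, c in zip(self.species, self.initial_counts):
            lines.append(f"species: {s} {int(c)}")
        lines.append("# reactions: reactants -> products @ law(params)")
        for rx in self.reactions:
            lhs = " + ".join(f"{v} {s}" if v != 1 else s for s, v in rx.reactants.items()) or "0"
            rhs = " + ".join(f"{v} {s}" if v != 1 else s for s, v in rx.products.items()) or "0"
            if rx.kind == MASS_ACTION:
                law = f"mass_action(k={rx.rate:.17g})"
            else:
                law = (
                    f"{rx.kind}(k={rx.rate:.17g}, regulator={rx.regulator}, "
                    f"K={rx.K:.17g}, n={rx.n:.17g})"
                )
            lines.append(f"reaction: {lhs} -> {rhs} @ {law}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ReactionNetwork":
        species, counts, reactions = [], [], []

        def parse_side(side):
            out = {}
            side = side.strip()
            if side == "0":
                return out
            for term in side.split("+"):
                parts = term.split()
                if len(parts) == 1:
                    out[parts[0]] = out.get(parts[0], 0) + 1
                else:
                    out[parts[1]] = out.get(parts[1], 0) + int(parts[0])
            return out

        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("species:"):
                _, name, c = line.split()
                species.append(name)
                counts.append(int(c))
            elif line.startswith("reaction:"):
                body = line[len("reaction:"):].strip()
                eq, law = body.split("@")
                lhs, rhs = eq.split("->")
                kind, _, argstr = law.strip().partition("(")
                args = {}
                for kv in argstr.rstrip(")").split(","):
                    k, v = kv.split("=")
                    args[k.strip()] = v.strip()
                reactions.append(
                    Reaction(
                        reactants=parse_side(lhs),
                        products=parse_side(rhs),
                        rate=float(args["k"]),
                        kind=kind.strip(),
                        regulator=args.get("regulator"),
                        K=float(args.get("K", 1.0)),
                        n=float(args.get("n", 1.0)),
                    )
                )
        return cls(species=species, reactions=reactions, initial_counts=np.array(counts))


@dataclass
class ClockParamVector:
    """Named parameter vector Theta over which the ensemble fit samples.

    ``log_scale_mask`` marks entries proposed multiplicatively (log scale)
    by the MCMC; count-valued entries stay on the linear scale.
    """

    theta: dict
    log_scale_mask: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.theta.items():
            if k.startswith("init_"):
                if v < 0 or int(v) != v:
                    raise ValueError(f"count parameter {k} must be a nonnegative integer")
            elif v < 0:
                raise ValueError(f"rate parameter {k} must be nonnegative")

    def replace(self, **updates) -> "ClockParamVector":
        theta = dict(self.theta)
        theta.update(updates)
        return ClockParamVector(theta=theta, log_scale_mask=dict(self.log_scale_mask))


@dataclass
class SSATrajectory:
    """State sampled on a regular frame grid (0.5 h default spacing)."""

    frame_times: np.ndarray
    counts: np.ndarray  # species x frames
    species: list

    def series(self, name: str) -> np.ndarray:
        return self.counts[self.species.index(name)]


def _p_on(k_on: float, k_off: float) -> float:
    return k_on / (k_on + k_off)


def default_clock_params() -> ClockParamVector:
    """Calibrated default parameters, loaded from the versioned file."""
    with importlib.resources.files("dropclock.data").joinpath("clock_params.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    mask = raw.pop("_log_scale", [])
    return ClockParamVector(theta=raw, log_scale_mask={k: True for k in mask})


def build_default_clock(params: ClockParamVector | None = None) -> ReactionNetwork:
    """Assemble the bursting Hill-type negative-feedback clock network."""
    p = (params or default_clock_params()).theta
    species = [
        "frq_gene_off", "frq_gene_on",
        "wc1_gene_off", "wc1_gene_on",
        "ccg2_gene_off", "ccg2_gene_on",
        "frq_mrna", "FRQ",
        "wc1_mrna", "WC1", "WC2", "WCC",
        "ccg2_mrna", "CCG2",
    ]
    rx = []
    for gene in ("frq", "wc1", "ccg2"):
        rx.append(Reaction({f"{gene}_gene_off": 1}, {f"{gene}_gene_on": 1},
                           p["k_gene_on"], name=f"{gene} locus on"))
        rx.append(Reaction({f"{gene}_gene_on": 1}, {f"{gene}_gene_off": 1},
                           p["k_gene_off"], name=f"{gene} locus off"))
    rx += [
        Reaction({"frq_gene_on": 1}, {"frq_gene_on": 1, "frq_mrna": 1}, p["k_tx_frq"],
                 kind=HILL_ACTIVATION, regulator="WCC", K=p["K_act"], n=p["n_act"],
                 name="frq transcription (WCC-activated)"),
        Reaction({"frq_mrna": 1}, {}, p["d_mrna_frq"], name="frq mRNA decay"),
        Reaction({"frq_mrna": 1}, {"frq_mrna": 1, "FRQ": 1}, p["k_tl_frq"],
                 name="FRQ translation"),
        Reaction({"FRQ": 1}, {}, p["d_FRQ"], name="FRQ decay"),
        Reaction({"wc1_gene_on": 1}, {"wc1_gene_on": 1, "wc1_mrna": 1}, p["k_tx_wc1"],
                 kind=HILL_REPRESSION, regulator="FRQ", K=p["K_rep"], n=p["n_rep"],
                 name="wc-1 transcription (FRQ-repressed)"),
        Reaction({"wc1_mrna": 1}, {}, p["d_mrna_wc1"], name="wc-1 mRNA decay"),
        Reaction({"wc1_mrna": 1}, {"wc1_mrna": 1, "WC1": 1}, p["k_tl_wc1"],
                 name="WC-1 translation"),
        Reaction({"WC1": 1}, {}, p["d_WC1"], name="WC-1 decay"),
        Reaction({}, {"WC2": 1}, p["k_WC2"], name="WC-2 synthesis"),
        Reaction({"WC2": 1}, {}, p["d_WC2"], name="WC-2 decay"),
        Reaction({"WC1": 1, "WC2": 1}, {"WCC": 1}, p["k_WCC"], name="WCC formation"),
        Reaction({"WCC": 1}, {}, p["d_WCC"], name="WCC decay"),
        Reaction({"FRQ": 1, "WCC": 1}, {"FRQ": 1}, p["k_inact"],
                 name="FRQ-catalyzed WCC inactivation"),
        Reaction({"ccg2_gene_on": 1}, {"ccg2_gene_on": 1, "ccg2_mrna": 1}, p["k_tx_ccg2"],
                 kind=HILL_ACTIVATION, regulator="WCC", K=p["K_act"], n=p["n_act"],
                 name="ccg-2 transcription (WCC-activated)"),
        Reaction({"ccg2_mrna": 1}, {}, p["d_mrna_ccg2"], name="ccg-2 mRNA decay"),
        Reaction({"ccg2_mrna": 1}, {"ccg2_mrna": 1, "CCG2": 1}, p["k_tl_ccg2"],
                 name="CCG-2 translation"),
        Reaction({"CCG2": 1}, {}, p["d_CCG2"], name="CCG-2 decay"),
    ]
    init = {
        "frq_gene_on": 1, "wc1_gene_on": 1, "ccg2_gene_on": 1,
        "frq_mrna": int(p["init_frq_mrna"]), "FRQ": int(p["init_FRQ"]),
        "wc1_mrna": int(p["init_wc1_mrna"]), "WC1": int(p["init_WC1"]),
        "WC2": int(p["init_WC2"]), "WCC": int(p["init_WCC"]),
        "ccg2_mrna": int(p["init_ccg2_mrna"]), "CCG2": int(p["init_CCG2"]),
    }
    counts = np.array([init.get(s, 0) for s in species], dtype=np.int64)
    return ReactionNetwork(species=species, reactions=rx, initial_counts=counts)


def _propensities_py(x, react, kinds, rates, hill_K, hill_n, reg):
    nr = react.shape[0]
    a = np.empty(nr)
    for j in range(nr):
        aj = rates[j]
        for s in range(react.shape[1]):
            v = react[j, s]
            if v == 1:
                aj *= x[s]
            elif v == 2:
                aj *= x[s] * (x[s] - 1) / 2.0
            elif v > 2:
                for m in range(v):
                    aj *= (x[s] - m)
                for m in range(2, v + 1):
                    aj /= m
        if kinds[j] == 1:
            xn = float(x[reg[j]]) ** hill_n[j]
            aj *= xn / (hill_K[j] ** hill_n[j] + xn)
        elif kinds[j] == 2:
            xn = float(x[reg[j]]) ** hill_n[j]
            aj *= hill_K[j] ** hill_n[j] / (hill_K[j] ** hill_n[j] + xn)
        a[j] = aj
    return a


@njit(cache=True)
def _ssa_kernel(react, change, kinds, rates, hill_K, hill_n, reg, x0,
                n_frames, frame_dt, t_end, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    ns = x0.size
    nr = react.shape[0]
    out = np.zeros((ns, n_frames), dtype=np.int64)
    x = x0.copy()
    a = np.empty(nr)
    t = 0.0
    frame = 0
    status = 0
    while frame < n_frames:
        a0 = 0.0
        for j in range(nr):
            aj = rates[j]
            for s in range(ns):
                v = react[j, s]
                if v == 1:
                    aj *= x[s]
                elif v == 2:
                    aj *= x[s] * (x[s] - 1) * 0.5
                elif v > 2:
                    for m in range(v):
                        aj *= (x[s] - m)
                    for m in range(2, v + 1):
                        aj /= m
            if kinds[j] == 1:
                xn = float(x[reg[j]]) ** hill_n[j]
                aj *= xn / (hill_K[j] ** hill_n[j] + xn)
            elif kinds[j] == 2:
                xn = float(x[reg[j]]) ** hill_n[j]
                aj *= hill_K[j] ** hill_n[j] / (hill_K[j] ** hill_n[j] + xn)
            if aj < 0.0:
                status = 1  # negative propensity: invalid state
                return out, status
            a[j] = aj
            a0 += aj
        if a0 <= 0.0:
            # absorbing state: freeze remaining frames
            while frame < n_frames:
                out[:, frame] = x
                frame += 1
            break
        tau = -np.log(np.random.random()) / a0
        t_next = t + tau
        while frame < n_frames and frame * frame_dt < t_next:
            out[:, frame] = x
            frame += 1
        if t_next > t_end:
            break
        t = t_next
        u = np.random.random() * a0
        acc = 0.0
        r = nr - 1
        for j in range(nr):
            acc += a[j]
            if u < acc:
                r = j
                break
        for s in range(ns):
            x[s] += change[r, s]
    return out, status


def _derive_seed(master_seed: int, index: int) -> int:
    """Counter-based per-cell seed so ensembles are order-independent."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % np.int64(2**31 - 1)) + 1


def gillespie_run(
    net: ReactionNetwork,
    t_end: float,
    frame_dt: float = FRAME_DT_H,
    seed: int = 0,
) -> SSATrajectory:
    """Exact direct-method SSA sample of one cell.

    The state is recorded at each frame boundary as the last state before
    the frame time (right-continuous step convention); a zero total
    propensity freezes the state to ``t_end``.
    """
    if t_end <= 0 or frame_dt <= 0:
        raise ValueError("t_end and frame_dt must be positive")
    arrays = net.compiled()
    n_frames = int(round(t_end / frame_dt))
    counts, status = _ssa_kernel(
        *arrays, net.initial_counts.copy(), n_frames, float(frame_dt),
        float(t_end), int(seed) % (2**31 - 1)
    )
    if status != 0:
        raise RuntimeError(
            "negative propensity encountered during SSA; check rate laws"
        )
    times = np.arange(n_frames) * frame_dt
    return SSATrajectory(frame_times=times, counts=counts, species=list(net.species))


def gillespie_ensemble(
    net: ReactionNetwork,
    n_cells: int,
    t_end: float,
    frame_dt: float = FRAME_DT_H,
    seed: int = 0,
) -> list:
    """Independent SSA runs with per-cell seeds split off the master seed."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return [
        gillespie_run(net, t_end, frame_dt, seed=_derive_seed(seed, i))
        for i in range(n_cells)
    ]


def ensemble_species_matrix(trajs: list, name: str) -> np.ndarray:
    """Stack one species across an ensemble into a cells x frames matrix."""
    return np.vstack([tr.series(name) for tr in trajs])
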