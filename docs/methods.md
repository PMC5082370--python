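# Methods

This note records the models implemented in `dropclock`, the assumptions
behind them, the numerical choices that matter, and what the synthetic
data do and do not emulate.

## The stochastic clock network

The fitted single-cell clock model for *N. crassa* (its full species
list and rate constants) has never been republished in a reusable form,
so `dropclock` implements a *minimal stand-in with the same qualitative
architecture*, stated here explicitly so nobody mistakes it for a fitted
model:

* three gene loci (*frq*, *wc-1*, *ccg-2*) that toggle stochastically
  between transcriptionally active and inactive states (transcriptional
  bursting, mean occupancy 0.8, mean on-time ≈ 4 h);
* WCC → *frq* and WCC → *ccg-2* Hill activation (n = 2, K = 30 molecules);
* FRQ ⊣ *wc-1* Hill repression (n = 6, K = 80 molecules) — the Hill-type
  negative feedback appropriate to fungal clocks — plus a weak
  FRQ-catalyzed WCC inactivation channel;
* WC-1 translated from *wc-1* mRNA, WC-2 constitutive, WCC formed
  bimolecularly;
* CCG-2, translated from *ccg-2* mRNA, is the fluorescent observable.

14 species, 23 reactions. Simulation is the exact Gillespie direct method
(exponential waiting times from the total propensity, channel chosen
proportionally), with the state recorded at each 0.5-h frame boundary as
the last state before the frame time. Propensities use standard stochastic
mass action, multiplied by the Hill factor where applicable. The inner
loop is compiled with numba; 1,024 cells × 240 h complete in about a
minute on one CPU.

**Calibration.** Defaults (frozen in `src/dropclock/data/clock_params.yaml`,
never revisited) were set once by: (1) grid-searching the deterministic
mirror of the network (gene states replaced by mean occupancy) for a
robust limit cycle with realistic molecule numbers; (2) rescaling all rate
constants uniformly — which rescales time exactly — to put the
deterministic period at 21 h; (3) one further uniform rescale against the
stochastic observable itself, because demographic noise and slow gene
toggling lengthen the effective period relative to the ODE. The final
target is the frequency-grid point nearest 21 h on the default analysis
window: 240 h of 0.5-h frames lose 24 frames per edge to detrending,
leaving L = 432 frames (216 h), whose grid offers 21.6 h and 19.64 h as
the neighbors of 21 h; the calibration centers the spectral mass on the
21.6 h bin so the reported principal period is stable across seeds. Mean
ccg-2 mRNA ≈ 130 molecules/cell and CCG-2 ≈ 270, matching the low-copy
regime that motivates a stochastic treatment.

**Seeding.** A master seed spawns per-cell seeds through a counter-based
`SeedSequence` rule, so ensembles are reproducible and independent of
evaluation order.

## Quorum-sensing droplet model

Cells in a droplet are coupled through a shared, instantaneously mixed
external signal (mean-field assumption). Per cell j: the deterministic
clock mirror plus an intracellular signal S_j produced from CCG-2 at rate
k_S1·Ω (Ω = `signal_scale`, the unit/volume conversion folding molecule
counts into signal concentration; default 10⁻¹⁰), exchanged with the pool
at rate η, and degraded at D9. The pool obeys
dS^e/dt = η_ext·Σ_j(S_j − S^e) − D10·S^e, with the cell/droplet volume
ratio folded into η_ext. Feedback closes by S slowing WCC formation: the
formation rate is multiplied by max(0, 1 − C4·S_j) (the zero-clipping
implements the Heaviside guard), and S additionally drains WC-1 and WC-2
at rate C2·S_j. Rate constants η = 100, η_ext = 1.44, D9 = 26, D10 = 4,
C4 = 0.8, k_S1 = 5×10⁹ are taken as published; the algebraic placement of
the C2 term, the D9 decay target, a small D2 loss on CCG-2, and Ω are
*reconstructions* (the corresponding equations were never printed in
full), chosen so the
model couples through WCC repression and synchronizes within the 10-day
horizon (Ω = 10⁻¹⁰ gives late-time ICC → 1 for droplets of 2–4 cells while
leaving the single-cell oscillation intact; an order of magnitude more
suppresses the clock in larger droplets).

Integration uses LSODA at rtol 10⁻⁶, states clipped at zero inside the
right-hand side, and a hard failure if any output state is below −10⁻⁶.
Droplet initial conditions sample the uncoupled limit cycle at random
phases, emulating cells that have free-run in the dark before loading.

The Kuramoto control model replaces the biochemistry with phases
dφ_j/dt = ω_j + (K_c/a)·Σ_k sin(φ_k − φ_j) within each droplet (optional
white phase noise), integrated by Euler–Maruyama at 1/10 frame step;
pseudo-fluorescence is amplitude·sin φ. Defaults: ω centered on the 21.6 h
clock period with SD 0.02 rad/h, K_c = 0.2 rad/h, amplitude 40.

## Synthetic measurement chain

Raw fluorescence per cell:

    raw(t) = E(t) · B(t) · (gain·signal(t) + background) + ε(t)

* E(t): shared excitation fluctuation, lognormal with mean 1 and CV 0.05
  per frame (the magnitude is a free configuration value; the experiment
  does not print one), multiplying the Rhodamine-B reference identically —
  so reference division cancels it exactly;
* B(t) = exp(−bleach·t): photobleaching, default 6.8×10⁻⁴ /h so the trend
  loses ≈15 % over 240 h (a "slight" trend, kept ≤ 20 %);
* ε(t) ~ N(0, σ²(I)) with σ²(I) = c₀ + c₁I + c₂I² evaluated at the
  noise-free intensity — the empirical bead-calibrated quadratic error
  model. Bead tables run the same chain with constant signal and no
  bleaching.

Droplet occupancies are truncated-Poisson(λ) on {1..max_a}, the standard
encapsulation statistics for flow-focusing devices. All generators are
bit-reproducible under a fixed seed.

What the generator does **not** emulate: tracking errors and particle
loss, focus drift, cell death (80 % viability at day 10 in the real
assay), cross-talk between fluorescence channels, non-Gaussian detector
tails, or any genotype-specific biology. Tests that pass on these
synthetics therefore validate the *analysis chain*, not the instrument.

## Preprocessing

Normalization divides each cell by the shared Rhodamine-B series.
Detrending subtracts a centered moving average and drops edge frames where
the full window does not fit, keeping the operator's weights identical at
every retained frame (that uniformity is what makes the noise propagation
below exact). The 24-h window is implemented as 49 frames — the odd,
exactly symmetric choice — so the filter is zero-phase and its transfer
function is the real Dirichlet kernel sin(πwf)/(w·sin(πf)); an even 48-
frame "centered" window would carry a half-frame phase shift and no real
transfer function. Subtracting the MA attenuates a sinusoid of frequency f
by exactly 1 − sin(πwf)/(w·sin(πf)), which the tests verify to 10⁻⁹.

Quality control drops cells with missing frames (>5 %), any point beyond
10 median absolute deviations (tracking jumps), or zero variance.

## Spectral summaries

Unnormalized forward DFT; power |X_l|² on f_l = l/(L·Δt), l = 1..⌊L/2⌋;
DC excluded (input is detrended); normalized variant divides by the sum
over l. The period is reported as 1/f_l at the argmax; an alternative
"1/2πf_l" convention sometimes quoted for this analysis contradicts the
published frequency-period pairing (0.0471 h⁻¹ ↔ 21 h), which is
consistent only with 1/f. Ties break toward the lower frequency and are flagged. The
secondary peak is the second-highest local maximum above a 10⁻⁹ relative
floor (numerical leakage ripple is not a peak).

Phase is computed from the analytic signal of the *full* mean-subtracted
series (confining Hilbert edge effects to the ends), unwrapped by choosing
each increment's 2π multiple to minimize its magnitude, then differenced
over the analysis window (default frames 60–230, i.e. 85 h) and divided by
2π. Because the analytic construction keeps only positive frequencies,
this phase is a cycle *count*; a time-reversed oscillation accumulates the
same count, not its negative. The originally reported mean phase
(17 cycles/85 h) is not self-consistent with a 21 h period over 85 h
(≈ 4 cycles); the implementation keeps the self-consistent pure-tone
definition, under which a 21 h tone over 85 h yields 4.05 cycles.

## Variance partition

Let Q be the detrending operator and r_l = (F·Q)_l the l-th row of the DFT
applied after Q. For white detector noise ε with variance σ², write
E_l = r_l·ε = A + iB with a = Re r_l, b = Im r_l. Gaussian moment algebra
gives, per unit σ²: E|E_l|² = ‖a‖² + ‖b‖², and

    Var|E_l|² = 2‖a‖⁴ + 2‖b‖⁴ + 4(a·b)²  =: β_Q(l)·σ⁴,
    signal cross term: 2(‖a‖² + ‖b‖²)·σ²·⟨|S_l|²⟩  =: γ_Q(l)·σ²·⟨|S_l|²⟩,

averaging the cross term over the cell population's random signal phases.
The population mean ⟨|S_l|²⟩ is replaced by the sample mean of the
observed bare periodogram minus its noise bias ‖r_l‖²σ² (first
approximation; the same subtraction is exposed as the periodogram bias
correction). These coefficients are computed from the actual MA weights by
direct matrix algebra, and the whole route is validated against a
brute-force Monte-Carlo oracle (simulate noise, detrend, periodogram, take
variances; 10⁴ replicates agree in the mean to well within 5 %).

σ_det² on the normalized scale is the bead-model variance at the observed
raw intensities divided by the squared reference, averaged over frames and
cells. The total per-frequency variance across cells comes directly or by
the 5000-replicate cell bootstrap (which estimates the variance of the
cell-averaged periodogram, s²_l/K for i.i.d. cells); the stochastic
component is the floored difference, with the number of floored
frequencies reported. Two summaries are exposed: the per-frequency maximum
detector fraction (the "< x % at all frequencies" style statement) and the
summed-over-frequency share, which is the statistically stable choice for
recovery studies because per-bin variance ratios at 256 cells carry ~20 %
sampling noise and their maximum is biased upward.

Harmonic ANOVA projects a series onto sine and cosine at each model
frequency (2 df per frequency, frequencies must lie on the observable
grid), scales all sums of squares so they total 1, and forms
F = EMS_freq/EMS_error. When assembled from published SS/df components the
same table arithmetic applies. For the data route the error df defaults to
n − 2m − 1; a perfect noise-free tone yields F = ∞, reported as such with
p = 0.

## Ensemble fitting

χ²(Θ) = Σ_l (P̄_obs − P̄_model(Θ))²/(σ_l,tot)², df = included frequencies
minus constraint count. The published account of the ensemble method does not pin down the
acceptance rule beyond periodogram similarity; the implementation adopts
Metropolis with acceptance min(1, exp(−Δχ²/2T)), T = 1 by default, and
log-scale Gaussian proposals on the masked parameters. Because P̄_model is
a Monte-Carlo estimate, proposals share common random numbers within
blocks (one simulation seed per `crn_refresh` = 50 steps, with the current
state re-scored at each block boundary); this is a pragmatic deviation
from exact pseudo-marginal MCMC, adequate at desk scale and validated two
ways: the chain reproduces the exact Gaussian stationary law on a
closed-form quadratic target (KS on a thinned chain), and a 2-parameter
recovery study (data generated at 128 cells × 120 h from known Θ*, chain
at 32 cells, 200 steps) returns posterior medians within 25 % of truth.
Desk scales replace the original GPU scales (1,024 cells per proposal,
>165,000 proposals) throughout; they are the package's default study
sizes, not a claim of equivalence.

The phase distribution — functionally independent of the periodogram used
in fitting — provides the independent validation channel: mean-subtracted
two-sample KS between data and model phases.

## Synchronization measures

The ICC uses the balanced one-way variance-components estimator per
single time point and exact droplet-size stratum (the estimator is
balanced-only, and the surfaces index by exact occupancy): SS_B with n−1
df, SS_W with n(a−1) df, ICC = (EMS_B − EMS_W)/(EMS_B + (a−1)EMS_W). Its
range is [−1/(a−1), 1]; negative values are reported as computed, since
the resampling null relies on values scattering around zero. Strata with
fewer than 2 droplets are left missing. The strangers control resamples,
independently at every frame and with replacement, each multi-cell
droplet's values from the singleton pool at that frame, 20 replicates by
default. Surface-on-surface regression fits one common slope with one
intercept per droplet size by OLS, all defined (a, t) cells weighted
equally. The Garcia-Ojalvo ratio and the per-stratum time-averaged
Kuramoto order parameter follow their standard definitions.

## Known limitations

* The clock network topology and rates are a calibrated stand-in, not the
  fitted published ensemble; conclusions about *which* parameters set the
  period transfer only qualitatively.
* The quorum model's C2/C4 coupling algebra and signal scaling are
  reconstructions (flagged above).
* The detector propagation treats noise as Gaussian and white across
  frames and replaces population by sample means; both approximations are
  tested only within the Monte-Carlo oracle's regime.
* The Hilbert phase is a positive cycle count; signals without a dominant
  oscillation give phases dominated by edge and unwrapping noise.
* The balanced-only ICC discards no data here because strata are exact
  sizes, but it cannot pool across sizes; sparse large-droplet strata stay
  undefined rather than smoothed.
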