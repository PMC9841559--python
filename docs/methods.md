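# Methods

## Model

The transferring proton is treated as a single effective particle of mass
μ (default 1.00783 amu; 2.01410 amu for deuterium) moving on a
one-dimensional potential V(q) obtained by interpolating a discrete
reaction path.  Coupling to the cellular environment is modelled as an
ohmic bath of harmonic oscillators in the high-temperature
(Caldeira–Leggett) limit, which closes the dynamics of the Wigner
quasi-probability density W(q, p):

    ∂W/∂t = −(p/μ) ∂q W + Σ_{n odd} (1/n!) (iħ/2)^{n−1} ∂q^n V ∂p^n W
            + γ ∂p(p W) + γ μ k_B T̃ ∂p² W .

The first line is the quantum Liouville (Moyal) flow — truncated at n = 1
it is the classical Klein–Kramers equation; the second line is ohmic
friction γ and momentum diffusion at the effective bath temperature T̃.
The master equation is Markovian and its diffusion coefficient is the
classical (high-T) one, so the stationary state in a harmonic well is the
classical Maxwellian regardless of ħ; all quantum effects on the rate
enter through the dynamics near the barrier.  This is the appropriate
regime for a proton strongly coupled to the aqueous/enzymatic
environment; it deliberately excludes low-temperature quantum-bath
corrections (non-Lindblad positivity issues are mitigated in practice by
the bath's smoothing and the weak spectral filter described below).

Everything is computed in an eV / Å / fs / amu unit system in which
ħ = 0.6582119569 eV·fs and k_B = 8.617333262×10⁻⁵ eV/K.  A coupling
quoted as a wavenumber is converted as an angular frequency,
γ[fs⁻¹] = 2πc·γ[cm⁻¹] (so the water-band value 3900 cm⁻¹ ↦ 0.735 fs⁻¹);
the convention is stated here because γ is a phenomenological matching of
vibrational frequencies and an alternative linear-frequency convention
would differ by 2π.

## Potentials

Reaction paths are tables of (s [Å], E [eV]) images; energies are
re-zeroed at the first image.  A natural cubic spline provides the C²
interpolant; its piecewise-constant third derivative feeds the Moyal
term, accepting discontinuities at the knots (with ≥100 images the effect
is far below other discretization errors, and the natural end conditions
only perturb ∂³V near the path ends where no barrier physics lives).
Stationary points come from prominence-filtered extrema on a dense grid
refined by bounded minimization; the global transition state is the
highest interior maximum between the terminal minima, ties within 1 neV
broken toward the path midpoint.  Region segmentation thresholds the
smoothed |dE/ds| (default 0.05 eV/Å, 0.25 Å window) and labels the
contiguous steep run containing the transition state as proton transfer;
gaps narrower than the window (e.g. the zero-gradient barrier top) are
closed morphologically.

For dynamics the potential is extended beyond the path domain by a
quadratic continuation matched to value/slope/curvature at each end.  The
reactant side is confined by a quadratic wall rising to `wall_height`
(default 1.2 eV) across the grid padding (default 1.0 Å).  The wall is
deliberately soft so the thermal turning region spans several grid cells:
a near-hard wall is unresolvable on the grid and sheds spurious
grid-scale structure into the well.

## Propagator

The solver is an operator-split spectral scheme in which each sub-step is
applied through its exact flow:

* **streaming** −(p/μ)∂qW: an exact translation per momentum row,
  implemented as a phase in the q-Fourier domain;
* **potential term**: a phase Φ(q, y) in the Fourier conjugate y of
  momentum.  Order 1 uses Φ = y·V′(q) (classical), order 3 adds
  (ħ²/24)·y³·V′′′(q) (leading quantum correction), and the
  `spectral-kernel` scheme applies the full nonlocal Wigner kernel
  Φ = [V(q + ħy/2) − V(q − ħy/2)]/ħ, which is exact to all Moyal orders
  on the grid; the truncated and kernel schemes agree to <0.1% on the
  validation barriers, so the cheaper truncated form is the default;
* **friction + diffusion**: the exact Ornstein–Uhlenbeck Green's
  function — a mass-conserving contraction p → p·e^{γΔt} (cubic Lagrange
  interpolation, column-normalized) followed by a Gaussian convolution of
  variance μk_BT̃(1 − e^{−2γΔt}).

A symmetric composition (half potential / OU / half potential inside half
streaming steps) gives second-order accuracy in Δt; because the classical
and quantum propagators share every operator except the potential phase,
they agree to machine precision on harmonic potentials, where the Moyal
corrections vanish identically.

Collisionless phase-space flow generates ever finer filaments (barrier
shear, wall turning points).  Once filaments reach the grid scale a
spectral translation rings globally and the local continuity of the flux
breaks — mass appears to cross the barrier without passing the dividing
surface.  A weak exponential filter, exp(−36(k/k_max)^16) on both axes,
removes only the top third of the spectrum, conserves mass exactly
(unity at k = 0), and restores flux continuity to <1% while leaving the
resolved physics untouched; κ changes by <2% under simultaneous halving
of dq, dp and dt, which bounds the filter's bias at the default
resolution.

Boundaries: the product side is absorbed by a gentle sponge
(smooth-onset exponential damping, peak rate 1 fs⁻¹ over 24 cells); the
reactant side reflects via the confining wall, with a small sponge hidden
in the outer part of the wall (where V ≥ 75% of the wall height, i.e.
physical density ~e^{−βV} ≈ 0) to remove numerical debris before it can
wrap around the periodic grid.  `boundary="reflecting"` disables all
sponges and walls both ends; in that closed configuration the norm is
conserved to machine precision (<10⁻¹⁵ over 10³ steps).

Guard rails: the per-step streaming shift and momentum kick must stay
below a quarter of the respective grid span and γΔt ≤ 0.5, otherwise a
stability error is raised before the run; NaN during propagation raises a
divergence error naming the step.

## Thermal states and rates

The initial state is the Boltzmann mixture of the lowest eigenstates of
the well-restricted 1-D Hamiltonian (finite differences on 1024 points,
tridiagonal eigensolver, states added until the spectrum spans 25 k_BT),
Wigner-transformed onto the simulation grid by quadrature of
ρ(q+y, q−y)·cos(2py/ħ).  For rate runs the diagonalization uses the
propagator's own extended potential and a window reaching into the
confining wall, so the eigenfunctions decay naturally instead of kinking
at an artificial hard edge — without this the released kink contaminates
the population decay at the few-percent level.  A `gaussian` method
(harmonic approximation with the quantum-corrected effective temperature
T_eff = (ħω/2k_B)·coth(ħω/2k_BT), or plain T in classical mode) is
available for harmonic wells.

The rate protocol prepares the thermal state on the reactant side,
propagates, and monitors k(t) = J(s_TS, t)/N_reactant(t), with
J = ∫(p/μ)W(s_TS, p)dp the net flux through the transition state and N
the population left of it.  The rate is the mean of k over the first
window of 500 fs in which its relative slope stays below 10⁻³ per 100 fs;
no plateau within `max_time` raises a non-convergence error carrying the
partial series, and a plateau below 10⁻²⁵ fs⁻¹ raises an underflow error
recommending the analytic estimate.  An exponential fit to N(t) over the
same window provides an independent rate; the two agree to well under 10%
on the validation fixtures.  κ is the ratio of quantum to classical
plateau rates computed on identical grids from the identical initial
state (quantum preparation for both — the bath rethermalizes each mode
within ~1/γ, so the ratio isolates the barrier dynamics).  The KIE is
reported on two bases: `eyring` (κ-corrected Eyring rates, which reduces
to κ_H/κ_D because the Eyring prefactor and electronic barrier are
mass-independent) and `raw` (ratio of raw dynamical quantum rates).

Closed-form oracles used in validation: the Kramers/TST rate
k = F·√(1/2πβμ)·e^{−βE‡}/∫_well e^{−βV}dq with the spatial-diffusion
factor F = √(1+(γ/2ω_b)²) − γ/2ω_b, and the high-temperature tunnelling
correction κ_W = 1 + (βħω‡)²/24.  The latter is a weak-coupling
(γ → 0) transition-state result, so the solver is checked against it at
γ = 100 cm⁻¹; at the water-band coupling the same fixtures give κ ≈ 1.0 —
decoherence-suppressed tunnelling, which is the physically expected
behaviour at strong coupling, not a solver artifact.

## Rate combination

Eyring rates use the standard prefactor 1/(βh); the same κ multiplies the
forward and reverse directions, so detailed balance
k_f/k_r = e^{−β(G_f−G_r)} holds to machine precision.  Electronic
barriers are converted to Gibbs barriers by fractional reductions
(defaults exposed as parameters; the reference correction is −20%
forward, −30% reverse, from a normal-mode free-energy analysis consumed
as data).  One caveat: because of the T-linear prefactor, the raw van 't
Hoff slope of ln k vs 1/T is −G/k_B − T, not −G/k_B; the barrier is
recovered exactly from the prefactor-free ratio ln(kh/k_BT).  The
competition with nucleotide unbinding is the two-branch fraction
k_pt/(k_pt + k_unbind).

## TRS occupancy analysis

Δ is the RMS Cartesian deviation of the selected atoms from the
tunnelling-ready reference; by default no rigid-body superposition is
applied ("RMS distance" in the insertion-site frame), with an optional
Kabsch alignment (`align=True`).  Thresholds: Δ < 0.096 Å ⇒ TRS,
Δ > 2.0 Å ⇒ unbound, both strict so boundary frames fall in the middle
(bound) class.  The 0.096 Å default can be re-derived from a path's own
image spacing (`trs_cut_from_path`: Δ between consecutive images
bracketing the barrier start).  The mean waiting time between
compressions assumes uniformly distributed events:
frame interval / TRS fraction, flagged undefined when no TRS frame is
observed.  The cumulative likelihood is the empirical CDF P(Δ ≤ x).
Atom selection is a user-supplied 0-based index list; with no statement
of the reference selection available, the default is all atoms of the
provided reference.

## Synthetic data

The fixture generator composes smoothstep flats, an optional pre-barrier
rise (default 0.275 eV — the compression penalty into the
tunnelling-ready geometry), and sech² (Eckart-type) barrier cores, then
calibrates the main amplitude by root finding so the forward barrier
matches the request; the residual error of the composed profile is
<10⁻³ eV, dominated by the far tails of the sech² core.  Default
parameters reproduce the three reference topologies: the full wobble path
(0.926/0.680 eV, regions 0–4/4–7.5/7.5–9.5 Å), a bare inner barrier, and
the compact double-transfer profile (0.356 eV, ΔE = 0.017 eV, with a
post-transition-state shoulder realized as a shallow intermediate
minimum).  What the fixtures do *not* emulate: DFT-level path curvature,
corner-cutting in multiple dimensions, or real polymerase geometry — so
passing tests demonstrate the correctness of the machinery on paths of
the right shape and scale, not agreement with any specific
electronic-structure surface.

Synthetic trajectories are Markov chains over three template geometries
(bound/TRS/unbound; the TRS template is the reference, the bound template
0.5 Å RMS away, the unbound one translated 3 Å) with isotropic Gaussian
coordinate noise (default σ = 0.02 Å, small against the 0.096 Å
threshold).  The transition matrix ρI + (1−ρ)·1πᵀ has stationary
distribution π exactly for any persistence ρ, so occupancy recovery can
be tested against closed-form ground truth; statistical acceptance tests
use ρ = 0 (independent frames) so the binomial confidence interval is the
correct reference distribution.  All randomness flows from a single
`numpy` `default_rng` seed; identical seeds give bitwise-identical
trajectories.

## Problem sizes and defaults

Default grids are 256×256 (q×p) with momentum extent 6√(μk_BT) and
Δt = 0.25 fs; solver validation and the fixture grid for monotonicity
checks run at 128×128 with Δt = 0.5 fs, where κ is converged to ~2%.
Validation barriers are 0.12–0.25 eV at 550–800 K so that βE‡ ≈ 3–5 and
plateaus form within a few picoseconds — the same machinery applied to
the 0.926 eV barrier at 298 K (βE‡ ≈ 36) correctly reports that the
classical flux is unmeasurable in double precision and defers to the
analytic estimate.  The synthetic-trajectory studies use 10⁵ frames at
1 ps spacing.

## Known limitations

* One reaction coordinate: no proton–proton coupling in the double
  transfer, no corner-cutting.
* High-temperature ohmic bath only: no coloured baths, no exact
  (non-Markovian) quantum diffusion coefficients, so deep-tunnelling
  rates at low T̃ are outside the validated regime.
* The order-3 Moyal truncation degrades for βħω‡ ≳ 2–3; the
  spectral-kernel scheme extends the range but shares the classical
  diffusion kernel.
* Waiting-time statistics assume uniform events; correlated compression
  bursts would need a dwell-time analysis on the labelled series.
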