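# Methods

This note documents the models implemented in `talin_clutch`, the
numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.  All internal units
are pN, nm and s; thermal energy is kT = 4.1419 pN nm at 300 K.

## The mechanochemical clutch model

A single Talin molecule links a stationary integrin to the actin
network flowing rearward at speed v (10–50 nm/s in lamellipodia).  The
molecule is a chain of N rod subdomains plus two end linkers (the
integrin and actin bonds), each a spring segment:

* **Folded subdomains and end linkers** are Hookean,
  F = k_f (l − l_f0) for l > l_f0, with k_f = 10⁴ pN/µm and
  l_f0 = 2 nm.  Forces are tensile only; a segment below its rest
  length is slack.  The loading protocol only lengthens the chain, so
  compression never matters after the first few steps.
* **Unfolded subdomains** are freely jointed chains,
  F = (kT/b) L⁻¹(l / (b n)), with Kuhn length b = 0.38 nm (one amino
  acid) and n = 145 residues per subdomain, giving a contour length of
  55.1 nm per unfolded subdomain.  L⁻¹ is the inverse Langevin
  function, evaluated by Newton iteration from the Cohen Padé seed
  x(3 − x²)/(1 − x²) to a relative tolerance below 1e-8.

The chain starts straight at an angle θ to the substrate with every
segment at rest length, so the anchor separation grows as
L(t) = √(L0² + 2 L0 v t cosθ + v²t²), L0 = (N+2) l_f0.  Geometry is
planar.

**Force balance.**  In the master-equation method, tension is assumed
uniform along the chain at each instant (bead relaxation is far faster
than loading; the stochastic simulations confirm tension equilibrates
along the chain to < 1% in ~10⁻⁵ s).  Given i unfolded subdomains and
the current L(t), the tension solves the monotone scalar equation
i·l_u(τ) + (N+2−i)·l_f(τ) = L(t); the solver is a warm-started Newton
iteration with a bisection fallback, with length conservation enforced
to 1e-6 nm (1e-9 relative in the Python path).

**Kinetics.**  A folded subdomain unfolds, and the integrin bond
breaks, at Bell-law rates k(F) = k₀ exp(F Δx / kT).  Unbinding uses
the measured k₀ = 0.17 s⁻¹ and Δx = 0.51 nm.  Unfolding parameters for
Talin rod subdomains are configurable per subdomain; the shipped
defaults (k₀ = 1e-4 s⁻¹, Δx = 4 nm) are an illustrative set in the
range reported by single-molecule pulling studies, not fitted values —
all trend results below were produced with them.  Refolding is not
modelled.  Exponents are capped at 700 to avoid overflow; a capped
rate is certain on any simulated step.

An alternative **catch–slip** integrin bond is provided: rapid
equilibrium between a fast- (1) and a slow-dissociating (2) bound
state, overall rate (k₂₁k₁₀ + k₁₂k₂₀)/(k₁₂ + k₂₁) with each
k_ij = k_ij0 exp(F x_ij/kT).  The printed expression for the combined
rate is typographically garbled; the denominator k₁₂ + k₂₁ is the
unique reading whose zero-force value reproduces the measured
0.17 s⁻¹ (0.194/1.142).  Only the ratio k₁₂0/k₂₁0 = 0.142 is
determined at rapid equilibrium, so k₂₁0 is fixed at 1 s⁻¹ by
convention.

## Master equation

With identical subdomains the chain state is the number j = 0..M of
unfolded subdomains plus "unbound".  The discrete-time update over Δt
first redistributes bound probability over additional unfolds with the
binomial kernel A_ij = C(M−i, j−i)(1−p_i)^{M−j} p_i^{j−i},
p_i = 1 − exp(−k_unfold(F_i)Δt), then removes unbinding mass
p_unbind,j·P_j evaluated on the pre-update state (the printed exponent
j−1 in the binomial kernel is read as j−i, the unique reading that
makes each row a probability distribution).  Tension is evaluated at
the step's start (explicit scheme).  Default Δt = 1e-3 s; halving Δt
changes the mean clutch duration by < 0.5%, and the oracle comparison
below uses Δt = 2e-5 s.  Runs terminate when P_unbound exceeds 0.999
(configurable; the lifetime test uses 1−1e-6 so truncation bias stays
below 0.1%).  Probability conservation holds to 1e-9 per step by
construction and is asserted against the accumulated unbinding mass.

With per-subdomain parameters every subset σ of unfolded subdomains is
a state (2^M of them, M ≤ 20 enforced, M ≲ 12 practical); the update
applies each subdomain's unfolding probability independently with
rates evaluated at the source state, which reduces exactly to the
binomial kernel when parameters are identical (verified to 1e-8).

**Observables.**  dP_unbound/dt is the unbinding-time density;
x = v t maps it to the unbinding-displacement density; the
maximum-force histogram bins the per-step unbinding mass at the
state's tension (0.5 pN bins by default).  The ensemble work on actin
accumulates Σ_j F_j(t)·cosφ(t)·v·Δt·P_j(t), where cosφ(t) =
(L0 cosθ + v t)/L(t) projects the (straight-chain) tension onto the
flow axis.  Mean clutch duration is the density-weighted mean
unbinding time normalised by the terminal unbound probability.

**Calibration.**  `calibrate_dx_unbind` scans a grid of unbinding
barrier distances, solves the master equation at each, and minimises
the chi-square distance between the normalised model and target
displacement histograms on the target's bins; ties are reported.

## Stochastic pulling simulations

The same model is realised explicitly: N+3 beads (integrin anchor,
N+1 chain beads, actin bead) move by overdamped forward-Euler steps
ζ dr/dt = F with the anchor fixed and the actin bead driven at v in
+x.  Thermal noise on positions is implicit in the Bell rates and FJC
elasticity, as in the deterministic path.  Unfolding/unbinding events
fire when each channel's accumulated hazard ∫k(τ_local)dt crosses a
pre-drawn unit-exponential threshold — exact for time-varying rates —
with k evaluated from the local segment tension after each position
update.  A trace ends at unbinding (or is censored at t_max, default
600 s); work integrates the actin-side tension component along the
drive.  The event log stores each unfold's time, segment and tension.

ζ is not a measured quantity; the reference pairing ζ = 1e-4 pN s/nm,
Δt = 1e-6 s puts the bead relaxation time ζ/k_f = 1e-5 s an order of
magnitude above the step (stability: Δt·k_max/ζ < 0.5, enforced) and
four orders below the kinetics.  Because observables in this
quasi-static regime are independent of ζ, ensemble tests use the
cheaper pairing ζ = 1e-3, Δt = 1e-5 s (same separation of scales,
10× fewer steps); a dedicated test verifies the two pairings agree
within statistical error.  A bead moving > 1 nm in one step aborts the
trace as a reported instability.

**Compliance variant.**  Two extra beads model soft integrin/actin
layers: a substrate bead behind the anchor and a network bead beyond
the actin bead, each joined by a Hookean spring of constant k₃ (rest
length l_f0); only the substrate bead is then fixed and the network
bead carries the drive.  With k₃ = 10⁵ pN/µm observables match the
rigid-anchor model within error; at k₃ = 10² pN/µm the dependence of
work on the number of unfoldable subdomains flattens out, because the
soft springs absorb the loading before subdomains can unfold.

**Cross-validation.**  For N = 12, M = 12, θ = 45°, v = 20 nm/s, a
1000-trace ensemble agrees with the master equation in mean unbinding
time (within 3 SE) and in the full unbinding-time/displacement
distribution (Kolmogorov–Smirnov distance < 0.05).  The ensemble size
is scaled from the ~10⁴ used for production statistics to keep the
default test run on one CPU; at n = 1000 the KS bound is, if anything,
harder to meet.

## SiMS kinetic analysis

Speckle tracks are (t, x, y) series at a uniform frame interval with a
known flow axis and localization SD (18.6 nm for the imaging these
parameters come from).  Two modes: coarse (2-s intervals, 120-s
window, minimum lifetime 4 s) and fast (100-ms intervals, 10-s window,
minimum lifetime 2 s).

**Coarse classification.**  Each frame-to-frame interval gets a motion
state by thresholding its along-flow displacement at twice the
localization SD.  At 2-s intervals the per-interval flow signal
(≈60 nm at 30 nm/s) is comparable to the noise of a single frame pair
(SD ≈ 26 nm), so the displacement attributed to interval i is averaged
over the three intervals centred on i before thresholding; this
recovers near-perfect per-interval discrimination at the cost of
blurring mode boundaries by about one frame.  Run-length rules then
follow the classification's definitions: a sustained mode needs a run
spanning more than two sequential images (≥ 2 intervals); a switch
counts once the new mode persists two or more sequential images
(≥ 1 interval); a track with qualifying runs of both modes is
switching, with neither unclassified.

**Flow-onset detection (fast mode).**  The along-flow mean of all
frames before the candidate point (at least 8) is the origin and
provides the reference SD; flowing motion is detected at the first of
three consecutive frames whose distance from the origin exceeds twice
that SD, and Δx is the value at the detection time of a line fitted to
the flowing segment, minus the origin.  The classical criterion uses
one SD; measured on synthetic ensembles it false-triggers on ~20% of
purely stationary tracks, whereas the 2-SD default holds false
triggers near 1% and reproduces both the observed modal Δx bin
(40–60 nm) and the observed mean (≈44 nm at 30 nm/s).  Fast-mode
classification (switching, back-and-forth) is built on this detector:
a detected onset preceded by a long stationary segment is switching; a
flowing excursion of more than 8 frames that returns to within one SD
of the origin for ≥ 3 frames is back-and-forth.

**Survival rates.**  Each transition rate is estimated from segment
durations by Kaplan–Meier survival analysis (lifelines) with the
competing transition right-censored, plus censoring at the window end.
The rate is the weighted-least-squares slope of −log S(t) with a free
amplitude (segments below the minimum lifetime are excluded upstream,
so the curve need not start at 1); weights are the numbers at risk.
The closed-form censored MLE (events / time at risk) is reported
alongside as a cross-check and supplies the confidence interval.
Photobleaching (0.0071 per frame at 2-s intervals, i.e. 0.00355 s⁻¹)
is subtracted from fitted disappearance rates; the fast-mode bleaching
rate under full illumination is not separately characterised, so the
correction is off by default there.

**Flux balance.**  At steady state the stationary/clutch/flowing
proportions satisfy three balance equations (linearly dependent — they
sum to zero) plus the net-flux closure X = k₂S − k₄F.  Given S and the
six rates the linear system yields C, F and X; residuals of all three
balance equations are verified below 1e-9.  With the measured rates
and S = 57% this gives C = 4.15% and F = 39.7%.  (The rounded printed
constants are slightly over-determined: fixing k_d instead of F gives
F ≈ 39.7% rather than the printed 38.3%; the solver reports the
k_d-given solution and makes no attempt to reverse-engineer the
original rounding.)

**Force bookkeeping.**  Concentration × cytosol volume × Avogadro
gives molecules per cell; the speckle and clutch fractions, the
per-filament force, the filament count and the lamellipodium region
fraction then propagate (as low/high ranges) to the force per speckle
and per clutch-engaged molecule.

## Synthetic data

Tracks are generated from the continuous-time chain
stationary ⇄ clutch ⇄ flowing with exits to an invisible diffusing
state (rates: k_a = 0.0548, k_b = 0.374, k_c = 0.680, k_d = 0.0315,
exits k₁ = 0.170 from stationary and k₃ = 0.104 from flowing, all
s⁻¹), observed through frame sampling, isotropic Gaussian localization
noise (SD 18.6 nm), per-frame Bernoulli photobleaching (0.0071,
state-independent) and window truncation.  New speckles appear
stationary or flowing with a split (0.815/0.185) derived from the
steady-state flux balance of the rates themselves, so the ensemble's
occupancy reproduces the model's state proportions (57/4.1/39.7) — a
property checked against the matrix-analytic occupancy oracle
a(−T)⁻¹.

Tag geometry: the actin-end (C-terminal) tag moves with actin during
clutch and flowing phases and snaps back (within one frame) when a
clutch releases toward stationary; the integrin-end (N-terminal) tag
holds still through stationary and clutch phases and jumps forward by
the accumulated stretch, v × clutch duration, when the clutch releases
toward flowing.  Clutch-phase kinematics are a kinematic surrogate
(linear advance at v), not the full chain mechanics; diffusing
molecules are not speckles, and a re-binding molecule would start a
fresh track.

**What recovery tests do and do not show.**  The published coarse-mode
and clutch rate sets are not mutually consistent (e.g. the effective
flowing→stationary rate implied by the clutch chain is
k_d·k_b/(k_b+k_c) = 0.0112 s⁻¹ against the printed 0.00694 s⁻¹, and
the clutch sojourn of the chain is 1/(k_b+k_c) = 0.95 s against the
printed mean duration 1.47 s).  Closed-loop tests therefore compare
recovered rates against the generator's own effective coarse rates,
derived in closed form by semi-Markov absorption algebra with clutch
visits merged into the surrounding mode (validated against a
rule-level Monte Carlo oracle).  Sub-resolution state visits are a
real limitation: any thresholded detector at 2-s sampling misses
visits shorter than ~2–4 s, so noise-free recovery of the switch rates
k₂/k₄ is biased low by 25–40% while the dissociation rates k₁/k₃
recover sharply; with realistic noise, false and missed switch events
largely cancel and all four rates recover within 15% at 1000 tracks.
The Δx ensemble draws clutch durations from Exp(k_c) (mean 1.47 s), as
the published duration estimate assumes.  Passing these tests shows
the pipeline is unbiased for data generated by this kinetic model with
Gaussian noise; real tracks add drift, uneven illumination, tracking
errors and spot-merging that are not emulated.

## Problem sizes and runtimes

Default test-suite sizes, chosen to keep the whole run on one CPU in
minutes: master-equation runs at Δt = 1e-3 s (≈0.2 s each), the
quadrature-oracle comparison at Δt = 2e-5 s, cross-validation with
1000 traces at (ζ, Δt) = (1e-3, 1e-5), compliance ensembles of 80–120
traces per condition, recovery at 1000 tracks, and the calibration on
a 9-point 0.05-nm grid.  Production-quality statistics (the ~10⁴
traces used for the distribution comparisons) scale linearly.

## Known limitations

* No refolding of unfolded subdomains, no Talin–actin dissociation,
  no rebinding after unbinding; worm-like-chain elasticity and bending
  stiffness are out of scope.
* Planar geometry in both solvers; no hydrodynamic interactions or
  explicit positional noise in the bead dynamics.
* The unfolding Bell parameters are illustrative defaults; per-figure
  values from single-molecule studies should be supplied via config
  for quantitative comparisons to specific constructs.
* The classification and onset rules contain genuinely interpretive
  thresholds (motion threshold, onset threshold factor); both are
  exposed in configuration and their defaults are justified above.
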