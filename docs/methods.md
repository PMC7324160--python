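# Methods

`isnkit` models and analyzes the signature of inhibition-stabilized
cortical circuits: the *paradoxical* steady-state suppression of inhibitory
neurons when they are directly depolarized (e.g. optogenetically). This
note records the models, the estimation procedures, the synthetic-data
assumptions, and the numerical and design choices, in enough detail that a
user can judge what a passing test suite does and does not establish.

## The two-population rate model

The core forward model is a Wilson–Cowan-style pair of equations for the
mean firing rates of an excitatory (E) and an inhibitory (I) population:

    tau_E dr_E/dt = -r_E + phi_E(W_EE r_E - W_EI r_I + I_EX)
    tau_I dr_I/dt = -r_I + phi_I(W_IE r_E - W_II r_I + I_IX + lambda L)

* `W_AB >= 0` — magnitude of the coupling from population B onto A; signs
  are fixed by the equations (E excitatory, I inhibitory).
* `I_EX, I_IX` — external (thalamic/corticocortical) inputs,
  spk/s-equivalent.
* `lambda` — opsin efficacy, spk/s per unit of normalized light intensity
  `L`; the drive enters the inhibitory population only (whole-population
  inhibitory stimulation).
* `phi_A` — a rectified-linear transfer function `a [x - x0]+` by default;
  a softplus `b log(1 + exp(a/b (x - x0)))` is available and converges to
  the rectified-linear case as `b -> 0`. Gains default to `a = 1` (see
  identifiability below).
* `tau_E, tau_I` — rate time constants in ms, relevant only for dynamics.

The network is an **ISN** when the excitatory subnetwork alone is unstable
(`a_E W_EE > 1`) but feedback inhibition stabilizes the full circuit. On
the interior fixed-point branch (both populations above threshold) the
steady-state slope of the inhibitory dose-response is

    d r_I / dL = -(W_EE - 1) lambda / D,
    D = W_EI W_IE - (W_II + 1)(W_EE - 1),

so, in the saddle-free regime `D > 0`, paradoxical suppression is
*equivalent* to ISN operation. Once the excitatory population is silenced
(boundary branch, reached at the intensity `L*` where the interior `r_E`
crosses zero), the inhibitory slope flips to `+lambda/(W_II + 1)`; the
inhibitory minimum therefore coincides with excitatory silencing, and the
high-intensity slope is unaffected by excitatory blockade — two
parameter-free predictions the test suite checks.

Fixed points are computed in closed form (piecewise-linear algebra).
When both branches are simultaneously self-consistent the interior branch
is returned with a `BistableWarning`; single-valued response curves are
the intended regime and bistability is outside the fitted operating range.

### Pharmacological blockade

Blockers are modeled as multiplicative survival factors: excitatory
blockers scale every glutamatergic term — `W_EE, I_EX, W_IE, I_IX` — by
`eps_E in [0, 1]` (the external inputs are glutamatergic, so they are
scaled too); inhibitory blockers additionally scale `W_EI, W_II` by
`eps_I`. The opsin conductance is unaffected by synaptic blockers, so
`lambda` is never scaled. The three experimental phases are: intact,
E-blocked, and E+I-blocked.

### Stability

At an interior fixed point the dynamics are linear with Jacobian

    J = [[ (W_EE - 1)/tau_E,  -W_EI/tau_E ],
         [  W_IE/tau_I,       -(W_II + 1)/tau_I ]]

(unit gains). The eigenvalues are implemented in closed form and
cross-checked against a numeric eigendecomposition. For an ISN with
`D > 0`, stability is lost exactly once as `tau_I/tau_E` grows, at the
ratio `(W_II + 1)/(W_EE - 1)`; the boundary is located by bisection on the
maximal real part (tolerance 1e-8, bracket [1e-3, 1e3]), with the closed
form serving as an independent check. Note that the maximal real part is
*not* globally monotone in the ratio (the larger of two real eigenvalues
can decrease before the complex-pair real part rises); only the sign
transition is monotone, which is what the boundary search relies on. For
the fitted V1 parameters the eigenvalues are complex over an interval of
ratios below the boundary, so step responses show damped oscillations —
including a visible undershoot–rebound of `r_E` that rectification can
mask in noisy data.

### Identifiability and rescaling

The equilibrium equations determine the parameters only up to one
multiplicative constant per population:

    {W_EE - 1, W_EI, I_EX, x0_E}        -> gamma_E (...)
    {W_IE, W_II + 1, I_IX, x0_I, lambda} -> gamma_I (...)

leaves every fixed point unchanged. Consequently the gains can be pinned
at `a_E = a_I = 1`, and single-phase data identify only ratios. Blocker
scaling acts on `W_EE` (not `W_EE - 1`) and therefore does not commute
with this family: combining the three phases breaks the degeneracy and
identifies all 11 free equilibrium parameters (4 weights, 2 inputs, 2
thresholds, lambda, and one `(eps_E, eps_I)` pair per session; 13 before
pinning the gains; +2 time constants for dynamics).

## Parameter inference

`fit_global` minimizes the unweighted sum of squared differences between
observed and predicted population rates over all phases, sessions and
intensities simultaneously (SEM weighting is available behind a flag but
off by default). Each restart draws the nine equilibrium parameters i.i.d.
uniform on [0, 10] and each efficacy pair uniform on [0, 1], then runs a
bounded trust-region-reflective nonlinear least-squares solve
(`scipy.optimize.least_squares`, all parameters >= 0, efficacies in
[0, 1]); the minimum-error restart wins. A singular model (`|D| < 1e-9`
in any phase) contributes a large finite penalty per point instead of
raising, so the optimizer can traverse such regions. Results are
deterministic given the seed. The default is 1000 restarts; on noiseless
three-phase curves convergence to the global optimum occurs far earlier
(tens of restarts), and the full 10^4-restart protocol is available via
the `n_restarts` argument.

`eps_E` is shared between the E-blocked and E+I-blocked phases within a
session — one `(eps_E, eps_I)` pair per session.

**Bootstrap.** Uncertainty is estimated by resampling units with
replacement within each (session, population) stratum, rebuilding the
population curves, and rerunning the global fit per resample; summaries
are per-parameter median, histogram-peak mode, and percentile intervals.
The resampling unit (units, stratified) is a design choice — trials or
sessions would be defensible alternatives — and preserves the shape of
the dataset.

**Time constants.** With connectivity fixed from the equilibrium fit,
`fit_time_constants` fits `(tau_E, tau_I)` by least squares of the
simulated step response against E and I rate traces, starting from
(10, 10) ms with bounds [0.5, 1e4] ms. Flat traces are flagged
non-identifiable.

## Three-population model (inhibitory-subset stimulation)

When only a fraction `frac` of inhibitory cells expresses the opsin
(e.g. viral expression in PV cells), the inhibitory population splits into
stimulated (P) and non-stimulated (I) subpopulations. The three-population
parameter set is built from a fitted two-population model by splitting
each population's inhibitory input column `frac : (1 - frac)` between P
and I, with the I and P rows copying the source inhibitory row (drive
`W_IE`, input `I_IX`, threshold `x0_I`); the opsin drive enters P only.
This construction satisfies exact column conservation
(`W_XI + W_XP` = source inhibitory weight onto X) and reduces to the
source model at `frac = 1` ((E, P) subsystem identical, I decoupled from
the feedback loop). The published description of this construction is
ambiguous in the available text (several right-hand sides are rendered
with dimensionally inconsistent subscripts); the mapping implemented here
is the self-consistent reading validated by the `frac = 1` reduction.

Fixed points are found by integrating the three-population dynamics from
the resting state and solving the converged rectification pattern's
linear system exactly (patterns ordered by decreasing number of active
populations as a deterministic tie-break); divergence yields an
"unstable" verdict. In the all-active regime the equilibrium response of
the stimulated population has the closed form

    r_P(L) - r_P(0) = [(1 - W_EE)(W_II + 1) + W_EI W_IE] lambda L / N

with `N` the all-active normalizer; its sign decides paradoxical vs
non-paradoxical. In the presynaptic-identity-only simplification
(E weight `W`, I weight `kI W`, P weight `kP W`) the response factor is
`[1 + (kI - 1)W] / [1 + (kP + kI - 1)W]`, negative in the large-`W` limit
exactly when `kI < 1` and `kP > 1 - kI`: with multiple inhibitory
populations, ISN operation does **not** imply paradoxical suppression of
the stimulated subset. As `frac` decreases from 1 the initial slope of
the stimulated population's dose-response rises monotonically toward
non-paradoxical values.

## Unit-level analysis chain

* **E/I classification.** Three methods. (1) *Pharmacology*: under E+I
  blockade only opsin-expressing cells respond to light; a unit is I iff
  its rate change from baseline to maximum intensity is positive with
  Welch's unequal-variance t-test p < 0.01. The test is two-sided with
  the sign requirement applied separately (the effective one-sided level
  is therefore ~alpha/2). (2) *High power*: the same rule on the intact
  phase — inhibitory cells driven past the silencing point rise above
  baseline; units that stay suppressed at every measured intensity are
  missed (documented stringency). (3) *Waveform width*: Gaussian KDE of
  the width distribution (default bandwidth factor 0.25), dominant modes
  located with a 2%-of-max prominence filter, threshold at the density
  minimum between the two dominant modes, narrow units labeled I
  (fast-spiking). Genuinely overlapping mixtures can be effectively
  unimodal, in which case the method refuses with a diagnostic rather
  than inventing a threshold.
* **L0 normalization.** Per session, a continuous two-segment
  piecewise-linear function with a free breakpoint is least-squares fit
  to the average inhibitory dose-response (breakpoint on a 200-point grid
  over the interior of the intensity range, then bounded scalar
  refinement). The breakpoint L0 — the inhibitory minimum — maps to 1 on
  the normalized intensity scale, absorbing day-to-day variation in
  tissue optics; a non-negative first-segment slope flags "no paradox"
  and leaves L0 undefined. Normalized slopes are thereby invariant to the
  raw laser units.
* **Initial slopes.** OLS slope of mean rate vs normalized intensity over
  [0, 1] (all points at or below L0; at least two required). The exact
  definition of "initial slope" (two-point difference vs regression) is
  not fixed by the source description; OLS over the sub-minimum range
  uses all pre-minimum points and is robust to grid density. The
  normalized slope divides by (baseline + 0.1 spk/s), bounding it below
  by about -1 and taming low-baseline units.
* **Population averages.** Mean over units of per-unit mean rates; the
  SEM is computed on the *summed* spike counts across units per trial
  (population-level counting noise), converted back to spk/s per unit.
* **Transient detection.** The ISN mechanism requires a brief inhibitory
  rate increase before paradoxical suppression. On a 1 ms PSTH the onset
  bin (stimulation artifact) is dropped; the 1–12 ms post-onset window is
  compared with the matched-duration 12 ms pre-onset window by two-sample
  KS test with a separate positive-mean requirement. Peak geometry
  (amplitude, latency, FWHM by linear interpolation, baseline-crossing
  time) is measured on a 3 ms boxcar-smoothed trace; normalized transient
  and steady-state values are (rate - baseline)/baseline.
* **Current decomposition.** At an interior fixed point the excitatory
  current into E cells is `(W_EE r_E + I_EX)/x0_E`, the inhibitory
  current `-W_EI r_I / x0_E` (threshold units), and their sum obeys
  `net = (r_E + x0_E)/x0_E` exactly — a loose-balance diagnostic.
* **Depth strata.** Superficial <= 400 um, deep >= 500 um; units between
  are excluded from both strata.

## Synthetic data generator

The generator emulates the experimental design the pipeline assumes so
that every stage is testable without recordings: three pharmacological
phases; a raw-mW laser grid presented as 600 ms pulses with 100
repetitions per level and steady-state counts over the last 300 ms; an
~80/20 E/I unit mixture; waveform widths from two Gaussians (means
0.58 ms for E, 0.46 ms for I, sd 0.05 ms); a per-session laser scale (the
true L0, defaults evenly spread over 0.8–1.6 mW so the normalized grid
spans the minimum); per-session blocker efficacies (default 0.3/0.3,
optional jitter); log-normal per-unit rate multipliers (sigma 0.5,
mean-one parameterization); and Poisson trial counts around
(rate x window), with optional gamma-mixture overdispersion. Trial noise
is Poisson *by assumption* — the source experiments report no noise
model. PSTH generation simulates the step response (including the brief
inhibitory transient) and draws Poisson bin counts, with an optional
onset-bin artifact to exercise the artifact-drop logic.

What passing round-trip tests show: the pipeline recovers the latent
structure the generator actually produces — homogeneous populations
scaled per unit, Poisson noise, exact model means. What they do not show:
robustness to cell-to-cell heterogeneity of connectivity, non-Poisson
variability, drift, spike-sorting contamination, or opsin kinetics, none
of which the generator emulates.

## Problem sizes and numerics

Default sizes keep every computation desk-scale: dynamics use explicit
Euler at dt = 0.1 ms (convergence verified by dt-halving; dt is capped at
min(tau)/10); the acceptance computation uses 1000 fit restarts on
10-intensity three-phase curves and a 0.5 ms trace grid for time-constant
fitting; unit-level tests use tens of units with 100 trials per level.
Fixed-point vs dynamics agreement is asserted at 1e-6 spk/s, closed-form
vs numeric eigenvalues at 1e-10. All randomness flows from explicit
seeds; generated datasets are byte-identical given the seed.

## Known limitations

* Short-term synaptic plasticity and spiking (conductance-based) network
  extensions are out of scope.
* The three-population stability analysis is numeric only (3x3
  eigensolve with user-supplied tau_P); no closed form is provided.
* The width classifier assumes an (at least locally) bimodal width
  distribution and refuses otherwise.
* Bootstrap resampling is by unit; trial-level resampling would capture
  within-unit counting noise instead of between-unit heterogeneity.
* The rescaling transformation is defined for the rectified-linear
  transfer function; for softplus it would hold only approximately and is
  rejected.
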