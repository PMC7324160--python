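# isnkit

Modeling and inference toolkit for **inhibition-stabilized networks
(ISNs)** probed with optogenetic stimulation of inhibitory neurons.

Cortical circuits can operate in a regime where the excitatory subnetwork
is unstable on its own (`W_EE > 1`) and is held in check by feedback
inhibition. The experimental signature of this regime is *paradoxical
suppression*: driving inhibitory cells directly (e.g. with an excitatory
opsin expressed in all GABAergic neurons) *decreases* their steady-state
firing, because the stabilizing excitatory drive they receive withdraws
faster than the direct input adds. `isnkit` is for systems neuroscientists
who want to simulate this circuit, analyze extracellular dose-response
recordings for its signatures, and infer the underlying connectivity.

The core model is a two-population rate network

    tau_E dr_E/dt = -r_E + phi_E(W_EE r_E - W_EI r_I + I_EX)
    tau_I dr_I/dt = -r_I + phi_I(W_IE r_E - W_II r_I + I_IX + lambda L)

with rectified-linear transfer functions `phi(x) = a [x - x0]+`, laser
intensity `L`, and opsin efficacy `lambda`. On the interior fixed-point
branch the inhibitory dose-response slope is
`-(W_EE - 1) lambda / D` with
`D = W_EI W_IE - (W_II + 1)(W_EE - 1)` — negative exactly when the
network is an ISN.

The package provides, as importable modules with a thin CLI on top:

* `isnkit.rate_model` — transfer functions, pharmacological blocker
  transforms, closed-form fixed points (interior/boundary branches),
  Euler dynamics, and the equilibrium rescaling invariance;
* `isnkit.stability` — closed-form Jacobian eigenvalues, ISN
  classification, and the maximal stable `tau_I/tau_E` ratio by bisection;
* `isnkit.inference` — multi-restart bounded least-squares inference of
  all 11 free equilibrium parameters from three-phase (intact /
  E-blocked / E+I-blocked) dose-response curves, stratified unit
  bootstrap, and time-constant fitting from step dynamics;
* `isnkit.three_pop` — the three-population (E / non-stimulated I /
  stimulated P) model of inhibitory-subset stimulation, with the
  closed-form stimulated-population response and the simplified
  presynaptic-identity paradox criterion;
* `isnkit.pipeline` — unit-level analysis: E/I classification
  (pharmacology, high-power, waveform width), per-session L0 laser
  normalization, initial-slope statistics, population averaging with
  summed-count SEM, onset-transient detection, and model-based current
  decomposition;
* `isnkit.synth` — a synthetic-experiment generator (Poisson spike
  counts around model means, 80/20 E/I mixtures, per-session efficacies
  and laser scales) so every stage is testable without recordings;
* `isnkit.io` / `isnkit.cli` — CSV/JSON readers and writers, run
  manifests, and the `isnkit` command (`generate`, `classify`, `slopes`,
  `fit`, `bootstrap`, `stability`, `pvsim`, `simulate`, `report`).

See `docs/methods.md` for the full model description and assumptions,
and `examples/` for one short narrative script per capability.

## Worked example

```python
import numpy as np
from isnkit import TimeConstants, fixed_point, is_isn, stability_boundary_ratio
from isnkit.synth import v1_best_fit_params

params = v1_best_fit_params()   # fitted V1 operating point, W_EE = 2.56
print(is_isn(params))        # True

for L in (0.0, 1.0, 2.0):
    fp = fixed_point(params, L)
    print(f"L={L}: r_E={fp.r_E:.3f}, r_I={fp.r_I:.3f} ({fp.branch})")

print(f"stable for tau_I/tau_E up to {stability_boundary_ratio(params):.3f}")
```

prints

```
True
L=0.0: r_E=5.768, r_I=9.219 (interior)
L=1.0: r_E=1.242, r_I=5.231 (interior)
L=2.0: r_E=0.000, r_I=4.699 (boundary)
stable for tau_I/tau_E up to 5.199
```

Inhibitory rates fall from 9.2 to 5.2 spk/s as the direct drive to them
increases — the paradoxical effect — and reach their minimum where the
excitatory population is silenced (the boundary branch); the resting
fixed point stays linearly stable as long as inhibition is not slower
than about 5.2 times the excitatory time constant. Running
`python examples/03_fit_three_phase_curves.py` shows the inverse problem:
the multi-restart fit recovers every generating parameter (e.g.
`W_EE = 2.5600`, `lambda = 6.3000`) from noiseless three-phase curves.

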