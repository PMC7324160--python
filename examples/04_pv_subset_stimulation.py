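"""Stimulating a subset of inhibitory cells weakens the paradoxical effect.

Splits the fitted inhibitory population into stimulated (P) and
non-stimulated (I) subsets and computes the initial dose-response slope of
the stimulated cells as the expressing fraction varies. With multiple
inhibitory populations, ISN operation no longer guarantees paradoxical
suppression of the stimulated subset.
"""

from isnkit import build_three_pop, delta_rP, simplified_paradox
from isnkit.three_pop import SimplifiedWeights
from isnkit.synth import v1_best_fit_params

source = v1_best_fit_params()
TAUS = (7.8, 34.3, 34.3)
dL = 0.05

print("fraction of inhibitory cells stimulated -> initial slope of their "
      "dose-response (spk/s per intensity unit):")
for frac in (1.0, 0.8, 0.6, 0.4):
    p3 = build_three_pop(source, frac)
    slope = delta_rP(p3, dL, taus=TAUS) / dL
    tag = "paradoxical" if slope < 0 else "non-paradoxical"
    print(f"  frac = {frac:.1f}: {slope:+8.3f}  ({tag})")

print("\nSimplified presynaptic-identity model "
      "(factor = [1+(kI-1)W]/[1+(kP+kI-1)W]):")
for kI, kP in ((0.5, 0.6), (1.2, 0.6), (0.5, 0.3)):
    factor, cls = simplified_paradox(SimplifiedWeights(W=100, kI=kI, kP=kP))
    print(f"  kI={kI}, kP={kP}: factor = {factor:+.3f} -> {cls}")
print("\nAt large W the stimulated subset is suppressed only when kI < 1 "
      "and kP > 1 - kI.")
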