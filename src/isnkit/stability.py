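"""Linear stability of the rate-model fixed point.

At an interior fixed point (both populations above threshold) the
rectified-linear dynamics are linear, with Jacobian

    J = [[ (aE W_EE - 1)/tau_E,  -aE W_EI/tau_E ],
         [  aI W_IE/tau_I,       -(aI W_II + 1)/tau_I ]]

The closed-form eigenvalues depend on the time constants only through the
ratio r = tau_E aI W_IE / (tau_I aE W_EI), which cannot be inferred from
equilibrium data. For an ISN (aE W_EE > 1) in the saddle-free regime
(determinant D > 0), stability requires tau_I/tau_E below the boundary
(aI W_II + 1)/(aE W_EE - 1); the boundary is located here by bisection on an
eigenvalue scan and the closed form serves as a cross-check.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rate_model import BlockerEfficacy, Phase, TimeConstants, TwoPopParams, apply_blockers

__all__ = [
    "EigenResult",
    "jacobian",
    "eigenvalues_closed_form",
    "stability_boundary_ratio",
    "is_isn",
    "ratio_scan",
    "eigenvalues_numeric_3x3",
]

_IMAG_TOL = 1e-12


@dataclass(frozen=True)
class EigenResult:
    """Eigenvalue pair of the 2x2 Jacobian (units 1/ms)."""

    lambda_plus: complex
    lambda_minus: complex
    max_real: float
    stable: bool
    oscillatory: bool


def jacobian(params: TwoPopParams, taus: TimeConstants) -> np.ndarray:
    """Jacobian of the dynamics at an interior fixed point."""
    aE, aI = params.tf_E.a, params.tf_I.a
    return np.array(
        [
            [(aE * params.W_EE - 1.0) / taus.tau_E, -aE * params.W_EI / taus.tau_E],
            [aI * params.W_IE / taus.tau_I, -(aI * params.W_II + 1.0) / taus.tau_I],
        ]
    )


def eigenvalues_closed_form(params: TwoPopParams, taus: TimeConstants) -> EigenResult:
    """Closed-form eigenvalues of the interior-fixed-point Jacobian.

    lambda_pm = aE W_EI / (2 tau_E) * [ (p - r q) +- sqrt((p + r q)^2 - 4 r) ]

    with p = (aE W_EE - 1)/(aE W_EI), q = (aI W_II + 1)/(aI W_IE) and
    r = tau_E aI W_IE / (tau_I aE W_EI). Valid when both populations sit
    above threshold (rectified-linear transfer).
    """
    if taus.tau_E <= 0 or taus.tau_I <= 0:
        raise ValueError("time constants must be positive")
    aE, aI = params.tf_E.a, params.tf_I.a
    if params.W_EI == 0 or params.W_IE == 0:
        # feedback loop open: Jacobian is triangular, eigenvalues on the diagonal
        lp = (aE * params.W_EE - 1.0) / taus.tau_E
        lm = -(aI * params.W_II + 1.0) / taus.tau_I
        lam_p, lam_m = complex(max(lp, lm)), complex(min(lp, lm))
    else:
        r = taus.tau_E * aI * params.W_IE / (taus.tau_I * aE * params.W_EI)
        p = (aE * params.W_EE - 1.0) / (aE * params.W_EI)
        q = (aI * params.W_II + 1.0) / (aI * params.W_IE)
        pref = aE * params.W_EI / (2.0 * taus.tau_E)
        disc = cmath.sqrt((p + r * q) ** 2 - 4.0 * r)
        lam_p = pref * ((p - r * q) + disc)
        lam_m = pref * ((p - r * q) - disc)
    max_real = max(lam_p.real, lam_m.real)
    return EigenResult(
        lambda_plus=lam_p,
        lambda_minus=lam_m,
        max_real=max_real,
        stable=max_real < 0.0,
        oscillatory=abs(lam_p.imag) > _IMAG_TOL,
    )


def is_isn(
    params: TwoPopParams,
    phase: Phase | str = Phase.INTACT,
    eff: BlockerEfficacy | None = None,
) -> bool:
    """True iff the excitatory subnetwork alone is unstable (aE W_EE > 1).

    Optionally evaluated after applying blocker transforms for ``phase``.
    """
    if eff is not None:
        params = apply_blockers(params, phase, eff)
    return params.tf_E.a * params.W_EE > 1.0


def stability_boundary_ratio(
    params: TwoPopParams,
    bracket: tuple[float, float] = (1e-3, 1e3),
    tol: float = 1e-8,
) -> float:
    """Supremum of tau_I/tau_E for which the interior fixed point is stable.

    Found by bisection on the maximal eigenvalue real part over the ratio
    (tau_E is held at 1 ms; only the ratio matters for the sign). Equals
    (aI W_II + 1)/(aE W_EE - 1) when aE W_EE > 1, and +inf when the network
    is not an ISN (the trace is then negative for every ratio).

    Raises ``ValueError`` when D <= 0 (saddle: unstable at every ratio).
    """
    if params.determinant <= 0:
        raise ValueError("determinant D <= 0: fixed point unstable for all ratios")

    def max_real(ratio: float) -> float:
        taus = TimeConstants(1.0, ratio)
        return eigenvalues_closed_form(params, taus).max_real

    lo, hi = bracket
    if not is_isn(params):
        return math.inf
    if max_real(lo) >= 0:
        raise ValueError("unstable already at the lower bracket edge")
    if max_real(hi) < 0:
        return math.inf
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if max_real(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ratio_scan(
    params: TwoPopParams, ratios, tau_E: float = 1.0
) -> pd.DataFrame:
    """Eigenvalues over a grid of tau_I/tau_E ratios.

    Returns a DataFrame with columns ratio, re_plus, im_plus, re_minus,
    im_minus — the raw material of the stability diagram.
    """
    rows = []
    for ratio in np.asarray(ratios, dtype=float):
        res = eigenvalues_closed_form(params, TimeConstants(tau_E, tau_E * ratio))
        rows.append(
            {
                "ratio": ratio,
                "re_plus": res.lambda_plus.real,
                "im_plus": res.lambda_plus.imag,
                "re_minus": res.lambda_minus.real,
                "im_minus": res.lambda_minus.imag,
            }
        )
    return pd.DataFrame(rows)


def eigenvalues_numeric_3x3(J: np.ndarray) -> tuple[np.ndarray, bool]:
    """Numeric eigendecomposition for the three-population Jacobian.

    Plumbing for models with several inhibitory subclasses: returns the
    eigenvalues and a stability verdict (all real parts negative).
    """
    J = np.asarray(J, dtype=float)
    if J.shape != (3, 3):
        raise ValueError("expected a 3x3 Jacobian")
    vals = np.linalg.eigvals(J)
    return vals, bool(np.max(vals.real) < 0.0)
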