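"""Three-population model of inhibitory-subset stimulation.

When the opsin is expressed in only a fraction ``frac`` of inhibitory cells
(e.g. viral expression in PV interneurons), the circuit splits into three
populations: excitatory E, stimulated inhibitory P, and non-stimulated
inhibitory I. The three-population parameter set is constructed from a
fitted two-population model by splitting every inhibitory input column
``frac : (1 - frac)`` between P and I, while the I and P rows copy the
source inhibitory row (same excitatory drive, external input and
threshold). At ``frac = 1`` the (E, P) subsystem reduces exactly to the
source two-population model and I decouples from the feedback loop.

In this circuit an unstable excitatory subnetwork (W_EE > 1) no longer
guarantees paradoxical suppression of the stimulated cells: the sign of
the equilibrium response of P to its own stimulation depends on the full
connectivity. A further simplification — connectivity depending only on
the presynaptic population (E weight W, I weight kI*W, P weight kP*W) —
gives the closed-form response factor

    [1 + (kI - 1) W] / [1 + (kP + kI - 1) W]

which, for large W, is negative (paradoxical) exactly when kI < 1 and
kP > 1 - kI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rate_model import TwoPopParams

__all__ = [
    "ThreePopParams",
    "SimplifiedWeights",
    "ThreePopFixedPoint",
    "build_three_pop",
    "simulate_3pop",
    "fixed_point_3pop",
    "delta_rP",
    "delta_rP_closed_form",
    "simplified_paradox",
    "jacobian_3pop",
]

_POPS = ("E", "I", "P")


@dataclass(frozen=True)
class ThreePopParams:
    """Weights, inputs and thresholds of the E/I/P circuit.

    ``W`` is a 3x3 array of non-negative magnitudes indexed
    ``W[post, pre]`` in population order (E, I, P); presynaptic E is
    excitatory, presynaptic I and P inhibitory (signs applied in the
    equations). The opsin drive ``lam * L`` enters the P population only.
    """

    W: np.ndarray
    I_X: np.ndarray  # external inputs (E, I, P)
    x0: np.ndarray  # thresholds (E, I, P)
    lam: float
    frac: float

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape != (3, 3) or (W < 0).any():
            raise ValueError("W must be a 3x3 array of non-negative magnitudes")
        if not 0.0 < self.frac <= 1.0:
            raise ValueError("frac must lie in (0, 1]")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "I_X", np.asarray(self.I_X, dtype=float))
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float))

    def signed_weights(self) -> np.ndarray:
        """Weight matrix with inhibitory columns negated (I and P presynaptic)."""
        S = self.W.copy()
        S[:, 1] *= -1.0
        S[:, 2] *= -1.0
        return S


@dataclass(frozen=True)
class SimplifiedWeights:
    """Presynaptic-identity-only connectivity: E weight W, I k_I*W, P k_P*W."""

    W: float
    kI: float
    kP: float

    def __post_init__(self) -> None:
        if not (self.W > 0 and self.kI > 0 and self.kP > 0):
            raise ValueError("W, kI, kP must be positive")


@dataclass(frozen=True)
class ThreePopFixedPoint:
    """Fixed point with per-population active flags ('above threshold')."""

    rates: tuple[float, float, float]  # (r_E, r_I, r_P)
    active: tuple[bool, bool, bool]
    stable: bool

    @property
    def r_E(self) -> float:
        return self.rates[0]

    @property
    def r_I(self) -> float:
        return self.rates[1]

    @property
    def r_P(self) -> float:
        return self.rates[2]


def build_three_pop(source: TwoPopParams, frac: float) -> ThreePopParams:
    """Split the source inhibitory population into stimulated/non-stimulated.

    The E row keeps W_EE and I_EX from the source; each population's
    inhibitory input is split ``(1 - frac)`` onto I and ``frac`` onto P from
    the source's inhibitory weight onto that population (W_EI for E, W_II
    for I and P). The I and P rows copy the source inhibitory row (W_IE,
    I_IX, x0_I). Column conservation W_XI + W_XP = source inhibitory weight
    onto X holds exactly.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    s = source
    W = np.array(
        [
            [s.W_EE, (1 - frac) * s.W_EI, frac * s.W_EI],
            [s.W_IE, (1 - frac) * s.W_II, frac * s.W_II],
            [s.W_IE, (1 - frac) * s.W_II, frac * s.W_II],
        ]
    )
    I_X = np.array([s.I_EX, s.I_IX, s.I_IX])
    x0 = np.array([s.tf_E.x0, s.tf_I.x0, s.tf_I.x0])
    return ThreePopParams(W=W, I_X=I_X, x0=x0, lam=s.lam, frac=frac)


def _inputs(params: ThreePopParams, r: np.ndarray, L: float) -> np.ndarray:
    x = params.signed_weights() @ r + params.I_X
    x[2] += params.lam * L
    return x


def simulate_3pop(
    params: ThreePopParams,
    L: float,
    taus=(10.0, 10.0, 10.0),
    r0=(0.0, 0.0, 0.0),
    dt: float = 0.1,
    T: float = 2000.0,
    rate_cap: float = 1e6,
):
    """Euler integration of the three-population rectified-linear dynamics."""
    taus = np.asarray(taus, dtype=float)
    n = int(round(T / dt))
    r = np.asarray(r0, dtype=float).copy()
    traj = np.empty((n + 1, 3))
    traj[0] = r
    diverged = False
    for k in range(n):
        x = _inputs(params, r, L)
        phi = np.maximum(x - params.x0, 0.0)
        r = r + dt / taus * (-r + phi)
        traj[k + 1] = r
        if (r > rate_cap).any():
            diverged = True
            traj[k + 1 :] = np.minimum(r, rate_cap)
            break
    return traj, diverged


def _solve_pattern(params: ThreePopParams, L: float, active: tuple[bool, ...]):
    """Exact fixed point for one rectification pattern, or None."""
    S = params.signed_weights()
    h = params.I_X - params.x0
    h = h.copy()
    h[2] += params.lam * L
    idx = [i for i in range(3) if active[i]]
    r = np.zeros(3)
    if idx:
        A = np.eye(len(idx)) - S[np.ix_(idx, idx)]
        try:
            r_act = np.linalg.solve(A, h[idx])
        except np.linalg.LinAlgError:
            return None
        r[idx] = r_act
        if (r_act <= 0).any():
            return None
    # inactive populations must sit at or below threshold
    x = _inputs(params, r, L)
    for i in range(3):
        if not active[i] and x[i] - params.x0[i] > 1e-9:
            return None
    return r


def fixed_point_3pop(
    params: ThreePopParams,
    L: float,
    taus=(10.0, 10.0, 10.0),
    dt: float = 0.1,
    T: float = 2000.0,
) -> ThreePopFixedPoint:
    """Fixed point of the three-population model at intensity ``L``.

    The piecewise-linear equilibrium is found by integrating the dynamics
    from the resting (L = 0) state until convergence, identifying the
    rectification pattern of the converged state, and solving that
    pattern's linear system exactly. Patterns are checked in order of
    decreasing number of active populations (deterministic tie-break) if
    the integrated pattern is not self-consistent. Returns an "unstable"
    verdict (``stable=False``) when the dynamics diverge.
    """
    rest, div0 = simulate_3pop(params, 0.0, taus=taus, dt=dt, T=T)
    traj, diverged = simulate_3pop(params, L, taus=taus, r0=rest[-1], dt=dt, T=T)
    if div0 or diverged:
        r = tuple(float(v) for v in traj[-1])
        return ThreePopFixedPoint(rates=r, active=(True, True, True), stable=False)
    r_end = traj[-1]
    patterns = sorted(
        [(bool(a), bool(b), bool(c)) for a in (1, 0) for b in (1, 0) for c in (1, 0)],
        key=lambda p: -sum(p),
    )
    guess = tuple(bool(v > 1e-6) for v in r_end)
    ordered = [guess] + [p for p in patterns if p != guess]
    for pat in ordered:
        r = _solve_pattern(params, L, pat)
        if r is not None and np.allclose(r, r_end, atol=1e-4):
            return ThreePopFixedPoint(
                rates=tuple(float(v) for v in r), active=pat, stable=True
            )
    # fall back to any self-consistent pattern near the trajectory end
    for pat in ordered:
        r = _solve_pattern(params, L, pat)
        if r is not None:
            return ThreePopFixedPoint(
                rates=tuple(float(v) for v in r), active=pat, stable=True
            )
    return ThreePopFixedPoint(
        rates=tuple(float(v) for v in r_end), active=guess, stable=False
    )


def delta_rP_closed_form(params: ThreePopParams, L: float) -> float:
    """Equilibrium response of the stimulated population, all-active regime.

    r_P(L) - r_P(0) = [(1 - W_EE)(W_II + 1) + W_EI W_IE] * lam * L / N

    with N the determinant-like normalizer of the all-active linear system.
    Valid when all three populations are above threshold at 0 and L.
    """
    W = params.W
    W_EE, W_EI, W_EP = W[0]
    W_IE, W_II, W_IP = W[1]
    W_PE, W_PI, W_PP = W[2]
    N = (
        (1 - W_EE) * ((W_II + 1) * (W_PP + 1) - W_IP * W_PI)
        - W_EI * (W_IP * W_PE - W_IE * (W_PP + 1))
        + W_EP * ((W_II + 1) * W_PE - W_IE * W_PI)
    )
    if N == 0:
        raise ZeroDivisionError("singular three-population model: N = 0")
    num = (1 - W_EE) * (W_II + 1) + W_EI * W_IE
    return num * params.lam * L / N


def delta_rP(params: ThreePopParams, L: float, **kw) -> float:
    """r_P(L) - r_P(0) from two fixed-point solves (any regime)."""
    fp0 = fixed_point_3pop(params, 0.0, **kw)
    fpL = fixed_point_3pop(params, L, **kw)
    return fpL.r_P - fp0.r_P


def simplified_paradox(sw: SimplifiedWeights) -> tuple[float, str]:
    """Signed response factor of the presynaptic-identity-only model.

    Returns ``(factor, classification)`` with
    ``factor = [1 + (kI - 1) W] / [1 + (kP + kI - 1) W]`` and
    classification ``"paradoxical"`` iff the factor is negative. In the
    large-W limit the classification reduces to (kI < 1 and kP > 1 - kI).
    """
    den = 1.0 + (sw.kP + sw.kI - 1.0) * sw.W
    if den == 0.0:
        raise ZeroDivisionError("singular simplified model: zero denominator")
    factor = (1.0 + (sw.kI - 1.0) * sw.W) / den
    return factor, "paradoxical" if factor < 0 else "non-paradoxical"


def jacobian_3pop(params: ThreePopParams, taus) -> np.ndarray:
    """Jacobian of the all-active linearized dynamics (plumbing for eigensolves)."""
    taus = np.asarray(taus, dtype=float)
    S = params.signed_weights()
    return (S - np.eye(3)) / taus[:, None]
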