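"""Two-population excitatory/inhibitory rate model with optogenetic drive.

The forward model is a Wilson–Cowan-style pair of rate equations

    tau_E dr_E/dt = -r_E + phi_E(W_EE r_E - W_EI r_I + I_EX)
    tau_I dr_I/dt = -r_I + phi_I(W_IE r_E - W_II r_I + I_IX + lambda * L)

where ``phi`` is a static transfer function (rectified-linear by default,
optionally a softplus smoothing of it), ``W_AB >= 0`` is the magnitude of the
connection from population B onto A (signs live in the equations), ``I_AX``
is the external input, and the optogenetic stimulus enters the inhibitory
population as an extra input ``lambda * L`` proportional to light intensity.

Pharmacological blockade of excitatory or inhibitory synapses is modeled by
multiplicative survival factors (:class:`BlockerEfficacy`): excitatory
blockers scale every glutamatergic term (``W_EE``, ``I_EX``, ``W_IE``,
``I_IX``) by ``eps_E``; inhibitory blockers additionally scale ``W_EI`` and
``W_II`` by ``eps_I``. The opsin drive is never scaled.

The network is an inhibition-stabilized network (ISN) when the excitatory
subnetwork is unstable on its own (``a_E * W_EE > 1``) but the full circuit
is stable; its signature is the paradoxical steady-state suppression of the
inhibitory population under direct inhibitory stimulation.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TransferFunctionSpec",
    "TwoPopParams",
    "TimeConstants",
    "BlockerEfficacy",
    "Phase",
    "RateState",
    "FixedPointResult",
    "BistableWarning",
    "evaluate_tf",
    "apply_blockers",
    "fixed_point",
    "fixed_point_curve",
    "interior_slope_dri_dl",
    "silencing_intensity",
    "simulate_dynamics",
    "rescale_params",
    "load_params",
    "save_params",
]


class BistableWarning(UserWarning):
    """Both fixed-point branches are self-consistent at this intensity."""


class Phase(str, enum.Enum):
    """Pharmacological phase of the experiment."""

    INTACT = "intact"
    E_BLOCKED = "e_blocked"
    EI_BLOCKED = "ei_blocked"


@dataclass(frozen=True)
class TransferFunctionSpec:
    """Static transfer function (f-I curve) of one population.

    Parameters
    ----------
    kind : {"rectified_linear", "softplus"}
    a : float
        Gain (spk/s per input unit), > 0.
    x0 : float
        Threshold, in input units (spk/s-equivalent).
    b : float, optional
        Softplus smoothing width; required (> 0) for ``kind="softplus"``.
        The softplus ``b * log(1 + exp(a/b * (x - x0)))`` converges to the
        rectified-linear ``a * max(x - x0, 0)`` as ``b -> 0+``.
    """

    kind: str = "rectified_linear"
    a: float = 1.0
    x0: float = 0.0
    b: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rectified_linear", "softplus"):
            raise ValueError(f"unknown transfer function kind {self.kind!r}")
        if not self.a > 0:
            raise ValueError("gain a must be positive")
        if self.kind == "softplus" and (self.b is None or not self.b > 0):
            raise ValueError("softplus requires smoothing width b > 0")

    def __call__(self, x):
        return evaluate_tf(x, self)


def evaluate_tf(x, tf: TransferFunctionSpec):
    """Evaluate the transfer function at input ``x`` (scalar or array).

    Returns a non-negative rate in spk/s. The softplus branch is
    overflow-guarded (uses ``logaddexp``) and is accurate for |x| up to 1e6.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to transfer function")
    if tf.kind == "rectified_linear":
        out = tf.a * np.maximum(x - tf.x0, 0.0)
    else:
        z = (tf.a / tf.b) * (x - tf.x0)
        out = tf.b * np.logaddexp(0.0, z)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TwoPopParams:
    """Connectivity, inputs, opsin efficacy and transfer functions.

    Weights are stored as non-negative magnitudes; the inhibitory sign is
    applied inside the equations. ``lam`` is the opsin efficacy (spk/s per
    normalized intensity unit).
    """

    W_EE: float
    W_EI: float
    W_IE: float
    W_II: float
    I_EX: float
    I_IX: float
    lam: float = 0.0
    tf_E: TransferFunctionSpec = field(default_factory=TransferFunctionSpec)
    tf_I: TransferFunctionSpec = field(default_factory=TransferFunctionSpec)

    def __post_init__(self) -> None:
        for name in ("W_EE", "W_EI", "W_IE", "W_II"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")

    @property
    def determinant(self) -> float:
        """D = aE aI W_EI W_IE - (aI W_II + 1)(aE W_EE - 1).

        D != 0 is required for the interior fixed point; D > 0 is the
        saddle-free regime.
        """
        aE, aI = self.tf_E.a, self.tf_I.a
        return aE * aI * self.W_EI * self.W_IE - (aI * self.W_II + 1.0) * (
            aE * self.W_EE - 1.0
        )


@dataclass(frozen=True)
class TimeConstants:
    """Rate time constants in milliseconds."""

    tau_E: float
    tau_I: float

    def __post_init__(self) -> None:
        if not (self.tau_E > 0 and self.tau_I > 0):
            raise ValueError("time constants must be positive")

    @property
    def ratio(self) -> float:
        return self.tau_I / self.tau_E


@dataclass(frozen=True)
class BlockerEfficacy:
    """Survival factors of synaptic efficacy under blockade; 1 = no blockade."""

    eps_E: float = 1.0
    eps_I: float = 1.0

    def __post_init__(self) -> None:
        for name in ("eps_E", "eps_I"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class RateState:
    """Population rates (spk/s)."""

    r_E: float
    r_I: float


@dataclass(frozen=True)
class FixedPointResult:
    """Fixed point with the rectification branch that produced it.

    ``branch`` is ``"interior"`` (both populations above threshold) or
    ``"boundary"`` (excitatory population silenced, r_E = 0). ``bistable``
    marks intensities where both branches are simultaneously self-consistent.
    """

    rates: RateState
    branch: str
    bistable: bool = False

    @property
    def r_E(self) -> float:
        return self.rates.r_E

    @property
    def r_I(self) -> float:
        return self.rates.r_I


def apply_blockers(
    params: TwoPopParams, phase: Phase | str, eff: BlockerEfficacy
) -> TwoPopParams:
    """Return the parameter set as modified by pharmacological blockade.

    Excitatory blockers scale W_EE, I_EX, W_IE and I_IX by ``eps_E`` (the
    external inputs are glutamatergic and are blocked too); inhibitory
    blockers additionally scale W_EI and W_II by ``eps_I``. The opsin
    efficacy ``lam`` is never scaled. ``intact`` is the identity.
    """
    phase = Phase(phase)
    if phase is Phase.INTACT:
        return params
    out = replace(
        params,
        W_EE=params.W_EE * eff.eps_E,
        I_EX=params.I_EX * eff.eps_E,
        W_IE=params.W_IE * eff.eps_E,
        I_IX=params.I_IX * eff.eps_E,
    )
    if phase is Phase.EI_BLOCKED:
        out = replace(out, W_EI=out.W_EI * eff.eps_I, W_II=out.W_II * eff.eps_I)
    return out


def _require_relu(params: TwoPopParams, what: str) -> None:
    if params.tf_E.kind != "rectified_linear" or params.tf_I.kind != "rectified_linear":
        raise ValueError(f"{what} is defined for rectified-linear transfer functions")


def fixed_point_curve(params: TwoPopParams, L) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fixed points over an intensity array.

    Returns ``(r_E, r_I, interior_mask)`` arrays. Rectified-linear transfer
    functions only. The interior branch is used wherever it is
    self-consistent (both rates positive); elsewhere the boundary branch
    ``r_E = 0, r_I = max(aI (I_IX + lam L - x0_I) / (aI W_II + 1), 0)``.
    """
    _require_relu(params, "fixed_point")
    L = np.atleast_1d(np.asarray(L, dtype=float))
    aE, aI = params.tf_E.a, params.tf_I.a
    D = params.determinant
    if D == 0.0:
        raise ZeroDivisionError("singular model: determinant D = 0")
    hE = params.I_EX - params.tf_E.x0
    hI = params.I_IX + params.lam * L - params.tf_I.x0
    rE_int = ((aI * params.W_II + 1.0) * aE * hE - aE * aI * params.W_EI * hI) / D
    rI_int = (aI * params.W_IE * aE * hE + (1.0 - aE * params.W_EE) * aI * hI) / D
    interior = (rE_int > 0.0) & (rI_int > 0.0)
    rI_bnd = np.maximum(aI * hI / (aI * params.W_II + 1.0), 0.0)
    r_E = np.where(interior, rE_int, 0.0)
    r_I = np.where(interior, rI_int, rI_bnd)
    return r_E, r_I, interior


def fixed_point(params: TwoPopParams, L: float) -> FixedPointResult:
    """Steady-state rates at constant intensity ``L`` (rectified-linear).

    Returns the interior branch of the piecewise-linear equilibrium when it
    is self-consistent, otherwise the boundary branch with the excitatory
    population silenced. When both branches are simultaneously
    self-consistent the interior branch is returned and a
    :class:`BistableWarning` is issued.
    """
    r_E, r_I, interior = fixed_point_curve(params, L)
    rE, rI, inter = float(r_E[0]), float(r_I[0]), bool(interior[0])
    bistable = False
    if inter:
        # boundary branch also valid if its E input stays below threshold
        aI = params.tf_I.a
        hI = params.I_IX + params.lam * float(L) - params.tf_I.x0
        rI_bnd = max(aI * hI / (aI * params.W_II + 1.0), 0.0)
        xE = -params.W_EI * rI_bnd + params.I_EX
        if xE <= params.tf_E.x0 and rI_bnd >= 0.0:
            bistable = True
            warnings.warn(
                "both fixed-point branches are self-consistent; returning the "
                "interior branch",
                BistableWarning,
                stacklevel=2,
            )
    return FixedPointResult(
        rates=RateState(rE, rI), branch="interior" if inter else "boundary",
        bistable=bistable,
    )


def interior_slope_dri_dl(params: TwoPopParams) -> float:
    """Slope d r_I / dL of the interior branch: -(aE W_EE - 1) aE aI lam / D.

    Negative iff the network is an ISN (aE W_EE > 1) in the saddle-free
    regime D > 0 — the paradoxical-suppression law.
    """
    aE, aI = params.tf_E.a, params.tf_I.a
    return -(aE * params.W_EE - 1.0) * aE * aI * params.lam / params.determinant


def silencing_intensity(params: TwoPopParams) -> float:
    """Intensity L* at which the interior-branch r_E crosses zero.

    Above L* the excitatory population is silent and the inhibitory
    dose-response slope flips to +aI*lam/(aI*W_II + 1); the inhibitory
    minimum coincides with L*. Returns +inf when lam = 0 or the interior
    r_E does not depend on L.
    """
    _require_relu(params, "silencing_intensity")
    if params.lam == 0.0 or params.W_EI == 0.0:
        return math.inf
    hE = params.I_EX - params.tf_E.x0
    # interior r_E = 0  <=>  (aI W_II + 1) hE = aI W_EI (I_IX + lam L - x0_I)
    aI = params.tf_I.a
    lhs = (aI * params.W_II + 1.0) * hE / (aI * params.W_EI)
    return (lhs - (params.I_IX - params.tf_I.x0)) / params.lam


def simulate_dynamics(
    params: TwoPopParams,
    taus: TimeConstants,
    L,
    dt: float = 0.1,
    T: float = 500.0,
    init: RateState | None = None,
    rate_cap: float = 1e6,
):
    """Integrate the rate equations with fixed-step explicit Euler.

    Parameters
    ----------
    L : float, array, or callable
        Laser intensity: constant, per-time-step array (length = number of
        steps), or a function of time in ms (piecewise-constant traces are
        typical).
    dt : float
        Step, ms; must satisfy ``dt <= min(tau_E, tau_I) / 10``.
    T : float
        Total duration, ms.
    init : RateState, optional
        Initial rates; defaults to the L(0) fixed point for rectified-linear
        transfer functions, else zeros.

    Returns
    -------
    t, r_E, r_I : ndarray
        Time grid (ms) and rate traces (spk/s), including t = 0.
    diverged : bool
        True if either rate exceeded ``rate_cap`` (trace is capped there).
    """
    if dt > min(taus.tau_E, taus.tau_I) / 10.0 + 1e-12:
        raise ValueError("dt too large: require dt <= min(tau)/10")
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    if callable(L):
        Lt = np.asarray([float(L(ti)) for ti in t[:-1]], dtype=float)
    else:
        La = np.atleast_1d(np.asarray(L, dtype=float))
        Lt = np.full(n, La[0]) if La.size == 1 else La
        if Lt.size != n:
            raise ValueError(f"L trace has {Lt.size} entries, expected {n}")
    if init is None:
        if params.tf_E.kind == "rectified_linear" and params.tf_I.kind == "rectified_linear":
            fp = fixed_point(params, float(Lt[0]))
            init = fp.rates
        else:
            init = RateState(0.0, 0.0)
    rE = np.empty(n + 1)
    rI = np.empty(n + 1)
    rE[0], rI[0] = init.r_E, init.r_I
    diverged = False
    for k in range(n):
        xE = params.W_EE * rE[k] - params.W_EI * rI[k] + params.I_EX
        xI = params.W_IE * rE[k] - params.W_II * rI[k] + params.I_IX + params.lam * Lt[k]
        rE[k + 1] = rE[k] + dt / taus.tau_E * (-rE[k] + evaluate_tf(xE, params.tf_E))
        rI[k + 1] = rI[k] + dt / taus.tau_I * (-rI[k] + evaluate_tf(xI, params.tf_I))
        if rE[k + 1] > rate_cap or rI[k + 1] > rate_cap:
            diverged = True
            rE[k + 1 :] = min(rE[k + 1], rate_cap)
            rI[k + 1 :] = min(rI[k + 1], rate_cap)
            break
    return t, rE, rI, diverged


def rescale_params(
    params: TwoPopParams, gamma_E: float, gamma_I: float
) -> TwoPopParams:
    """Apply the two-family rescaling that leaves every fixed point invariant.

    The equilibrium equations determine the parameters only up to one
    multiplicative constant per population:

        {W_EE - 1, W_EI, I_EX, x0_E}          -> gamma_E * (...)
        {W_IE, W_II + 1, I_IX, x0_I, lam}     -> gamma_I * (...)

    Defined for rectified-linear transfer functions with unit gains.
    Raises if the transformed W_EE or W_II would be negative.
    """
    _require_relu(params, "rescale_params")
    if not (gamma_E > 0 and gamma_I > 0):
        raise ValueError("gammas must be positive")
    W_EE = gamma_E * (params.W_EE - 1.0) + 1.0
    W_II = gamma_I * (params.W_II + 1.0) - 1.0
    if W_EE < 0 or W_II < 0:
        raise ValueError("rescaling leaves the non-negative-weight region")
    return replace(
        params,
        W_EE=W_EE,
        W_EI=gamma_E * params.W_EI,
        I_EX=gamma_E * params.I_EX,
        W_IE=gamma_I * params.W_IE,
        W_II=W_II,
        I_IX=gamma_I * params.I_IX,
        lam=gamma_I * params.lam,
        tf_E=replace(params.tf_E, x0=gamma_E * params.tf_E.x0),
        tf_I=replace(params.tf_I, x0=gamma_I * params.tf_I.x0),
    )


# --- parameter file I/O ------------------------------------------------------

_JSON_KEYS = (
    "W_EE", "W_EI", "W_IE", "W_II", "I_EX", "I_IX",
    "x0_E", "x0_I", "a_E", "a_I", "b_E", "b_I", "lambda",
    "tau_E_ms", "tau_I_ms",
)


def load_params(path) -> tuple[TwoPopParams, TimeConstants | None]:
    """Read a flat-JSON parameter file.

    Recognized keys: W_EE, W_EI, W_IE, W_II, I_EX, I_IX, x0_E, x0_I, a_E,
    a_I, b_E, b_I, lambda, tau_E_ms, tau_I_ms. Missing b_* implies
    rectified-linear transfer. Returns ``(params, taus_or_None)``.
    """
    d = json.loads(Path(path).read_text())
    unknown = set(d) - set(_JSON_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")

    def tf(which: str) -> TransferFunctionSpec:
        b = d.get(f"b_{which}")
        return TransferFunctionSpec(
            kind="softplus" if b is not None else "rectified_linear",
            a=d.get(f"a_{which}", 1.0),
            x0=d.get(f"x0_{which}", 0.0),
            b=b,
        )

    params = TwoPopParams(
        W_EE=d["W_EE"], W_EI=d["W_EI"], W_IE=d["W_IE"], W_II=d["W_II"],
        I_EX=d["I_EX"], I_IX=d["I_IX"], lam=d.get("lambda", 0.0),
        tf_E=tf("E"), tf_I=tf("I"),
    )
    taus = None
    if "tau_E_ms" in d and "tau_I_ms" in d:
        taus = TimeConstants(d["tau_E_ms"], d["tau_I_ms"])
    return params, taus


def save_params(path, params: TwoPopParams, taus: TimeConstants | None = None) -> None:
    """Write a parameter file readable by :func:`load_params`."""
    d = {
        "W_EE": params.W_EE, "W_EI": params.W_EI,
        "W_IE": params.W_IE, "W_II": params.W_II,
        "I_EX": params.I_EX, "I_IX": params.I_IX,
        "x0_E": params.tf_E.x0, "x0_I": params.tf_I.x0,
        "a_E": params.tf_E.a, "a_I": params.tf_I.a,
        "lambda": params.lam,
    }
    if params.tf_E.kind == "softplus":
        d["b_E"] = params.tf_E.b
    if params.tf_I.kind == "softplus":
        d["b_I"] = params.tf_I.b
    if taus is not None:
        d["tau_E_ms"] = taus.tau_E
        d["tau_I_ms"] = taus.tau_I
    Path(path).write_text(json.dumps(d, indent=2) + "\n")
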