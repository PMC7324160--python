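"""Parameter inference from three-phase optogenetic dose-response curves.

The equilibrium model predicts population mean rates as a function of laser
intensity in each pharmacological phase (intact / excitatory blockers /
excitatory + inhibitory blockers). All free parameters — the four weights,
two external inputs, two thresholds, the opsin efficacy, and one blocker
efficacy pair per recorded session — are inferred simultaneously by
multi-restart bounded nonlinear least squares: random uniform starting
points on [0, 10] (efficacies on [0, 1]), a trust-region-reflective local
solve per restart, and the minimum-error solution over restarts.

With a single phase only ratios of parameters are identifiable (the
equilibrium equations admit a two-parameter rescaling family); combining
the three phases pins all of them, with gains fixed at 1.

Bootstrap uncertainty resamples units with replacement within each
(session, population) stratum, rebuilds the population curves, and reruns
the global fit per resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .rate_model import (
    BlockerEfficacy,
    Phase,
    TimeConstants,
    TransferFunctionSpec,
    TwoPopParams,
    apply_blockers,
    fixed_point,
    fixed_point_curve,
    simulate_dynamics,
)

__all__ = [
    "DoseResponseDataset",
    "FitResult",
    "BootstrapResult",
    "TauFitResult",
    "IdentifiabilityWarning",
    "residual_loss",
    "predict_rates",
    "fit_global",
    "bootstrap_fit",
    "build_dataset_from_units",
    "fit_time_constants",
    "count_free_parameters",
]

_PARAM_NAMES = ("W_EE", "W_EI", "W_IE", "W_II", "I_EX", "I_IX", "x0_E", "x0_I", "lam")
_SINGULAR_PENALTY = 1e3  # per-point residual when the model is singular


class IdentifiabilityWarning(UserWarning):
    """Dataset does not constrain all parameters (fewer than three phases)."""


@dataclass
class DoseResponseDataset:
    """Population dose-response curves in long format.

    ``table`` columns: session, phase, population ('E'|'I'), intensity
    (normalized laser units), rate (spk/s), sem (spk/s), n_units.
    Intact-phase rows are pooled across sessions (the model prediction does
    not depend on the session there); blocker-phase rows keep session
    identity because each session has its own blocker efficacy pair.
    """

    table: pd.DataFrame

    REQUIRED = ("session", "phase", "population", "intensity", "rate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("empty dataset")
        if "sem" not in self.table.columns:
            self.table = self.table.assign(sem=np.nan)
        if "n_units" not in self.table.columns:
            self.table = self.table.assign(n_units=1)
        if (self.table["rate"] < 0).any():
            raise ValueError("negative rates in dataset")
        for (sess, phase, pop), g in self.table.groupby(
            ["session", "phase", "population"], sort=False
        ):
            li = g["intensity"].to_numpy()
            if not np.all(np.diff(li) > 0):
                raise ValueError(
                    f"intensities must be strictly increasing within curve "
                    f"({sess}, {phase}, {pop})"
                )

    @property
    def phases(self) -> list[str]:
        return sorted(self.table["phase"].unique())

    @property
    def blocker_sessions(self) -> list:
        mask = self.table["phase"] != Phase.INTACT.value
        return sorted(self.table.loc[mask, "session"].unique())


@dataclass
class FitResult:
    """Best-fit parameters with per-session blocker efficacies."""

    params: TwoPopParams
    eps: dict
    sse: float
    n_restarts: int
    best_restart_seed: int
    success: bool = True

    def as_series(self) -> pd.Series:
        d = {n: getattr(self.params, n) for n in ("W_EE", "W_EI", "W_IE", "W_II",
                                                  "I_EX", "I_IX", "lam")}
        d["x0_E"] = self.params.tf_E.x0
        d["x0_I"] = self.params.tf_I.x0
        for s, e in self.eps.items():
            d[f"eps_E[{s}]"] = e.eps_E
            d[f"eps_I[{s}]"] = e.eps_I
        d["sse"] = self.sse
        return pd.Series(d)


@dataclass
class BootstrapResult:
    """Resampled fits with per-parameter summaries."""

    samples: list = field(default_factory=list)
    summary: pd.DataFrame | None = None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_series() for s in self.samples])


# --- prediction and loss -----------------------------------------------------


def _vector_to_params(theta: np.ndarray) -> TwoPopParams:
    (wee, wei, wie, wii, iex, iix, x0e, x0i, lam) = theta[:9]
    return TwoPopParams(
        W_EE=wee, W_EI=wei, W_IE=wie, W_II=wii, I_EX=iex, I_IX=iix, lam=lam,
        tf_E=TransferFunctionSpec(a=1.0, x0=x0e),
        tf_I=TransferFunctionSpec(a=1.0, x0=x0i),
    )


def _params_to_vector(params: TwoPopParams) -> np.ndarray:
    return np.array(
        [params.W_EE, params.W_EI, params.W_IE, params.W_II,
         params.I_EX, params.I_IX, params.tf_E.x0, params.tf_I.x0, params.lam]
    )


def predict_rates(
    params: TwoPopParams,
    eps: BlockerEfficacy,
    phase: Phase | str,
    intensities,
    population: str,
) -> np.ndarray:
    """Model mean rates for one curve (one phase, one population)."""
    p = apply_blockers(params, phase, eps)
    r_E, r_I, _ = fixed_point_curve(p, intensities)
    return r_E if population == "E" else r_I


def _curve_groups(dataset: DoseResponseDataset):
    """Pre-extracted arrays per (session, phase, population) curve."""
    groups = []
    for (sess, phase, pop), g in dataset.table.groupby(
        ["session", "phase", "population"], sort=True
    ):
        groups.append(
            (
                sess,
                Phase(phase),
                pop,
                g["intensity"].to_numpy(dtype=float),
                g["rate"].to_numpy(dtype=float),
                g["sem"].to_numpy(dtype=float),
            )
        )
    return groups


def _residual_vector(theta, groups, sessions, weight_sem):
    # hot path of the fit: the blocker transform and both fixed-point
    # branches are inlined as scalar/array arithmetic (unit gains)
    wee, wei, wie, wii, iex, iix, x0e, x0i, lam = theta[:9]
    sess_idx = {s: i for i, s in enumerate(sessions)}
    out = []
    for sess, phase, pop, L, rate, sem in groups:
        WEE, WEI, WIE, WII, IEX, IIX = wee, wei, wie, wii, iex, iix
        if phase is not Phase.INTACT:
            i = sess_idx[sess]
            eE = theta[9 + 2 * i]
            WEE, IEX, WIE, IIX = eE * WEE, eE * IEX, eE * WIE, eE * IIX
            if phase is Phase.EI_BLOCKED:
                eI = theta[10 + 2 * i]
                WEI, WII = eI * WEI, eI * WII
        D = WEI * WIE - (WII + 1.0) * (WEE - 1.0)
        if abs(D) < 1e-9:
            out.append(np.full(L.shape, _SINGULAR_PENALTY))
            continue
        hE = IEX - x0e
        hI = IIX + lam * L - x0i
        rE_int = ((WII + 1.0) * hE - WEI * hI) / D
        rI_int = (WIE * hE + (1.0 - WEE) * hI) / D
        interior = (rE_int > 0.0) & (rI_int > 0.0)
        pred_E = np.where(interior, rE_int, 0.0)
        pred_I = np.where(interior, rI_int,
                          np.maximum(hI / (WII + 1.0), 0.0))
        res = (pred_E if pop == "E" else pred_I) - rate
        if weight_sem:
            w = np.where(np.isfinite(sem) & (sem > 0), sem, 1.0)
            res = res / w
        out.append(res)
    return np.concatenate(out)


def residual_loss(
    params: TwoPopParams,
    eps_map: dict,
    dataset: DoseResponseDataset,
    weight_sem: bool = False,
) -> float:
    """Sum of squared differences between observed and predicted rates.

    A singular model (determinant ~ 0 in any phase) contributes a large
    finite penalty per point rather than raising, so optimizers can step
    through such regions.
    """
    sessions = dataset.blocker_sessions
    theta = np.concatenate(
        [
            _params_to_vector(params),
            np.ravel(
                [
                    [eps_map.get(s, BlockerEfficacy()).eps_E,
                     eps_map.get(s, BlockerEfficacy()).eps_I]
                    for s in sessions
                ]
            ) if sessions else np.empty(0),
        ]
    )
    res = _residual_vector(theta, _curve_groups(dataset), sessions, weight_sem)
    return float(np.sum(res**2))


# --- global fit --------------------------------------------------------------


def fit_global(
    dataset: DoseResponseDataset,
    n_restarts: int = 1000,
    init_range: tuple[float, float] = (0.0, 10.0),
    seed: int | None = None,
    weight_sem: bool = False,
    max_nfev: int | None = None,
) -> FitResult:
    """Multi-restart bounded least squares over all equilibrium parameters.

    Each restart draws the nine equilibrium parameters i.i.d. uniform on
    ``init_range`` and each session's efficacy pair uniform on [0, 1], then
    runs a trust-region-reflective local least-squares solve with all
    parameters constrained non-negative and efficacies in [0, 1] (gains are
    pinned at 1). The restart with minimal summed squared error wins;
    the result is deterministic given ``seed``.
    """
    if len(dataset.table) == 0:
        raise ValueError("empty dataset")
    if len(dataset.phases) < 3:
        warnings.warn(
            "fewer than three phases: parameters are identifiable only up to "
            "a two-parameter rescaling family",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    sessions = dataset.blocker_sessions
    groups = _curve_groups(dataset)
    n_eps = 2 * len(sessions)
    lower = np.concatenate([np.zeros(9), np.zeros(n_eps)])
    upper = np.concatenate([np.full(9, np.inf), np.ones(n_eps)])
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_restarts):
        x0 = np.concatenate(
            [
                rng.uniform(init_range[0], init_range[1], size=9),
                rng.uniform(0.0, 1.0, size=n_eps),
            ]
        )
        x0 = np.clip(x0, lower + 1e-9, None)
        try:
            sol = least_squares(
                _residual_vector,
                x0,
                bounds=(lower, upper),
                method="trf",
                args=(groups, sessions, weight_sem),
                max_nfev=max_nfev,
            )
        except Exception:  # pragma: no cover - defensive against optimizer edge cases
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x.copy(), k)
    if best is None:
        raise RuntimeError("all restarts failed")
    sse, theta, k_best = best
    eps = {
        s: BlockerEfficacy(float(theta[9 + 2 * i]), float(theta[10 + 2 * i]))
        for i, s in enumerate(sessions)
    }
    return FitResult(
        params=_vector_to_params(theta),
        eps=eps,
        sse=sse,
        n_restarts=n_restarts,
        best_restart_seed=k_best,
    )


# --- bootstrap ---------------------------------------------------------------


def build_dataset_from_units(unit_rates: pd.DataFrame) -> DoseResponseDataset:
    """Average unit-level dose-response rows into population curves.

    ``unit_rates`` columns: session, unit_id, population, phase, intensity,
    rate. Intact-phase rows are pooled under session label ``"pooled"``.
    """
    df = unit_rates.copy()
    df.loc[df["phase"] == Phase.INTACT.value, "session"] = "pooled"
    agg = (
        df.groupby(["session", "phase", "population", "intensity"])["rate"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "rate", "count": "n_units"})
    )
    agg = agg.sort_values(["session", "phase", "population", "intensity"])
    return DoseResponseDataset(agg.reset_index(drop=True))


def bootstrap_fit(
    unit_rates: pd.DataFrame,
    n_boot: int = 10_000,
    n_restarts_per_boot: int = 20,
    seed: int | None = None,
    weight_sem: bool = False,
    identity_first: bool = False,
) -> BootstrapResult:
    """Bootstrap the global fit by resampling units within strata.

    Units are resampled with replacement within each (session, population)
    stratum — preserving the shape of the dataset — the population curves
    are rebuilt, and :func:`fit_global` is run per resample. Summaries per
    parameter: median, mode (histogram peak), and 2.5/97.5 percentiles.

    ``identity_first`` makes the first "resample" the identity (no
    resampling), which reproduces the plain global fit.
    """
    if n_boot < 2 and not identity_first:
        raise ValueError("n_boot must be >= 2 for summaries")
    rng = np.random.default_rng(seed)
    strata = {
        key: g["unit_id"].unique()
        for key, g in unit_rates.groupby(["session", "population"])
    }
    samples = []
    for b in range(n_boot):
        if identity_first and b == 0:
            # identity resample, fitted with the caller's seed: reproduces
            # a plain fit_global(..., seed=seed) call exactly
            ds = build_dataset_from_units(unit_rates)
            samples.append(
                fit_global(ds, n_restarts=n_restarts_per_boot, seed=seed,
                           weight_sem=weight_sem)
            )
            continue
        else:
            parts = []
            for (sess, pop), ids in strata.items():
                draw = rng.choice(ids, size=len(ids), replace=True)
                g = unit_rates[
                    (unit_rates["session"] == sess)
                    & (unit_rates["population"] == pop)
                ]
                by_id = {u: gg for u, gg in g.groupby("unit_id")}
                for j, u in enumerate(draw):
                    gg = by_id[u].copy()
                    gg["unit_id"] = f"bs{j}:{u}"
                    parts.append(gg)
            resampled = pd.concat(parts, ignore_index=True)
        ds = build_dataset_from_units(resampled)
        fit = fit_global(
            ds,
            n_restarts=n_restarts_per_boot,
            seed=int(rng.integers(2**31 - 1)),
            weight_sem=weight_sem,
        )
        samples.append(fit)
    table = pd.DataFrame([s.as_series() for s in samples])
    rows = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        hist, edges = np.histogram(v, bins=min(30, max(5, len(v) // 2)))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        rows[col] = {
            "median": float(np.median(v)),
            "mode": float(mode),
            "p2.5": float(np.percentile(v, 2.5)),
            "p97.5": float(np.percentile(v, 97.5)),
        }
    return BootstrapResult(samples=samples, summary=pd.DataFrame(rows).T)


# --- time constants ----------------------------------------------------------


@dataclass(frozen=True)
class TauFitResult:
    """Time constants fitted from step-response dynamics."""

    taus: TimeConstants
    sse: float
    identifiable: bool


def fit_time_constants(
    params: TwoPopParams,
    trace_E: np.ndarray,
    trace_I: np.ndarray,
    dt: float,
    L: float,
    init: tuple[float, float] = (10.0, 10.0),
    t_on: float = 0.0,
) -> TauFitResult:
    """Fit (tau_E, tau_I) to step-response rate traces, connectivity fixed.

    The traces are assumed to start at the pre-step steady state (intensity
    0) and to follow a step to intensity ``L`` at time ``t_on`` (ms).
    Least squares from the fixed starting point (10, 10) ms, bounds
    tau > 0.5 ms. Traces with no dynamics (flat to within 1e-9) are flagged
    non-identifiable.
    """
    trace_E = np.asarray(trace_E, dtype=float)
    trace_I = np.asarray(trace_I, dtype=float)
    n = trace_E.size
    if trace_I.size != n:
        raise ValueError("E and I traces must have equal length")
    T = (n - 1) * dt
    flat = (np.ptp(trace_E) < 1e-9) and (np.ptp(trace_I) < 1e-9)
    if flat:
        warnings.warn("traces carry no dynamics; time constants not identifiable",
                      stacklevel=2)
        return TauFitResult(TimeConstants(*init), 0.0, identifiable=False)

    if 5.0 * max(init) > T:
        warnings.warn("traces shorter than 5x the initial tau candidates",
                      stacklevel=2)

    def L_of_t(t):
        return L if t >= t_on else 0.0

    init_state = fixed_point(params, 0.0).rates
    tg = np.arange(n) * dt

    def resid(x):
        taus = TimeConstants(x[0], x[1])
        step = max(min(dt, min(x) / 10.0), 1e-4)
        t, rE, rI, _ = simulate_dynamics(
            params, taus, L_of_t, dt=step, T=T, init=init_state
        )
        rEs = np.interp(tg, t, rE)
        rIs = np.interp(tg, t, rI)
        return np.concatenate([rEs - trace_E, rIs - trace_I])

    sol = least_squares(resid, np.asarray(init, float), bounds=(0.5, 1e4),
                        method="trf", xtol=1e-10, ftol=1e-10)
    return TauFitResult(
        taus=TimeConstants(float(sol.x[0]), float(sol.x[1])),
        sse=float(np.sum(sol.fun**2)),
        identifiable=True,
    )


# --- bookkeeping -------------------------------------------------------------


def count_free_parameters(
    equilibrium: bool = True,
    gains_pinned: bool = True,
    n_sessions: int = 1,
    blockers: bool = True,
    transfer: str = "rectified_linear",
) -> int:
    """Number of free model parameters for a given configuration.

    The full model has 15: 2 time constants, 2 thresholds, 2 gains, 4
    weights, 2 external inputs, 1 opsin efficacy, 2 blocker efficacies.
    Equilibrium fitting drops the time constants; pinning the gains at 1
    (allowed by the rescaling invariance) drops 2 more, leaving 11 in the
    canonical single-session three-phase setup.
    """
    n = 4 + 2 + 2 + 1  # weights, inputs, thresholds, opsin efficacy
    if blockers:
        n += 2 * n_sessions
    if not gains_pinned:
        n += 2
    if not equilibrium:
        n += 2
    if transfer == "softplus":
        n += 2
    return n
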