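"""Synthetic optogenetic experiments with the structure the pipeline assumes.

The generator emulates the experimental design the analysis chain was built
for: three pharmacological phases (intact, excitatory blockers, E+I
blockers), a grid of raw laser intensities presented in 600 ms pulses with
100 repetitions per level, steady-state spike counts over the last 300 ms,
an ~80/20 E/I unit mixture with distinct waveform-width distributions, a
per-session laser scale (the true L0) and per-session blocker efficacies.

Population mean rates come from the rate-model fixed points (with blocker
transforms applied per phase); each unit's expected rate is the population
rate times a log-normal heterogeneity multiplier, and trial counts are
Poisson around expected count (optionally overdispersed via a gamma
mixture). A ground-truth sidecar records every latent quantity so
round-trip tests can score the pipeline against what was actually
generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rate_model import (
    BlockerEfficacy,
    Phase,
    TimeConstants,
    TransferFunctionSpec,
    TwoPopParams,
    apply_blockers,
    fixed_point_curve,
    simulate_dynamics,
)
from .pipeline import UnitRecord

__all__ = ["GeneratorConfig", "v1_best_fit_params", "generate_dataset",
           "generate_dynamics", "unit_rate_table"]


def v1_best_fit_params(lam: float = 6.3) -> TwoPopParams:
    """A moderately coupled ISN operating point used as the default truth.

    Weights and inputs are the published best-fit values for mouse V1 under
    whole-population inhibitory stimulation (W_EE = 2.56, W_EI = 1.77,
    W_IE = 8.54, W_II = 7.11, I_EX = 8.51, I_IX = 34.16 spk/s, thresholds
    1.19 / 8.65 spk/s, opsin efficacy 6.3 spk/s per normalized intensity
    unit, gains 1).
    """
    return TwoPopParams(
        W_EE=2.56, W_EI=1.77, W_IE=8.54, W_II=7.11,
        I_EX=8.51, I_IX=34.16, lam=lam,
        tf_E=TransferFunctionSpec(a=1.0, x0=1.19),
        tf_I=TransferFunctionSpec(a=1.0, x0=8.65),
    )


@dataclass
class GeneratorConfig:
    """Study-design parameters of a synthetic experiment.

    Defaults mirror the emulated experiments: 100 trials per intensity,
    600 ms pulses with a 300 ms steady-state window, ~80% excitatory units,
    waveform widths 0.58 ms (E) vs 0.46 ms (I), per-session laser scale
    L0 in the low-mW range, log-normal rate heterogeneity sigma 0.5.
    """

    truth: TwoPopParams = field(default_factory=v1_best_fit_params)
    taus: TimeConstants = field(default_factory=lambda: TimeConstants(7.8, 34.3))
    n_sessions: int = 2
    units_per_session: int = 30
    frac_E: float = 0.8
    laser_grid_mW: tuple = (0.0, 0.3, 0.6, 1.0, 1.5, 2.1, 2.8, 3.6)
    session_L0_mW: tuple | None = None  # default: evenly spread in [0.8, 1.6]
    trials_per_level: int = 100
    pulse_ms: float = 600.0
    steady_window_ms: float = 300.0
    rate_sigma: float = 0.5  # log-normal unit-heterogeneity sd (log scale)
    eps_E: float = 0.3
    eps_I: float = 0.3
    eps_jitter: float = 0.0  # sd of per-session efficacy jitter
    width_mean_E: float = 0.58
    width_mean_I: float = 0.46
    width_sd: float = 0.05
    overdispersion: float = 0.0  # 0 = pure Poisson
    phases: tuple = (Phase.INTACT, Phase.E_BLOCKED, Phase.EI_BLOCKED)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.frac_E < 1.0:
            raise ValueError("frac_E must lie in (0, 1)")
        if self.trials_per_level <= 0 or self.units_per_session <= 0:
            raise ValueError("counts must be positive")
        if self.session_L0_mW is None:
            self.session_L0_mW = tuple(
                np.linspace(0.8, 1.6, self.n_sessions)
            )
        if len(self.session_L0_mW) != self.n_sessions:
            raise ValueError("session_L0_mW must have one entry per session")


def _session_eps(cfg: GeneratorConfig, rng: np.random.Generator) -> BlockerEfficacy:
    if cfg.eps_jitter == 0:
        return BlockerEfficacy(cfg.eps_E, cfg.eps_I)
    return BlockerEfficacy(
        float(np.clip(cfg.eps_E + rng.normal(0, cfg.eps_jitter), 0.0, 1.0)),
        float(np.clip(cfg.eps_I + rng.normal(0, cfg.eps_jitter), 0.0, 1.0)),
    )


def _draw_counts(rng, expected, size, overdispersion):
    """Poisson counts, optionally gamma-mixed for overdispersion."""
    if overdispersion <= 0:
        return rng.poisson(expected, size=size)
    shape = 1.0 / overdispersion
    lam = rng.gamma(shape, expected / shape, size=size)
    return rng.poisson(lam)


def generate_dataset(cfg: GeneratorConfig) -> tuple[list[UnitRecord], dict]:
    """Generate unit records plus a ground-truth sidecar.

    Returns ``(units, truth)`` where ``truth`` records per-session blocker
    efficacies and L0, per-unit population labels and rate multipliers, and
    the generator parameters. The output is fully determined by
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    window_s = cfg.steady_window_ms / 1000.0
    units: list[UnitRecord] = []
    truth: dict = {
        "params": cfg.truth,
        "sessions": {},
        "units": {},
        "config": cfg,
    }
    grid = np.asarray(cfg.laser_grid_mW, dtype=float)
    for s in range(cfg.n_sessions):
        sess = f"s{s}"
        L0 = float(cfg.session_L0_mW[s])
        eps = _session_eps(cfg, rng)
        Ln = grid / L0  # normalized intensities seen by the model
        pop_rates = {}
        for phase in cfg.phases:
            p = apply_blockers(cfg.truth, phase, eps)
            r_E, r_I, _ = fixed_point_curve(p, Ln)
            if (r_E < 0).any() or (r_I < 0).any():
                raise ValueError("configuration implies negative rates")
            pop_rates[Phase(phase).value] = {"E": r_E, "I": r_I}
        truth["sessions"][sess] = {"eps": eps, "L0_mW": L0}
        n_I = max(int(round(cfg.units_per_session * (1 - cfg.frac_E))), 1)
        labels = ["I"] * n_I + ["E"] * (cfg.units_per_session - n_I)
        rng.shuffle(labels)
        for u in range(cfg.units_per_session):
            label = labels[u]
            mult = float(rng.lognormal(mean=-cfg.rate_sigma**2 / 2.0,
                                       sigma=cfg.rate_sigma))
            width = float(
                rng.normal(
                    cfg.width_mean_E if label == "E" else cfg.width_mean_I,
                    cfg.width_sd,
                )
            )
            rows = []
            for phase in cfg.phases:
                pv = Phase(phase).value
                rates = pop_rates[pv][label] * mult
                for j, las in enumerate(grid):
                    expected = rates[j] * window_s
                    counts = _draw_counts(
                        rng, expected, cfg.trials_per_level, cfg.overdispersion
                    )
                    rows.append(
                        pd.DataFrame(
                            {
                                "phase": pv,
                                "laser_mW": las,
                                "trial": np.arange(cfg.trials_per_level),
                                "count": counts,
                            }
                        )
                    )
            uid = f"{sess}_u{u}"
            units.append(
                UnitRecord(
                    unit_id=uid,
                    session_id=sess,
                    counts=pd.concat(rows, ignore_index=True),
                    window_s=window_s,
                    depth_um=float(rng.uniform(100, 400)),
                    waveform_width_ms=max(width, 0.05),
                )
            )
            truth["units"][uid] = {"label": label, "multiplier": mult}
    return units, truth


def unit_rate_table(units: list[UnitRecord], truth: dict) -> pd.DataFrame:
    """Unit-level mean dose-response rows (for bootstrap resampling).

    Columns: session, unit_id, population (ground-truth label), phase,
    intensity (normalized by the session's true L0), rate.
    """
    rows = []
    for u in units:
        label = truth["units"][u.unit_id]["label"]
        L0 = truth["sessions"][u.session_id]["L0_mW"]
        for phase in sorted(u.phases()):
            mr = u.mean_rates(phase)
            for las, rate in mr.items():
                rows.append(
                    {
                        "session": u.session_id,
                        "unit_id": u.unit_id,
                        "population": label,
                        "phase": phase,
                        "intensity": las / L0,
                        "rate": rate,
                    }
                )
    return pd.DataFrame(rows)


def generate_dynamics(
    cfg: GeneratorConfig,
    L_level: float = 2.6,
    bin_ms: float = 1.0,
    pre_ms: float = 100.0,
    pulse_ms: float | None = None,
    n_trials: int | None = None,
    onset_artifact: bool = False,
    population: str = "I",
) -> pd.DataFrame:
    """Per-trial binned spike counts around a step pulse (PSTH table).

    Simulates the population rate response to a step from 0 to ``L_level``
    (normalized units; the emulated transient protocol uses 2.6) and draws
    Poisson counts per 1 ms bin and trial for one representative unit of
    the requested population. ``onset_artifact=True`` deletes the spikes in
    the onset bin, exercising the artifact-drop logic downstream.

    Returns a DataFrame with columns time_ms, trial, count and attrs
    ``rate`` (the noiseless rate trace) and ``onset_ms``.
    """
    import warnings

    if bin_ms > cfg.taus.tau_E:
        warnings.warn("bin larger than tau_E: transient will be under-resolved",
                      stacklevel=2)
    pulse = cfg.pulse_ms if pulse_ms is None else pulse_ms
    trials = cfg.trials_per_level if n_trials is None else n_trials
    rng = np.random.default_rng(cfg.seed + 1)
    dt = min(cfg.taus.tau_E, cfg.taus.tau_I) / 20.0
    T = pre_ms + pulse

    def L_of_t(t):
        return L_level if t >= pre_ms else 0.0

    t, rE, rI, _ = simulate_dynamics(cfg.truth, cfg.taus, L_of_t, dt=dt, T=T)
    edges = np.arange(0.0, T + bin_ms, bin_ms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    trace = rE if population == "E" else rI
    rate = np.interp(centers, t, trace)
    expected = rate * bin_ms / 1000.0
    counts = rng.poisson(expected, size=(trials, expected.size))
    if onset_artifact:
        k_on = int(round(pre_ms / bin_ms))
        counts[:, k_on] = 0
    df = pd.DataFrame(
        {
            "time_ms": np.tile(centers, trials),
            "trial": np.repeat(np.arange(trials), centers.size),
            "count": counts.ravel(),
        }
    )
    df.attrs["rate"] = rate
    df.attrs["onset_ms"] = pre_ms
    df.attrs["bin_ms"] = bin_ms
    return df
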