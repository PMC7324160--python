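"""Unit-level analysis of optogenetic dose-response recordings.

This module implements the processing chain applied to recorded (or
synthetic) units:

* E/I classification by three methods — response under synaptic blockade
  (pharmacology), response at maximum laser power, and spike waveform
  width (bimodal kernel-density split);
* per-session laser normalization: the intensity L0 at the minimum of the
  average inhibitory dose-response, located by fitting a continuous
  two-segment piecewise-linear function, maps to 1 on the normalized scale;
* initial-slope statistics of each unit's dose-response over the
  sub-minimum range, raw and normalized by (baseline + 0.1 spk/s);
* population averaging with the SEM computed on summed counts;
* detection of the brief inhibitory transient after stimulus onset
  (1-12 ms window, onset artifact bin dropped, two-sample KS test);
* decomposition of the current into excitatory cells predicted by a fitted
  model into excitatory, inhibitory and net components.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rate_model import Phase, TwoPopParams, fixed_point

__all__ = [
    "UnitRecord",
    "ClassificationResult",
    "SessionNormalization",
    "SlopeEstimate",
    "TransientResult",
    "classify_pharma",
    "classify_high_power",
    "classify_width",
    "find_L0",
    "initial_slope",
    "population_average",
    "detect_transient",
    "currents_into_E",
    "depth_stratum",
]

SLOPE_REGULARIZER = 0.1  # spk/s added to baseline when normalizing slopes


@dataclass
class UnitRecord:
    """One unit's per-phase, per-intensity, per-trial spike counts.

    ``counts`` is a long-format DataFrame with columns phase, laser_mW,
    trial, count; ``window_s`` is the steady-state counting window (s).
    """

    unit_id: str
    session_id: str
    counts: pd.DataFrame
    window_s: float = 0.3
    depth_um: float = 0.0
    waveform_width_ms: float = float("nan")
    psth: pd.DataFrame | None = None  # columns: phase, laser, time_ms, count

    def __post_init__(self) -> None:
        req = {"phase", "laser_mW", "trial", "count"}
        missing = req - set(self.counts.columns)
        if missing:
            raise ValueError(f"unit {self.unit_id}: counts missing {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValueError(f"unit {self.unit_id}: negative spike counts")
        if not self.window_s > 0:
            raise ValueError("window_s must be positive")

    def phases(self) -> set[str]:
        return set(self.counts["phase"].unique())

    def trial_rates(self, phase: Phase | str, laser_mW: float) -> np.ndarray:
        """Per-trial steady-state rates (spk/s) at one intensity."""
        phase = Phase(phase).value
        m = (self.counts["phase"] == phase) & np.isclose(
            self.counts["laser_mW"], laser_mW
        )
        return self.counts.loc[m, "count"].to_numpy(dtype=float) / self.window_s

    def intensities(self, phase: Phase | str) -> np.ndarray:
        phase = Phase(phase).value
        vals = self.counts.loc[self.counts["phase"] == phase, "laser_mW"].unique()
        return np.sort(vals)

    def mean_rates(self, phase: Phase | str) -> pd.Series:
        """Mean steady-state rate (spk/s) per intensity, index = laser_mW."""
        phase = Phase(phase).value
        g = self.counts[self.counts["phase"] == phase]
        return g.groupby("laser_mW")["count"].mean() / self.window_s


class Label(str, enum.Enum):
    E = "E"
    I = "I"  # noqa: E741


@dataclass(frozen=True)
class ClassificationResult:
    label: str  # 'E' | 'I'
    method: str  # 'pharma' | 'high_power' | 'width'
    p_value: float = float("nan")
    effect: float = float("nan")  # rate change, spk/s (or width margin, ms)


def _welch_positive_change(baseline: np.ndarray, driven: np.ndarray, alpha: float):
    """Two-sided Welch t-test with a separate positive-sign requirement."""
    effect = float(np.mean(driven) - np.mean(baseline))
    if np.ptp(baseline) == 0 and np.ptp(driven) == 0:
        p = 1.0 if effect == 0 else 0.0
    else:
        p = float(stats.ttest_ind(driven, baseline, equal_var=False).pvalue)
    is_positive = effect > 0 and p < alpha
    return is_positive, p, effect


def _classify_by_drive(unit: UnitRecord, phase: Phase, method: str, alpha: float):
    if phase.value not in unit.phases():
        raise ValueError(
            f"unit {unit.unit_id}: phase {phase.value!r} unavailable for "
            f"{method} classification"
        )
    lasers = unit.intensities(phase)
    base = unit.trial_rates(phase, lasers[0])
    top = unit.trial_rates(phase, lasers[-1])
    if lasers[0] != 0:
        warnings.warn(f"unit {unit.unit_id}: lowest intensity is {lasers[0]}, "
                      "treating it as baseline", stacklevel=3)
    pos, p, effect = _welch_positive_change(base, top, alpha)
    return ClassificationResult(
        label=Label.I.value if pos else Label.E.value,
        method=method, p_value=p, effect=effect,
    )


def classify_pharma(unit: UnitRecord, alpha: float = 0.01) -> ClassificationResult:
    """E/I label from the response under E+I synaptic blockade.

    With recurrent synapses blocked, only opsin-expressing (inhibitory)
    cells respond to light. The unit is labeled I iff its rate change from
    baseline to maximum intensity in the blocker phase is positive and
    significant (Welch's unequal-variance t-test, p < alpha); E otherwise.
    """
    return _classify_by_drive(unit, Phase.EI_BLOCKED, "pharma", alpha)


def classify_high_power(unit: UnitRecord, alpha: float = 0.01) -> ClassificationResult:
    """E/I label from the intact-phase response at maximum laser power.

    In an ISN driven past the excitatory-silencing point, inhibitory rates
    rise above baseline at high intensity while excitatory cells are
    suppressed. Same test as :func:`classify_pharma`, on the intact phase.
    Known to miss inhibitory units that stay suppressed at every measured
    intensity (a stringent, conservative rule).
    """
    return _classify_by_drive(unit, Phase.INTACT, "high_power", alpha)


def classify_width(
    units: list[UnitRecord], bandwidth: float | None = None, grid_n: int = 512
) -> tuple[list[ClassificationResult], float]:
    """E/I labels from the bimodal waveform-width distribution.

    Fits a Gaussian kernel density to the widths, locates the minimum
    between the two dominant modes, and labels units narrower than the
    threshold I (fast-spiking) and wider ones E. Requires at least 20
    units and a genuinely bimodal density.
    """
    widths = np.asarray([u.waveform_width_ms for u in units], dtype=float)
    if widths.size < 20:
        raise ValueError("need >= 20 units for a stable density fit")
    if not np.all(np.isfinite(widths)):
        raise ValueError("non-finite waveform widths")
    if np.ptp(widths) == 0:
        raise ValueError("width distribution is degenerate (all identical)")
    kde = stats.gaussian_kde(widths, bw_method=0.25 if bandwidth is None
                             else bandwidth)
    grid = np.linspace(widths.min(), widths.max(), grid_n)
    dens = kde(grid)
    # dominant modes only: prominence filter suppresses tail wiggles
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(dens, prominence=0.02 * dens.max())
    if peaks.size < 2:
        raise ValueError("width density is unimodal; cannot split E/I by width")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top2)
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    threshold = float(grid[valley])
    results = [
        ClassificationResult(
            label=Label.I.value if w < threshold else Label.E.value,
            method="width", effect=float(w - threshold),
        )
        for w in widths
    ]
    return results, threshold


@dataclass(frozen=True)
class SessionNormalization:
    """Per-session laser normalization from the inhibitory-response minimum.

    ``L0_mW`` is the breakpoint of the continuous two-segment
    piecewise-linear fit to the average inhibitory dose-response; dividing
    raw intensities by L0 maps the minimum to 1. ``paradoxical`` is False
    when the first-segment slope is non-negative (no suppression; L0
    undefined, set to NaN).
    """

    L0_mW: float
    intercept: float
    slope_low: float
    slope_high: float
    sse: float
    paradoxical: bool

    def normalize(self, laser_mW) -> np.ndarray:
        if not self.paradoxical:
            raise ValueError("L0 undefined: no paradoxical minimum in this session")
        return np.asarray(laser_mW, dtype=float) / self.L0_mW


def _pwl_fit_at(b: float, L: np.ndarray, r: np.ndarray):
    X = np.column_stack(
        [np.ones_like(L), np.minimum(L - b, 0.0), np.maximum(L - b, 0.0)]
    )
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    sse = float(np.sum((X @ coef - r) ** 2))
    return coef, sse


def find_L0(mean_I_response, grid_n: int = 200) -> SessionNormalization:
    """Locate the inhibitory-response minimum by piecewise-linear fitting.

    ``mean_I_response``: sequence of (laser_mW, rate) pairs, >= 4 levels.
    A continuous two-segment linear function with a free breakpoint is fit
    by least squares (breakpoint on a fine grid over the interior of the
    intensity range, then golden-section refinement); the breakpoint is L0.
    """
    arr = np.asarray(list(mean_I_response), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise ValueError("need >= 4 (laser, rate) pairs")
    L, r = arr[:, 0], arr[:, 1]
    order = np.argsort(L)
    L, r = L[order], r[order]
    lo, hi = L[1], L[-2]
    if hi <= lo:
        lo, hi = L[0] + 1e-9, L[-1] - 1e-9
    grid = np.linspace(lo, hi, grid_n)
    sses = np.array([_pwl_fit_at(b, L, r)[1] for b in grid])
    k = int(np.argmin(sses))
    # golden-section refinement in the bracketing cell
    a = grid[max(k - 1, 0)]
    c = grid[min(k + 1, grid_n - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: _pwl_fit_at(b, L, r)[1], bounds=(a, c), method="bounded"
    )
    b_opt = float(res.x)
    coef, sse = _pwl_fit_at(b_opt, L, r)
    intercept, s1, s2 = (float(v) for v in coef)
    paradoxical = s1 < 0
    return SessionNormalization(
        L0_mW=b_opt if paradoxical else float("nan"),
        intercept=intercept, slope_low=s1, slope_high=s2,
        sse=sse, paradoxical=paradoxical,
    )


@dataclass(frozen=True)
class SlopeEstimate:
    """Initial dose-response slope of one unit.

    ``raw_slope`` is in spk/s per normalized intensity unit;
    ``normalized_slope`` divides by (baseline + 0.1 spk/s), bounding the
    normalized slope below by about -1 over the [0, 1] range.
    """

    raw_slope: float
    normalized_slope: float
    baseline_rate: float
    n_points: int


def initial_slope(
    unit: UnitRecord,
    normalization: SessionNormalization,
    phase: Phase | str = Phase.INTACT,
) -> SlopeEstimate:
    """OLS slope of mean rate vs normalized intensity over [0, 1].

    Uses every intensity at or below L0 (normalized intensity <= 1, with a
    small tolerance for grid round-off); requires at least two such points.
    """
    rates = unit.mean_rates(phase)
    Ln = normalization.normalize(rates.index.to_numpy())
    mask = Ln <= 1.0 + 1e-9
    if mask.sum() < 2:
        raise ValueError(
            f"unit {unit.unit_id}: need >= 2 intensities at or below L0"
        )
    x = Ln[mask]
    y = rates.to_numpy()[mask]
    slope = float(np.polyfit(x, y, 1)[0])
    baseline = float(y[np.argmin(x)])
    return SlopeEstimate(
        raw_slope=slope,
        normalized_slope=slope / (baseline + SLOPE_REGULARIZER),
        baseline_rate=baseline,
        n_points=int(mask.sum()),
    )


def population_average(
    units: list[UnitRecord], phase: Phase | str = Phase.INTACT
) -> pd.DataFrame:
    """Population dose-response curve with summed-count SEM.

    The mean is the average over units of per-unit mean rates. The SEM at
    each intensity is computed on the summed spike counts across units per
    trial (population-level counting noise), converted back to spk/s per
    unit: sem(sum_counts over trials) / (n_units * window).
    """
    if not units:
        raise ValueError("need at least one unit")
    phase = Phase(phase).value
    lasers = sorted(
        set().union(*[set(u.intensities(phase)) for u in units])
    )
    rows = []
    for las in lasers:
        per_unit_means = []
        summed = None
        for u in units:
            tr = u.trial_rates(phase, las) * u.window_s  # back to counts
            if tr.size == 0:
                continue
            per_unit_means.append(tr.mean() / u.window_s)
            if summed is None:
                summed = tr.copy()
            elif tr.size == summed.size:
                summed = summed + tr
        n = len(per_unit_means)
        window = units[0].window_s
        sem = (
            float(np.std(summed, ddof=1) / np.sqrt(summed.size)) / (n * window)
            if summed is not None and summed.size > 1
            else float("nan")
        )
        rows.append(
            {"intensity": las, "mean_rate": float(np.mean(per_unit_means)),
             "sem": sem, "n_units": n}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransientResult:
    """Brief inhibitory rate increase after stimulus onset.

    Measured on the 1-12 ms post-onset window with the t = 0 artifact bin
    dropped; significance by two-sample KS test against a matched-duration
    pre-onset window, with the positive-mean requirement applied
    separately. Normalized quantities are (rate - baseline)/baseline.
    """

    significant: bool
    p_value: float
    peak_amplitude: float  # spk/s above baseline
    latency_to_peak_ms: float
    fwhm_ms: float
    crossing_time_ms: float  # first post-peak return to baseline
    normalized_transient: float
    normalized_steady_state: float
    baseline_rate: float


def _fwhm(t: np.ndarray, y: np.ndarray, half: float) -> float:
    """Full width of y(t) at the level ``half`` around its maximum."""
    k = int(np.argmax(y))
    left = t[0]
    for i in range(k, 0, -1):
        if y[i - 1] <= half:
            left = np.interp(half, [y[i - 1], y[i]], [t[i - 1], t[i]])
            break
    right = t[-1]
    for i in range(k, len(y) - 1):
        if y[i + 1] <= half:
            right = np.interp(half, [y[i + 1], y[i]], [t[i + 1], t[i]])
            break
    return float(right - left)


def detect_transient(
    rate_trace: np.ndarray,
    onset_ms: float,
    bin_ms: float = 1.0,
    window: tuple[float, float] = (1.0, 12.0),
    alpha: float = 0.01,
    smooth_ms: float = 3.0,
    steady_window_ms: float = 300.0,
    drop_onset_bin: bool = True,
) -> TransientResult:
    """Detect the onset transient in a trial-averaged PSTH (1 ms bins).

    ``rate_trace`` is the rate (spk/s) per bin; ``onset_ms`` the pulse
    onset relative to the start of the trace. Requires at least a 12 ms
    pre-onset baseline. The onset bin itself carries a stimulation
    artifact and is excluded from all statistics.
    """
    y = np.asarray(rate_trace, dtype=float)
    k_on = int(round(onset_ms / bin_ms))
    n_win = int(round((window[1] - window[0]) / bin_ms)) + 1
    if k_on < n_win:
        raise ValueError("insufficient pre-pulse baseline (need >= 12 ms)")
    pre = y[k_on - n_win : k_on]
    k0 = k_on + int(round(window[0] / bin_ms))
    post = y[k0 : k0 + n_win]
    if drop_onset_bin:
        pass  # post starts at 1 ms, onset bin already excluded
    baseline = float(np.mean(pre))
    ks = stats.ks_2samp(post, pre)
    significant = bool(ks.pvalue < alpha and np.mean(post) > baseline)

    # smoothed trace for peak geometry
    w = max(int(round(smooth_ms / bin_ms)), 1)
    kern = np.ones(w) / w
    ys = np.convolve(y, kern, mode="same")
    t_post = (np.arange(k0, min(k0 + 3 * n_win, len(y))) - k_on) * bin_ms
    y_post = ys[k0 : k0 + t_post.size] - baseline
    in_win = t_post <= window[1]
    k_peak = int(np.argmax(y_post[in_win]))
    peak = float(y_post[in_win][k_peak])
    latency = float(t_post[in_win][k_peak])
    fwhm = _fwhm(t_post, y_post, peak / 2.0) if peak > 0 else float("nan")
    # first crossing below baseline after the peak
    crossing = float("nan")
    for i in range(k_peak, t_post.size - 1):
        if y_post[i] > 0 >= y_post[i + 1]:
            crossing = float(
                np.interp(0.0, [y_post[i + 1], y_post[i]], [t_post[i + 1], t_post[i]])
            )
            break
    n_ss = int(round(steady_window_ms / bin_ms))
    steady = float(np.mean(y[max(len(y) - n_ss, k0):]))
    mean_trans = float(np.mean(y[k0 : k0 + n_win]))
    denom = baseline if baseline > 0 else float("nan")
    return TransientResult(
        significant=significant,
        p_value=float(ks.pvalue),
        peak_amplitude=peak,
        latency_to_peak_ms=latency,
        fwhm_ms=fwhm,
        crossing_time_ms=crossing,
        normalized_transient=(mean_trans - baseline) / denom,
        normalized_steady_state=(steady - baseline) / denom,
        baseline_rate=baseline,
    )


def currents_into_E(params: TwoPopParams, L: float) -> dict:
    """Excitatory, inhibitory and net current into E cells, threshold units.

    At an interior fixed point with unit gain the identity
    net = (r_E + x0_E)/x0_E holds. If x0_E = 0 the threshold-unit
    normalization is undefined and raw currents (spk/s-equivalent) are
    returned with ``units='raw'``.
    """
    fp = fixed_point(params, L)
    E_raw = params.W_EE * fp.r_E + params.I_EX
    I_raw = -params.W_EI * fp.r_I
    x0 = params.tf_E.x0
    if x0 == 0:
        return {"E": E_raw, "I": I_raw, "net": E_raw + I_raw, "units": "raw",
                "branch": fp.branch}
    return {
        "E": E_raw / x0,
        "I": I_raw / x0,
        "net": (E_raw + I_raw) / x0,
        "units": "threshold",
        "branch": fp.branch,
    }


def depth_stratum(depth_um: float) -> str | None:
    """Superficial (<= 400 um) vs deep (>= 500 um); None in between."""
    if depth_um <= 400:
        return "superficial"
    if depth_um >= 500:
        return "deep"
    return None
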