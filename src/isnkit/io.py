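"""CSV/JSON readers and writers and the end-to-end pipeline driver.

Interchange formats are plain text: long-format unit-trial CSV tables
(session, unit_id, phase, laser_mW, trial, spike_count, window_s, and
optional depth_um, width_ms), flat JSON parameter files, and a JSON run
manifest (config + seed + package version) written next to every output
bundle so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import build_dataset_from_units, fit_global
from .pipeline import (
    UnitRecord,
    classify_high_power,
    classify_pharma,
    find_L0,
    initial_slope,
    population_average,
)
from .rate_model import Phase
from .stability import is_isn, stability_boundary_ratio
from .synth import GeneratorConfig, generate_dataset, unit_rate_table

__all__ = ["read_unit_table", "write_unit_table", "write_manifest", "run_pipeline"]

_REQUIRED_COLS = ("session", "unit_id", "phase", "laser_mW", "trial",
                  "spike_count", "window_s")


def read_unit_table(path) -> list[UnitRecord]:
    """Read a long-format unit-trial CSV into unit records.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers. An empty file yields an empty list with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        warnings.warn(f"{path}: empty unit table", stacklevel=2)
        return []
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[df["spike_count"] < 0]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValueError(
            f"{path}: negative spike_count at line(s) {lines}"
            + ("..." if len(bad) > 5 else "")
        )
    try:
        df["phase"] = df["phase"].map(lambda s: Phase(s).value)
    except ValueError as e:
        raise ValueError(f"{path}: unknown phase label ({e})") from None
    units = []
    for (sess, uid), g in df.groupby(["session", "unit_id"], sort=True):
        counts = g.rename(columns={"spike_count": "count"})[
            ["phase", "laser_mW", "trial", "count"]
        ].reset_index(drop=True)
        units.append(
            UnitRecord(
                unit_id=str(uid),
                session_id=str(sess),
                counts=counts,
                window_s=float(g["window_s"].iloc[0]),
                depth_um=float(g["depth_um"].iloc[0]) if "depth_um" in g else 0.0,
                waveform_width_ms=float(g["width_ms"].iloc[0])
                if "width_ms" in g
                else float("nan"),
            )
        )
    return units


def write_unit_table(units: list[UnitRecord], path) -> None:
    """Write unit records to the long-format CSV read by read_unit_table."""
    frames = []
    for u in units:
        f = u.counts.rename(columns={"count": "spike_count"}).copy()
        f.insert(0, "session", u.session_id)
        f.insert(1, "unit_id", u.unit_id)
        f["window_s"] = u.window_s
        f["depth_um"] = u.depth_um
        f["width_ms"] = u.waveform_width_ms
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_manifest(out_dir, command: str, config: dict, seed) -> Path:
    """Write the reproducibility manifest for one run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config": {k: _jsonable(v) for k, v in config.items()},
        "isnkit_version": __version__,
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2) + "\n")
    return p


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    return repr(v)


def run_pipeline(
    config: GeneratorConfig,
    out_dir=None,
    n_restarts: int = 60,
    do_fit: bool = True,
) -> dict:
    """Generate -> classify -> normalize -> slopes -> fit -> stability.

    Runs the full analysis chain on a synthetic experiment and returns a
    report dict (also written as JSON/CSVs when ``out_dir`` is given).
    Every stage error is re-raised with the stage name prepended.
    """
    report: dict = {"seed": config.seed}

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    units, truth = stage("generate", lambda: generate_dataset(config))
    report["n_units"] = len(units)

    # pharmacology-based classification when the blocker phase exists,
    # otherwise fall back to the high-power rule on the intact phase
    have_blockers = Phase.EI_BLOCKED in config.phases
    classifier = classify_pharma if have_blockers else classify_high_power
    cls = stage("classify", lambda: {u.unit_id: classifier(u) for u in units})
    i_units = [u for u in units if cls[u.unit_id].label == "I"]
    e_units = [u for u in units if cls[u.unit_id].label == "E"]
    report["n_classified_I"] = len(i_units)
    report["n_classified_E"] = len(e_units)

    def normalize():
        norms = {}
        for sess in truth["sessions"]:
            sess_I = [u for u in i_units if u.session_id == sess]
            if not sess_I:
                continue
            curve = population_average(sess_I, Phase.INTACT)
            norms[sess] = find_L0(curve[["intensity", "mean_rate"]].to_numpy())
        return norms

    norms = stage("normalize", normalize)
    report["L0_mW"] = {s: n.L0_mW for s, n in norms.items()}

    def slopes():
        out = []
        for u in units:
            n = norms.get(u.session_id)
            if n is None or not n.paradoxical:
                continue
            try:
                est = initial_slope(u, n)
            except ValueError:
                continue
            out.append(
                {
                    "unit_id": u.unit_id,
                    "label": cls[u.unit_id].label,
                    "raw_slope": est.raw_slope,
                    "normalized_slope": est.normalized_slope,
                    "baseline_rate": est.baseline_rate,
                }
            )
        return pd.DataFrame(out)

    slope_df = stage("slopes", slopes)
    if len(slope_df):
        for lab in ("E", "I"):
            sub = slope_df[slope_df["label"] == lab]["normalized_slope"]
            if len(sub):
                report[f"mean_norm_slope_{lab}"] = float(sub.mean())
                report[f"median_norm_slope_{lab}"] = float(sub.median())

    if do_fit:
        if len(config.phases) < 3:
            report["fit"] = None
            report["identifiability_note"] = (
                "fewer than three phases: parameters identifiable only up to "
                "the two-parameter rescaling family; skipping the global fit"
            )
        else:
            def fit():
                table = unit_rate_table(units, truth)
                # use the pipeline's classified labels, not ground truth
                lbl = {u: c.label for u, c in cls.items()}
                table["population"] = table["unit_id"].map(lbl)
                ds = build_dataset_from_units(table)
                return fit_global(ds, n_restarts=n_restarts, seed=config.seed)

            fitres = stage("fit", fit)
            report["fit"] = {
                k: float(v) for k, v in fitres.as_series().items()
            }
            report["isn"] = bool(is_isn(fitres.params))
            try:
                report["stability_boundary_ratio"] = float(
                    stability_boundary_ratio(fitres.params)
                )
            except ValueError as e:
                report["stability_boundary_ratio"] = None
                report["stability_note"] = str(e)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_unit_table(units, out_dir / "units.csv")
        slope_df.to_csv(out_dir / "slopes.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2) + "\n"
        )
    return report
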