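"""CSV and structured-report input/output.

All tabular files are comma-separated, dot-decimal, UTF-8, with a
mandatory header. Structured results are JSON with a schema version
field so downstream consumers can detect format changes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import DoseResponseRecord, FitResult, SurvivalDataset
from .toxicity import TOXICITY_COLUMNS, CFUToxicityTable, GrowthCurve

SCHEMA_VERSION = "1"

SURVIVAL_HEADER = ("dose_kGy", "survival")  # optional: sd, n


def load_survival_csv(path, label: str | None = None, **kw) -> SurvivalDataset:
    """Read a dose-response table: ``dose_kGy,survival[,sd,n]``.

    Malformed rows raise with the offending line number; survival
    outside (0, 1] raises a validation error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(SURVIVAL_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(
                DoseResponseRecord(
                    dose=float(row["dose_kGy"]),
                    survival=float(row["survival"]),
                    replicate_sd=float(row["sd"]) if "sd" in df.columns and pd.notna(row["sd"]) else None,
                    n_replicates=int(row["n"]) if "n" in df.columns and pd.notna(row["n"]) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return SurvivalDataset(records=tuple(records), label=label or path.stem, **kw)


def write_survival_csv(dataset: SurvivalDataset, path) -> None:
    rows = []
    for r in dataset.records:
        row = {"dose_kGy": r.dose, "survival": r.survival}
        if r.replicate_sd is not None:
            row["sd"] = r.replicate_sd
        if r.n_replicates is not None:
            row["n"] = r.n_replicates
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_growth_csv(path) -> GrowthCurve:
    """Read a growth curve: ``time_min,od600``."""
    df = pd.read_csv(path)
    missing = {"time_min", "od600"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return GrowthCurve(times=df["time_min"].to_numpy(float), od600=df["od600"].to_numpy(float))


def load_toxicity_csv(path) -> CFUToxicityTable:
    """Read a toxicity table: ``concentration,time_h,replicate,cfu_count``."""
    df = pd.read_csv(path)
    missing = set(TOXICITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return CFUToxicityTable(data=df)


def fit_result_to_dict(result: FitResult) -> dict:
    p = result.params
    return {
        "alpha": p.alpha,
        "beta": p.beta,
        "delta": p.delta,
        "n_units": p.n_units,
        "standard_errors": result.standard_errors,
        "adjusted_r_squared": result.adjusted_r_squared,
        "mode": result.mode,
        "asymptotic_threshold_kGy": result.threshold,
        "alpha_stage1": result.alpha_stage1,
        "converged": result.converged,
        "residual_sum_of_squares": result.residual_sum_of_squares,
        "at_bounds": list(result.at_bounds),
    }


def format_fit_report(result: FitResult, label: str = "") -> str:
    d = fit_result_to_dict(result)
    lines = [f"Survival-model fit{': ' + label if label else ''}"]
    for name in ("alpha", "beta", "delta"):
        se = d["standard_errors"].get(name)
        se_txt = f" +/- {se:.3g}" if se is not None and np.isfinite(se) else ""
        unit = " kGy^-1" if name in ("alpha", "delta") else ""
        lines.append(f"  {name:5s} = {d[name]:.4g}{se_txt}{unit}")
    lines.append(f"  n_units = {d['n_units']}")
    lines.append(f"  adj. R^2 = {d['adjusted_r_squared']:.4f}")
    lines.append(f"  mode = {d['mode']}, tail threshold = {d['asymptotic_threshold_kGy']:g} kGy")
    return "\n".join(lines)


def write_results_json(payload: dict, path) -> None:
    """Write a structured results file with the schema version stamped in."""
    out = {"schema_version": SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


def read_results_json(path) -> dict:
    return json.loads(Path(path).read_text())
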