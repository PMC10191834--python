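"""CSV schemas, packaged reference tables, and run logging helpers.

All CSVs are UTF-8, comma-separated, ``.`` decimal, header row mandatory.
Counts tables: ``label,dose,r0..rk``.  Results: ``label,lambda,ci_low,
ci_high,method,alpha,saturated,n_cells``.
"""

from __future__ import annotations

import hashlib
import json
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ColorCountTable, LambdaEstimate
from .quant import MEASUREMENT_COLUMNS

__all__ = [
    "load_reference_counts",
    "read_counts_csv",
    "read_measurements_csv",
    "write_counts_csv",
    "write_measurements_csv",
    "write_results_csv",
    "write_run_log",
]

RESULT_COLUMNS = ["label", "lambda", "ci_low", "ci_high", "method", "alpha", "saturated", "n_cells"]

#: Printed per-table lambda values of the embedded reference tables, for
#: side-by-side reproduction reports.  The "vitro" saturated row prints a
#: lower bound, the "lobule VI" row is internally inconsistent (class counts
#: sum to 4416 but the printed total is 4316).
REFERENCE_PRINTED = {
    "vitro": {"1e10": "7.9", "5e10": "12.4", "5e11": ">> 31"},
    "vivo": {"ACC": "19.2", "MC": "18.6", "PFC": "19.7", "SSC": "20.2", "VI": "19.0"},
}
REFERENCE_PRINTED_TOTALS = {"vivo": {"VI": 4316}}


def read_counts_csv(path: str | Path) -> list[ColorCountTable]:
    """Read a ``label,dose,r0..rk`` CSV into count tables (one per row)."""
    df = pd.read_csv(path, dtype={"label": str})
    r_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"r\d+", c)), key=lambda c: int(c[1:])
    )
    if not r_cols or [int(c[1:]) for c in r_cols] != list(range(len(r_cols))):
        raise ValueError(f"{path}: expected contiguous r0..rk count columns, got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: no count rows")
    tables = []
    for _, row in df.iterrows():
        dose = row.get("dose")
        dose = None if dose is None or pd.isna(dose) else float(dose)
        label = "" if "label" not in df.columns or pd.isna(row["label"]) else str(row["label"])
        tables.append(
            ColorCountTable(tuple(int(row[c]) for c in r_cols), label=label, dose=dose)
        )
    return tables


def write_counts_csv(tables: list[ColorCountTable], path: str | Path) -> None:
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("all tables must share k")
    rows = [
        {"label": t.label, "dose": t.dose, **{f"r{i}": c for i, c in enumerate(t.counts)}}
        for t in tables
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results_csv(results: list[tuple[str, LambdaEstimate]], path: str | Path) -> None:
    rows = []
    for label, est in results:
        rows.append(
            {
                "label": label,
                "lambda": est.lambda_hat if np.isfinite(est.lambda_hat) else "inf",
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "method": est.method,
                "alpha": est.alpha,
                "saturated": est.saturated,
                "n_cells": est.n_cells,
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing measurement columns {missing}")
    return df


def write_measurements_csv(measurements: pd.DataFrame, path: str | Path) -> None:
    measurements[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def load_reference_counts(which: str) -> list[ColorCountTable]:
    """Load a packaged reference counts table: ``"vitro"`` (dose series) or
    ``"vivo"`` (brain areas)."""
    if which not in ("vitro", "vivo"):
        raise ValueError("which must be 'vitro' or 'vivo'")
    ref = resources.files("cotrans.data") / f"{which}_counts.csv"
    with resources.as_file(ref) as path:
        return read_counts_csv(path)


def write_run_log(path: str | Path, config: dict) -> None:
    """Record the exact configuration (and its hash) that produced an output."""
    import cotrans

    payload = {
        "package_version": cotrans.__version__,
        "config": config,
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
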