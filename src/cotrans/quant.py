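"""Per-cell fluorescence correction, threshold calling, and tabulation.

Measurement tables are long-format pandas frames with columns
``cell_id, channel, integrated_density, roi_area, background_mean``; one row
per cell x channel.  The corrected value per channel is

    ctcf = integrated_density - roi_area * background_mean

which may be negative.  A channel is called *expressed* when its ctcf is
strictly above a per-channel threshold; thresholds are either fixed or
calibrated as mean + z * sd of negative-control ctcf values.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ColorCountTable

__all__ = [
    "DEFAULT_CHANNELS",
    "ThresholdPolicy",
    "calibrate_threshold",
    "classify_cell",
    "classify_cells",
    "ctcf",
    "ctcf_table",
    "mixture_fractions",
    "mixture_table",
    "round_percent",
    "tabulate_counts",
]

DEFAULT_CHANNELS: tuple[str, ...] = ("EGFP", "mCherry", "mTurq2")

MEASUREMENT_COLUMNS = [
    "cell_id",
    "channel",
    "integrated_density",
    "roi_area",
    "background_mean",
]


def ctcf(integrated_density, roi_area, background_mean):
    """Corrected total cell fluorescence: integrated density minus the
    ROI-area-scaled mean background. Vectorized; may return negative values."""
    integrated_density = np.asarray(integrated_density, dtype=float)
    roi_area = np.asarray(roi_area, dtype=float)
    background_mean = np.asarray(background_mean, dtype=float)
    if not (np.all(np.isfinite(integrated_density)) and np.all(np.isfinite(roi_area)) and np.all(np.isfinite(background_mean))):
        raise ValueError("ctcf inputs must be finite")
    if np.any(roi_area <= 0):
        raise ValueError("roi_area must be strictly positive")
    out = integrated_density - roi_area * background_mean
    return float(out) if out.ndim == 0 else out


def ctcf_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long measurement table into a cell x channel frame of ctcf values.

    Channel column order follows first appearance in the input.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    df = measurements.copy()
    df["ctcf"] = ctcf(
        df["integrated_density"].to_numpy(),
        df["roi_area"].to_numpy(),
        df["background_mean"].to_numpy(),
    )
    wide = df.pivot(index="cell_id", columns="channel", values="ctcf")
    if wide.isna().any().any():
        raise ValueError("every cell must have a measurement for every channel")
    channel_order = list(dict.fromkeys(df["channel"]))
    wide = wide[channel_order]
    wide.columns.name = None
    return wide


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-channel ctcf cutoffs; strictly-above means expressed."""

    thresholds: Mapping[str, float]
    provenance: str = "fixed"

    def __post_init__(self) -> None:
        thr = dict(self.thresholds)
        if not thr:
            raise ValueError("at least one channel threshold required")
        if not all(np.isfinite(v) for v in thr.values()):
            raise ValueError("thresholds must be finite")
        object.__setattr__(self, "thresholds", thr)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.thresholds)


def calibrate_threshold(
    negative_control_ctcf: Mapping[str, Sequence[float]], z: float = 3.0
) -> ThresholdPolicy:
    """Set threshold_c = mean_c + z * sd_c of negative-control ctcf (sample sd)."""
    if z < 0:
        raise ValueError("z must be >= 0")
    thresholds = {}
    for channel, values in negative_control_ctcf.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError(f"channel {channel!r}: need >= 2 control values")
        thresholds[channel] = float(values.mean() + z * values.std(ddof=1))
    return ThresholdPolicy(thresholds, provenance=f"z_score(z={z})")


def classify_cell(cell_ctcf: Mapping[str, float], policy: ThresholdPolicy) -> dict:
    """Call one cell: channel expressed iff ctcf strictly above its threshold."""
    if set(cell_ctcf) != set(policy.channels):
        raise ValueError(
            f"channel mismatch: cell has {sorted(cell_ctcf)}, policy covers {sorted(policy.channels)}"
        )
    flags = {ch: bool(cell_ctcf[ch] > policy.thresholds[ch]) for ch in policy.channels}
    return {**flags, "n_colors": sum(flags.values())}


def classify_cells(measurements: pd.DataFrame, policy: ThresholdPolicy) -> pd.DataFrame:
    """Call every cell in a long measurement table.

    Returns a frame indexed by cell_id with one boolean column per channel
    plus ``n_colors``.
    """
    wide = ctcf_table(measurements)
    if set(wide.columns) != set(policy.channels):
        raise ValueError(
            f"channel mismatch: table has {sorted(wide.columns)}, policy covers {sorted(policy.channels)}"
        )
    thr = np.array([policy.thresholds[ch] for ch in wide.columns])
    flags = wide.to_numpy() > thr
    calls = pd.DataFrame(flags, index=wide.index, columns=wide.columns)
    calls["n_colors"] = flags.sum(axis=1)
    return calls


def round_percent(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for printed percentages (Python rounds half-even)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def tabulate_counts(
    calls: pd.DataFrame | Iterable[int],
    label: str = "",
    dose: float | None = None,
    k: int | None = None,
) -> ColorCountTable:
    """Tabulate color calls into r_0..r_k class counts.

    ``calls`` is either a classify_cells frame (k inferred from its channel
    columns) or a plain iterable of per-cell color counts (k defaults to 3).
    """
    if isinstance(calls, pd.DataFrame):
        if calls.empty:
            raise ValueError("no calls to tabulate")
        n_colors = calls["n_colors"].to_numpy()
        if k is None:
            k = len(calls.columns) - 1
    else:
        n_colors = np.asarray(list(calls), dtype=int)
        if n_colors.size == 0:
            raise ValueError("no calls to tabulate")
        if k is None:
            k = 3
    counts = np.bincount(n_colors, minlength=k + 1)
    if len(counts) > k + 1:
        raise ValueError(f"call with more than k={k} colors present")
    return ColorCountTable(tuple(int(c) for c in counts), label=label, dose=dose)


def class_percentages(table: ColorCountTable, ndigits: int = 2) -> list[float]:
    """Per-class percentages at fixed decimals, half-up, as printed in reports."""
    n = table.n_cells
    return [round_percent(100.0 * r / n, ndigits) for r in table.counts]


def mixture_fractions(cell_ctcf: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Per-channel fraction of total positive ctcf (negatives clamped to 0)."""
    values = np.asarray(
        list(cell_ctcf.values()) if isinstance(cell_ctcf, Mapping) else cell_ctcf,
        dtype=float,
    )
    clamped = np.clip(values, 0.0, None)
    total = clamped.sum()
    if total <= 0:
        raise ValueError("undefined composition: no channel with positive ctcf")
    return clamped / total


def mixture_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Compositions for every cell with at least one positive-ctcf channel.

    Cells whose channels are all <= 0 after clamping are silently dropped
    (they cannot be placed on the simplex).
    """
    wide = ctcf_table(measurements)
    clamped = wide.clip(lower=0.0)
    total = clamped.sum(axis=1)
    keep = total > 0
    return clamped.loc[keep].div(total[keep], axis=0)
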