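"""Cohort summaries of per-subject, per-compartment lipid-peak statistics.

Each subject contributes one (peak time, relative increase) pair per
anatomic compartment (cephalic vein, radial artery, skeletal muscle,
subcutaneous fat). Summaries are arithmetic means per compartment plus two
variability views of the peak times: sample standard deviation (n-1
denominator) within each compartment across subjects, and within each
subject across compartments. Display values are rounded half-away-from-zero
to one decimal; unrounded values are retained internally.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "load_records",
    "load_pilot_records",
    "summarize_compartment",
    "sd_sample",
    "peak_time_variability",
    "build_summary_table",
    "round_half_away",
    "COMPARTMENT_ORDER",
]

COMPARTMENT_ORDER = ("vein", "artery", "muscle", "fat")
RECORD_COLUMNS = ["subject", "compartment", "peak_time_min", "relative_increase_pct"]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the usual display convention for tables)."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("records are empty")
    if (records["peak_time_min"] < 0).any():
        raise ValueError("peak times must be >= 0 minutes")
    dup = records.duplicated(subset=["subject", "compartment"])
    if dup.any():
        pairs = records.loc[dup, ["subject", "compartment"]].to_records(index=False)
        raise ValueError(f"duplicate (subject, compartment) records: {list(pairs)}")
    return records


def load_records(path: str | Path) -> pd.DataFrame:
    """Read a per-subject records CSV (subject, compartment, peak time, increase)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed records CSV {path}: {exc}") from exc
    return _validate_records(df)


def load_pilot_records() -> pd.DataFrame:
    """The packaged four-subject pilot cohort records (transcribed inputs)."""
    ref = resources.files("lipidmsot.data") / "pilot_cohort_records.csv"
    with resources.as_file(ref) as path:
        return load_records(path)


def summarize_compartment(records: pd.DataFrame) -> tuple[float, float]:
    """(mean peak time, mean relative increase) for records of one compartment."""
    _validate_records(records)
    compartments = records["compartment"].unique()
    if len(compartments) != 1:
        raise ValueError(f"expected one compartment, got {sorted(compartments)}")
    return (
        float(records["peak_time_min"].mean()),
        float(records["relative_increase_pct"].mean()),
    )


def sd_sample(values: Iterable[float]) -> float:
    """Sample standard deviation, n-1 denominator."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values for a sample SD, got {arr.size}")
    return float(np.std(arr, ddof=1))


def peak_time_variability(records: pd.DataFrame, group_by: str) -> pd.Series:
    """Sample SD of peak times within each subject or each compartment."""
    if group_by not in ("subject", "compartment"):
        raise ValueError("group_by must be 'subject' or 'compartment'")
    _validate_records(records)
    sizes = records.groupby(group_by).size()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 records: {list(small.index)}")
    return records.groupby(group_by)["peak_time_min"].apply(sd_sample).rename("peak_time_sd_min")


def build_summary_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject rows plus a Means row per compartment.

    Columns: compartment, subject ('Means' for the aggregate row),
    peak_time_min, relative_increase_pct (unrounded), and their
    *_display variants rounded half-away-from-zero to 1 decimal.
    """
    _validate_records(records)
    rows = []
    present = [c for c in COMPARTMENT_ORDER if c in set(records["compartment"])]
    present += [c for c in records["compartment"].unique() if c not in present]
    for comp in present:
        sub = records[records["compartment"] == comp].sort_values("subject")
        for _, r in sub.iterrows():
            rows.append(
                dict(compartment=comp, subject=str(r["subject"]),
                     peak_time_min=float(r["peak_time_min"]),
                     relative_increase_pct=float(r["relative_increase_pct"]))
            )
        mean_t, mean_i = summarize_compartment(sub)
        rows.append(
            dict(compartment=comp, subject="Means",
                 peak_time_min=mean_t, relative_increase_pct=mean_i)
        )
    table = pd.DataFrame(rows)
    table["peak_time_display"] = table["peak_time_min"].map(round_half_away)
    table["relative_increase_display"] = table["relative_increase_pct"].map(round_half_away)
    return table
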