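"""Readers and writers for grouped observation tables and result records.

Input is a delimited text table with a required ``group,value`` header,
one row per observation; groups come out in order of first appearance.
Output records go to JSON (list of records) or CSV (flat), with reals
rounded to 6 significant digits.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import ObservedSample

__all__ = ["InputError", "read_samples", "write_results", "fit_record"]


class InputError(ValueError):
    """Malformed input data (missing columns, bad or non-positive values)."""


def read_samples(path) -> list[ObservedSample]:
    """Read ``group,value`` CSV into one sample per distinct group."""
    try:
        frame = pd.read_csv(path, dtype={"group": str})
    except Exception as exc:
        raise InputError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = {"group", "value"} - set(frame.columns)
    if missing:
        raise InputError(f"{path}: missing column(s) {sorted(missing)}")
    if len(frame) == 0:
        raise InputError(f"{path}: no data rows")
    values = pd.to_numeric(frame["value"], errors="coerce")
    bad = values.isna() | (values <= 0)
    if bad.any():
        row = int(bad.idxmax()) + 2  # header is line 1
        raise InputError(
            f"{path}: non-numeric or non-positive value at line {row}"
        )
    samples = []
    for group in frame["group"].drop_duplicates():
        vals = values[frame["group"] == group].to_numpy()
        if vals.size < 2:
            raise InputError(f"{path}: group {group!r} has fewer than 2 rows")
        samples.append(ObservedSample(str(group), vals))
    return samples


def _round_sig(value, digits: int = 6):
    if isinstance(value, float):
        if value == 0 or not math.isfinite(value):
            return value
        return round(value, digits - 1 - int(math.floor(math.log10(abs(value)))))
    return value


def write_results(records: Sequence[dict], path, fmt: str = "json") -> None:
    """Write result records as JSON (records) or CSV (flat table)."""
    records = [
        {key: _round_sig(val) for key, val in record.items()} for record in records
    ]
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    elif fmt == "csv":
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def fit_record(sample, fit, estimate) -> dict:
    """Flat summary record for one group's fit."""
    return {
        "group": sample.group_id,
        "n": sample.n,
        "c_hat": fit.c_hat,
        "k_hat": fit.k_hat,
        "mu_hat": estimate.mu_hat,
        "var_mu": estimate.var_hat,
        "loglik": fit.loglik,
    }
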