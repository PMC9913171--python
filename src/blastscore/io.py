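"""Cohort readers and writers for the tabular exchange format.

One row / object per case.  CSV: UTF-8, comma-separated, mandatory header
with the exact column names in :data:`~blastscore.model.COHORT_COLUMNS`;
empty cell = unknown; enum tokens lower-snake-case; booleans ``true`` /
``false``; percents plain numbers.  JSON mirrors the CSV as an array of
objects with the same keys (``null`` = unknown).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .model import (
    BOOL_FIELDS,
    COHORT_COLUMNS,
    PERCENT_FIELDS,
    Cohort,
    CohortValidationError,
    case_to_record,
    record_to_case,
)

PathLike = Union[str, Path]


def _infer_format(path: PathLike, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unsupported cohort format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "json" if suffix == ".json" else "csv"


def read_cohort(path: PathLike, format: str | None = None,
                provenance: str = "user") -> Cohort:
    """Read a cohort file, validating every cell against the contract.

    Raises :class:`CohortValidationError` naming the offending case and
    column for duplicate ids, unrecognized enum tokens, non-numeric or
    out-of-range percents.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(
                f"{path}: missing required columns {missing_cols}"
            )
        records = df.to_dict(orient="records")
    else:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise CohortValidationError(f"{path}: JSON cohort must be an array")
        records = data
    cases = [record_to_case(rec) for rec in records]
    return Cohort(cases=cases, provenance=provenance)


def write_cohort(cohort: Cohort, path: PathLike, format: str | None = None) -> None:
    """Write a cohort; ``read_cohort(write_cohort(c))`` is field-for-field identity."""
    fmt = _infer_format(path, format)
    path = Path(path)
    records = [case_to_record(c) for c in cohort]
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
        return
    rows = []
    for rec in records:
        row = {}
        for col in COHORT_COLUMNS:
            v = rec[col]
            if v is None:
                row[col] = ""
            elif col in BOOL_FIELDS:
                row[col] = "true" if v else "false"
            elif col in PERCENT_FIELDS:
                # keep integral percents integral for byte-stable round trips
                row[col] = f"{v:g}"
            else:
                row[col] = v
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS, dtype=str)
    df.to_csv(path, index=False, lineterminator="\n")


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Cohort as a pandas DataFrame (one row per case, unknown -> NA)."""
    return pd.DataFrame(
        [case_to_record(c) for c in cohort], columns=COHORT_COLUMNS
    )
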