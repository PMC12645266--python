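"""Trial-record dataset I/O with strict schema validation.

Datasets are plain UTF-8 comma-delimited CSV (the format behavioral data
are typically deposited in), one row per trial per subject.  Validation is
row-indexed and enforces the trial-record invariants: categorical levels,
range checks, the force-fields-iff-work rule and the delivered-shocks
contingency (work shocks on success, 6 after rest, 10 after failure or
non-response).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import DATASET_COLUMNS

__all__ = ["read_dataset", "write_dataset", "validate_dataset"]


class DatasetSchemaError(ValueError):
    pass


def validate_dataset(data: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalize) a trial-record table in place.

    Raises :class:`DatasetSchemaError` naming the offending column and row
    numbers (0-based within the table) on the first violated rule.
    """
    missing = [c for c in DATASET_COLUMNS if c not in data.columns]
    if missing:
        raise DatasetSchemaError(f"missing columns: {missing}")

    def _bad_rows(mask, column, rule):
        if mask.any():
            rows = data.index[mask].tolist()
            shown = rows[:10]
            suffix = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
            raise DatasetSchemaError(
                f"column {column!r}: {rule}; rows {shown}{suffix}"
            )

    _bad_rows(data["subject_id"].isna(), "subject_id", "must not be null")
    trial = pd.to_numeric(data["trial"], errors="coerce")
    _bad_rows(trial.isna() | (trial < 1) | (trial != trial.round()),
              "trial", "must be a positive integer (1-based)")
    _bad_rows(~data["recipient"].isin(["self", "other"]),
              "recipient", "must be 'self' or 'other'")
    eff = pd.to_numeric(data["effort_level"], errors="coerce")
    _bad_rows(~eff.isin([1, 2, 3, 4, 5]), "effort_level", "must be in 1..5")
    shk = pd.to_numeric(data["work_shocks"], errors="coerce")
    _bad_rows(~shk.isin([1, 2, 3, 4, 5]), "work_shocks",
              "must be in 1..5 (work offer must beat the 6-shock rest offer)")
    _bad_rows(~data["choice"].isin(["work", "rest", "nonresponse"]),
              "choice", "must be 'work', 'rest' or 'nonresponse'")

    rt = pd.to_numeric(data["rt_s"], errors="coerce")
    responded = data["choice"] != "nonresponse"
    _bad_rows(responded & (rt.isna() | (rt <= 0) | (rt >= 4.0)),
              "rt_s", "responded trials need an RT in (0, 4) seconds")
    _bad_rows(~responded & rt.notna(), "rt_s", "non-response trials cannot have an RT")

    force = pd.to_numeric(data["force_auc"], errors="coerce")
    is_work = data["choice"] == "work"
    _bad_rows(is_work & (force.isna() | (force <= 0) | (force > 1)),
              "force_auc", "work trials need force AUC in (0, 1]")
    _bad_rows(~is_work & force.notna(), "force_auc",
              "force AUC is only defined for work choices")

    succ = _normalize_success(data["success"])
    _bad_rows(is_work & succ.isna(), "success", "work trials need a success flag")
    _bad_rows(~is_work & succ.notna(), "success",
              "success is only defined for work choices")
    data["success"] = succ

    delivered = pd.to_numeric(data["delivered_shocks"], errors="coerce")
    expected = pd.Series(
        np.select(
            [~responded, ~is_work, succ.fillna(False).to_numpy(dtype=bool)],
            [10, 6, shk],
            default=10,
        ),
        index=data.index,
    )
    _bad_rows(delivered != expected, "delivered_shocks",
              "must follow the contingency (work shocks if successful work, "
              "6 if rest, 10 if failed or non-response)")
    return data


def _normalize_success(col: pd.Series) -> pd.Series:
    mapping = {True: True, False: False, "True": True, "False": False,
               "true": True, "false": False, 1.0: True, 0.0: False}
    out = col.map(lambda v: mapping.get(v, pd.NA) if pd.notna(v) else pd.NA)
    return out.astype("boolean")


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a trial-record CSV."""
    data = pd.read_csv(path)
    return validate_dataset(data)


def write_dataset(data: pd.DataFrame, path) -> None:
    """Validate and write a trial-record table as CSV.

    Floats are written with 10 significant digits, which makes
    write -> read -> write text-stable.
    """
    validate_dataset(data.copy()).to_csv(path, index=False, float_format="%.10g")
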