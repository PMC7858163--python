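"""CSV interchange for longitudinal scans and velocity observations.

Schema (all gestational ages in decimal weeks, all sizes in mm):

    fetus_id, ga_weeks, biometry, value_mm[, rep1_mm, rep2_mm, rep3_mm]

If the triplicate columns are present, a missing value_mm is filled with
their mean and a present value_mm must equal it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .standards import BiometryCode

__all__ = ["SchemaError", "read_scans_csv", "write_observations_csv", "read_zscores_csv"]

REQUIRED_COLUMNS = ("fetus_id", "ga_weeks", "biometry", "value_mm")
REPLICATE_COLUMNS = ("rep1_mm", "rep2_mm", "rep3_mm")


class SchemaError(ValueError):
    """A longitudinal CSV violates the interchange schema."""


def _line(idx: int) -> int:
    # +2: header line plus 1-based numbering
    return int(idx) + 2


def read_scans_csv(path) -> pd.DataFrame:
    """Read and validate a longitudinal scans CSV.

    Raises :class:`SchemaError` with file line numbers for missing
    columns, unknown biometry codes, non-positive sizes, out-of-range
    gestational ages, or replicate/value disagreement.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: no scan records")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "value_mm"]
    has_reps = all(c in df.columns for c in REPLICATE_COLUMNS)
    if "value_mm" not in df.columns and not has_reps:
        missing.append("value_mm (or rep1_mm..rep3_mm)")
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    if has_reps:
        reps = df[list(REPLICATE_COLUMNS)].astype(float)
        bad = reps.isna().any(axis=1) ^ reps.isna().all(axis=1)
        if bad.any():
            raise SchemaError(
                f"{path}: partial replicate triplets at lines "
                f"{[_line(i) for i in df.index[bad][:5]]}"
            )
        mean = reps.mean(axis=1)
        if "value_mm" not in df.columns:
            df["value_mm"] = mean
        else:
            df["value_mm"] = df["value_mm"].astype(float).fillna(mean)
            have = ~reps.isna().any(axis=1)
            off = have & (np.abs(df["value_mm"] - mean) > 1e-6)
            if off.any():
                raise SchemaError(
                    f"{path}: value_mm differs from the replicate mean at lines "
                    f"{[_line(i) for i in df.index[off][:5]]}"
                )

    try:
        df["ga_weeks"] = df["ga_weeks"].astype(float)
        df["value_mm"] = df["value_mm"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric ga_weeks/value_mm: {exc}") from None

    for col, ok, what in [
        ("ga_weeks", (df["ga_weeks"] > 0) & (df["ga_weeks"] < 45), "gestational age in (0, 45) weeks"),
        ("value_mm", df["value_mm"] > 0, "positive size (mm)"),
    ]:
        bad = ~ok | df[col].isna()
        if bad.any():
            raise SchemaError(
                f"{path}: expected {what}; offending lines "
                f"{[_line(i) for i in df.index[bad][:5]]}"
            )
    try:
        df["biometry"] = [BiometryCode.coerce(b).value for b in df["biometry"]]
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None
    return df


def write_observations_csv(path, observations: pd.DataFrame) -> None:
    """Write a velocity-observation table (one row per pair)."""
    observations.to_csv(path, index=False)


def read_zscores_csv(path) -> pd.DataFrame:
    """Read a per-visit Z-score series CSV (fetus_id, ga_weeks, z[, biometry])."""
    df = pd.read_csv(path)
    need = {"fetus_id", "ga_weeks", "z"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    df["ga_weeks"] = df["ga_weeks"].astype(float)
    df["z"] = df["z"].astype(float)
    if df["z"].isna().any() or df["ga_weeks"].isna().any():
        raise SchemaError(f"{path}: missing ga_weeks/z values")
    return df
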