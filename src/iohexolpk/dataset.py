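"""Long-format concentration dataset reading, validation and writing.

Dialect: CSV with header ``ID,TIME,DV,AMT,CKD,CREAT,WT``; one dose row per
subject at TIME=0 with ``AMT`` set (mg/kg) and ``DV`` empty; observation
rows carry ``DV`` (ug/ml) and an empty ``AMT``.  UTF-8, '.' decimal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_dataset", "write_dataset", "DatasetError"]

_COLUMNS = ["ID", "TIME", "DV", "AMT", "CKD", "CREAT", "WT"]


class DatasetError(ValueError):
    """Malformed dataset file; message names the offending row/column."""


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format PK dataset.

    Row numbers in error messages are 0-indexed data rows (header excluded).
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in raw.columns]
    if missing:
        raise DatasetError(f"missing required columns: {', '.join(missing)}")

    def num(col, row_idx, value, required):
        if value.strip() == "":
            if required:
                raise DatasetError(f"row {row_idx}: empty {col}")
            return np.nan
        try:
            return float(value)
        except ValueError:
            raise DatasetError(
                f"row {row_idx}: non-numeric {col} value {value!r}") from None

    records = []
    for i, row in enumerate(raw.itertuples(index=False)):
        rec = {"ID": row.ID,
               "TIME": num("TIME", i, row.TIME, required=True),
               "DV": num("DV", i, row.DV, required=False),
               "AMT": num("AMT", i, row.AMT, required=False),
               "CKD": num("CKD", i, row.CKD, required=True),
               "CREAT": num("CREAT", i, row.CREAT, required=True),
               "WT": num("WT", i, row.WT, required=False)}
        if np.isnan(rec["DV"]) and np.isnan(rec["AMT"]):
            raise DatasetError(f"row {i}: neither DV nor AMT set")
        if rec["TIME"] < 0:
            raise DatasetError(f"row {i}: negative TIME")
        if not np.isnan(rec["DV"]) and rec["DV"] <= 0:
            raise DatasetError(f"row {i}: non-positive DV")
        if rec["CKD"] not in (0.0, 1.0):
            raise DatasetError(f"row {i}: CKD must be 0 or 1")
        records.append(rec)
    df = pd.DataFrame(records, columns=_COLUMNS)
    if len(df):
        df["CKD"] = df["CKD"].astype(int)
        obs = df[df["DV"].notna()]
        dup = obs.duplicated(subset=["ID", "TIME"])
        if dup.any():
            raise DatasetError(
                f"duplicate (ID, TIME) observation at row {int(np.flatnonzero(dup.to_numpy())[0])}")
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a long-format dataset in the canonical dialect."""
    out = df.reindex(columns=_COLUMNS)
    out.to_csv(path, index=False, float_format="%.10g")
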