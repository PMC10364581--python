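"""Tidy CSV exchange for demographic tables.

One row per (location, age_start, age_end, sex, year) cell with a
``measure`` label and ``value`` (plus ``se`` where applicable). Missing
values are forbidden; writes are deterministic (sorted, fixed float
format) so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import pandas as pd

from .containers import key_columns_of

REQUIRED_ORDER = ["location", "age_start", "age_end", "sex", "year", "measure", "value", "se"]


def write_table(frame: pd.DataFrame, path, measure: str | None = None) -> None:
    out = frame.copy()
    if measure is not None and "measure" not in out.columns:
        out["measure"] = measure
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values are forbidden in tidy output (columns {bad})")
    cols = [c for c in REQUIRED_ORDER if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out = out[cols].sort_values(key_columns_of(out)).reset_index(drop=True)
    out.to_csv(path, index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if frame.isna().any().any():
        raise ValueError(f"missing values found in {path}")
    return frame
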