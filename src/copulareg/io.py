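"""Dataset reading and writing.

The on-disk format is a plain CSV with one row per subject: outcome columns
``y1`` (internet addiction total) and ``y2`` (smartphone addiction total),
binary columns GENDER/ALC/SMK coded 0/1 (GENDER reference 0 = male), the
psychosocial scores, daily usage hours and birth year. Missing outcomes stay
empty and survive a read/write round trip.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = ("y1", "y2")
BINARY_COLUMNS = ("GENDER", "ALC", "SMK")
REQUIRED_COLUMNS = (
    "y1", "y2", "GENDER", "BDI", "BAI", "BIS", "CASS", "AQ",
    "WDGH", "WEGH", "WDIH", "WDSH", "WESH", "YEAR", "ALC", "SMK",
)
OPTIONAL_COLUMNS = ("STAXI_E",)


def read_dataset(path, required_columns=REQUIRED_COLUMNS) -> pd.DataFrame:
    """Read and validate a study CSV.

    Missing required columns raise :class:`SchemaError` naming the column;
    binary columns holding non-0/1 codes (e.g. ``"M"``/``"F"``) raise with a
    recoding hint. Rows with unparseable numeric cells are dropped and
    reported (row indices in ``df.attrs["rejected_rows"]`` and the log);
    empty outcome cells are preserved as missing.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"dataset not found: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in required_columns if c not in raw.columns]
    if missing:
        raise SchemaError(f"required column(s) missing: {', '.join(missing)}")

    for col in BINARY_COLUMNS:
        if col not in raw.columns:
            continue
        vals = set(raw[col].dropna().unique()) - {"0", "1", "0.0", "1.0"}
        if vals:
            raise SchemaError(
                f"column {col!r} holds non-binary codes {sorted(vals)}; "
                "recode as 0/1 (GENDER: 0 = male, 1 = female)"
            )

    numeric_cols = [c for c in raw.columns if c in required_columns or c in OPTIONAL_COLUMNS]
    df = raw.copy()
    bad_rows: set[int] = set()
    for col in numeric_cols:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        unparseable = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        bad_rows.update(np.flatnonzero(unparseable.to_numpy()).tolist())
        df[col] = parsed

    if bad_rows:
        logger.warning("rejected %d row(s) with unparseable numerics: %s",
                       len(bad_rows), sorted(bad_rows))
        df = df.drop(index=sorted(bad_rows)).reset_index(drop=True)

    neg = df[list(OUTCOME_COLUMNS)].le(0).any(axis=1)
    if neg.any():
        idx = np.flatnonzero(neg.to_numpy()).tolist()
        logger.warning("rejected %d row(s) with non-positive outcomes: %s", len(idx), idx)
        df = df.loc[~neg].reset_index(drop=True)

    df.attrs["rejected_rows"] = sorted(bad_rows)
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
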