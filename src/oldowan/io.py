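"""CSV readers/writers with schema validation.

Flake tables: UTF-8, comma-separated, '.' decimal, one header row, one row per
detached piece. Columns: ``core_id, flake_index, material, behavior, whole``
followed by the measurement columns in canonical order (mm, cortex in
percent 0-100, area in mm^2). ``behavior`` may be empty (non-diagnostic or
unlabelled archaeological pieces). Rows failing the measurement invariants
(whole flakes with non-positive measures, cortex outside 0-100, or a maximum
dimension shorter than length/width) are excluded with a logged count, the
table-level analogue of dropping flakes with missing measurements.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import SchemaError
from .morphometrics import CORTEX_MEASUREMENTS, LINEAR_MEASUREMENTS
from .simulate import CORE_COLUMNS, FLAKE_COLUMNS, Assemblage

logger = logging.getLogger("oldowan")

_FLOAT_FORMAT = "%.6g"


def read_flake_table(path, require_behavior: bool = False
                     ) -> tuple[pd.DataFrame, int]:
    """Read and validate a flake CSV.

    Returns ``(table, n_excluded)`` where ``n_excluded`` counts rows dropped
    for failing measurement invariants. Raises SchemaError for a missing
    required column or an empty file.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    required = [c for c in FLAKE_COLUMNS if c not in ("behavior", "whole")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    if "behavior" not in df.columns:
        if require_behavior:
            raise SchemaError(f"{path}: missing required column 'behavior'")
        df["behavior"] = ""
    df["behavior"] = df["behavior"].fillna("").astype(str)
    if "whole" not in df.columns:
        df["whole"] = True
    df["whole"] = df["whole"].astype(bool)

    ok = np.ones(len(df), dtype=bool)
    for c in LINEAR_MEASUREMENTS + ("platform_area",):
        v = df[c].to_numpy(dtype=float)
        ok &= np.isfinite(v) & (v > 0)
    for c in CORTEX_MEASUREMENTS:
        v = df[c].to_numpy(dtype=float)
        ok &= np.isfinite(v) & (v >= 0) & (v <= 100)
    maxdim = df["maximum_dimension"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ok &= maxdim >= np.maximum(df["length"].to_numpy(dtype=float),
                                   df["width"].to_numpy(dtype=float)) * (1 - 1e-9)
    n_excluded = int((~ok).sum())
    if n_excluded:
        bad_rows = (np.nonzero(~ok)[0] + 2).tolist()  # 1-based incl. header
        logger.warning(
            "%s: excluded %d row(s) with missing/invalid measurements "
            "(file rows %s%s)", path, n_excluded, bad_rows[:20],
            ", ..." if len(bad_rows) > 20 else "")
    return df.loc[ok].reset_index(drop=True), n_excluded


def write_flake_table(df: pd.DataFrame, path) -> None:
    """Write a flake table in canonical column order (extra columns appended)."""
    cols = [c for c in FLAKE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_core_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_core_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in CORE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_assemblage(assemblage: Assemblage, flakes_path, cores_path) -> None:
    write_flake_table(assemblage.flakes, flakes_path)
    write_core_table(assemblage.cores, cores_path)


def read_assemblage(flakes_path, cores_path,
                    labels_hidden: bool = False) -> tuple[Assemblage, int]:
    flakes, n_excluded = read_flake_table(flakes_path)
    cores = read_core_table(cores_path)
    return Assemblage(flakes=flakes, cores=cores,
                      labels_hidden=labels_hidden), n_excluded
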