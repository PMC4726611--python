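"""Size standardization of whole-flake measurements.

Flake measurements are recorded in millimetres (area in mm^2). Identical
production behaviors yield flakes of very different absolute sizes depending
on the parent cobble, so all shape comparisons are made on size-standardized
variables: each linear measurement is divided by the flake's own geometric
mean of a configured set of linear measurements, and platform area is divided
by the square of that geometric mean (an area is dimension two). Cortex
percentages are already dimensionless and pass through unchanged.

The standardized variables used downstream are:

====== ==============================
SL     size-standardized length
SW     size-standardized width
ST     size-standardized thickness
SMAX   size-standardized maximum dimension
SBT    size-standardized bulbar thickness
SAREA  size-standardized platform area
====== ==============================

By construction the geometric mean of a flake's standardized GM-set values is
exactly 1, so the standardized vector is a pure shape descriptor (a Mosimann
shape vector) and is invariant under rescaling of the whole flake.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

#: All linear measurements taken on a whole flake, in the canonical column order.
LINEAR_MEASUREMENTS: tuple[str, ...] = (
    "length",
    "width",
    "thickness",
    "bulbar_thickness",
    "platform_width",
    "left_platform_width",
    "right_platform_width",
    "platform_thickness",
    "left_platform_thickness",
    "right_platform_thickness",
    "maximum_dimension",
)

#: Cortex percentages (0-100, dimensionless).
CORTEX_MEASUREMENTS: tuple[str, ...] = ("platform_cortex", "dorsal_cortex")

#: All per-flake measurement columns, in canonical order.
FLAKE_MEASUREMENTS: tuple[str, ...] = (
    LINEAR_MEASUREMENTS + CORTEX_MEASUREMENTS + ("platform_area",)
)

#: Default set of linear measurements entering the geometric mean.  The
#: platform width/thickness terms are included so that the shape vector is a
#: closed system: the reference envelope statistics for SL..SBT are mutually
#: consistent with a per-flake unit geometric mean only once the (small)
#: platform dimensions enter the denominator.
DEFAULT_GM_FIELDS: tuple[str, ...] = (
    "length",
    "width",
    "thickness",
    "bulbar_thickness",
    "maximum_dimension",
    "platform_width",
    "platform_thickness",
)

#: Mapping from raw measurement column to its standardized variable name.
STANDARDIZED_OF: dict[str, str] = {
    "length": "SL",
    "width": "SW",
    "thickness": "ST",
    "maximum_dimension": "SMAX",
    "bulbar_thickness": "SBT",
    "platform_area": "SAREA",
    "platform_width": "SPW",
    "platform_thickness": "SPT",
}

#: The six standardized measures reported in envelopes and used as classifier
#: features (together with the two cortex percentages).
STANDARDIZED_MEASURES: tuple[str, ...] = ("SL", "SW", "ST", "SMAX", "SBT", "SAREA")


def geometric_mean(values: Iterable[float] | np.ndarray) -> float:
    """Geometric mean of strictly positive values, computed in log space.

    Parameters
    ----------
    values : iterable of float
        Non-empty collection of strictly positive numbers.

    Returns
    -------
    float
        ``(prod v_i)**(1/n)``, evaluated as ``exp(mean(log v_i))`` for
        numerical stability.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise DomainError("geometric_mean requires a non-empty input")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("geometric_mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(arr))))


def _row_geometric_means(df: pd.DataFrame, fields: Sequence[str]) -> np.ndarray:
    missing = [f for f in fields if f not in df.columns]
    if missing:
        raise DomainError(f"missing geometric-mean fields: {missing}")
    block = df.loc[:, list(fields)].to_numpy(dtype=float)
    bad = ~np.isfinite(block) | (block <= 0)
    if bad.any():
        rows = np.nonzero(bad.any(axis=1))[0]
        col = list(fields)[int(np.nonzero(bad[rows[0]])[0][0])]
        raise DomainError(
            f"non-positive or missing value in field '{col}' "
            f"(first offending row position {rows[0]})"
        )
    return np.exp(np.mean(np.log(block), axis=1))


def size_standardize(
    flake: Mapping[str, float] | pd.Series,
    gm_fields: Sequence[str] = DEFAULT_GM_FIELDS,
) -> dict[str, float]:
    """Size-standardize a single flake record.

    Each linear measurement in `gm_fields` and each of the reporting measures
    is divided by the geometric mean of the `gm_fields` values; platform area
    is divided by its square. Cortex percentages pass through.

    Returns a dict with the standardized variables (SL, SW, ST, SMAX, SBT,
    SAREA, SPW, SPT where available) plus cortex percentages.
    """
    row = pd.Series(dict(flake), dtype=float) if not isinstance(flake, pd.Series) else flake
    df = standardize_table(row.to_frame().T, gm_fields=gm_fields)
    keep = [c for c in df.columns if c in set(STANDARDIZED_OF.values())
            or c in CORTEX_MEASUREMENTS]
    return {k: float(df.iloc[0][k]) for k in keep}


def standardize_table(
    flakes: pd.DataFrame,
    gm_fields: Sequence[str] = DEFAULT_GM_FIELDS,
) -> pd.DataFrame:
    """Append standardized shape variables to a flake measurement table.

    Parameters
    ----------
    flakes : DataFrame
        One row per whole flake with the raw measurement columns (mm / mm^2 /
        percent). Identifier and label columns are carried through untouched.
    gm_fields : sequence of str
        Linear measurements entering the per-flake geometric mean.

    Returns
    -------
    DataFrame
        Copy of the input with SL, SW, ST, SMAX, SBT, SAREA (and SPW, SPT for
        GM-set platform measures) columns appended.  Cortex percentages are
        retained as-is.
    """
    gm = _row_geometric_means(flakes, gm_fields)
    out = flakes.copy()
    for raw, std in STANDARDIZED_OF.items():
        if raw == "platform_area":
            continue
        if raw in out.columns:
            out[std] = out[raw].to_numpy(dtype=float) / gm
    if "platform_area" in out.columns:
        area = out["platform_area"].to_numpy(dtype=float)
        if np.any(~np.isfinite(area)) or np.any(area <= 0):
            raise DomainError("non-positive or missing value in field 'platform_area'")
        out["SAREA"] = area / gm**2
    return out


def platform_area(flake: Mapping[str, float] | pd.Series) -> float:
    """Composite platform-area estimate from the platform sub-measures.

    The platform is modelled as two trapezoids hinged at the point of
    percussion: one spanning the left platform width between the central and
    left platform thicknesses, the other spanning the right platform width
    between the central and right platform thicknesses::

        area = 1/2 * lpw * (pt + lpt) + 1/2 * rpw * (pt + rpt)

    Use this when a measured ``platform_area`` column is not supplied.
    """
    needed = (
        "left_platform_width",
        "right_platform_width",
        "platform_thickness",
        "left_platform_thickness",
        "right_platform_thickness",
    )
    try:
        vals = {k: float(flake[k]) for k in needed}
    except (KeyError, TypeError) as exc:
        raise DomainError(
            "platform sub-measures missing; supply a precomputed "
            "'platform_area' column instead"
        ) from exc
    if any(not np.isfinite(v) or v <= 0 for v in vals.values()):
        raise DomainError("platform sub-measures must be strictly positive")
    left = 0.5 * vals["left_platform_width"] * (
        vals["platform_thickness"] + vals["left_platform_thickness"]
    )
    right = 0.5 * vals["right_platform_width"] * (
        vals["platform_thickness"] + vals["right_platform_thickness"]
    )
    return left + right
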