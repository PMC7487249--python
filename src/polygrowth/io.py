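"""Reading and writing nonchronological observation tables and run artifacts.

Observation tables are plain delimited text with a header row naming an age
column and a size column (defaults ``age`` and ``size``); extra columns are
ignored with a notice.  Rows with missing or non-positive values are
rejected with messages naming the offending row.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_models import ObservationSet

__all__ = ["read_observations", "write_observations", "ObservationReadError"]

logger = logging.getLogger(__name__)


class ObservationReadError(ValueError):
    """The observation table could not be parsed into a valid dataset."""


def read_observations(path, age_col: str = "age",
                      size_col: str = "size") -> ObservationSet:
    """Read an observation table from delimited text (CSV/TSV by sniffing).

    Validates that every row has strictly positive, finite age and size;
    offending rows are reported by their 1-based data row number.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else (";" if ";" in header else ",")
        # round_trip parsing: written data re-read bit-exactly
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except ObservationReadError:
        raise
    except Exception as err:
        raise ObservationReadError(f"cannot parse {path}: {err}") from err
    for col in (age_col, size_col):
        if col not in df.columns:
            raise ObservationReadError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})"
            )
    extra = [c for c in df.columns if c not in (age_col, size_col)]
    if extra:
        logger.info("%s: ignoring extra columns %s", path, extra)

    ages = pd.to_numeric(df[age_col], errors="coerce").to_numpy(dtype=float)
    sizes = pd.to_numeric(df[size_col], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(ages) | ~np.isfinite(sizes) | (ages <= 0) | (sizes <= 0)
    if bad.any():
        rows = (np.flatnonzero(bad) + 1).tolist()
        raise ObservationReadError(
            f"{path}: {bad.sum()} row(s) with missing or non-positive "
            f"age/size at data row(s) {rows[:20]}"
        )
    if ages.size == 0:
        raise ObservationReadError(f"{path}: no data rows")
    return ObservationSet(ages=ages, sizes=sizes)


def write_observations(data: ObservationSet, path,
                       age_col: str = "age", size_col: str = "size") -> None:
    """Write observations as CSV at full float precision (round-trip safe)."""
    df = pd.DataFrame({age_col: data.ages, size_col: data.sizes})
    # default str() formatting is shortest-round-trip for float64
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
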