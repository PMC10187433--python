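"""Table and image I/O with schema validation.

All tables are comma-separated UTF-8 CSV with '.' decimals; lines starting
with '#' carry run metadata (thresholds, seeds, package version) and are
skipped on read.  Each table kind has a required header; reading fails
with a :class:`SchemaError` naming the first missing column, while unknown
extra columns are preserved with a warning so user-augmented tables
survive a round trip.  Images are 16-bit TIFF (multi-channel intensity
stacks and integer label masks).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError

__all__ = ["SCHEMAS", "read_table", "write_table", "read_image",
           "write_image", "write_labels", "read_labels"]

#: Required columns per table kind (order is canonical on write).
SCHEMAS: dict[str, tuple[str, ...]] = {
    "trajectory": ("cell_id", "t_min", "foxo1_nf", "p53", "died", "t_death",
                   "truth_t_entry", "truth_t_exit", "truth_t_onset",
                   "truth_mode", "truth_dose_uM"),
    "snapshot": ("cell_id", "dose_uM", "p53_nuc", "foxo1_nf", "gh2ax",
                 "truth_foxo_active", "truth_p53_active"),
    "switch_states": ("t_min", "r", "s", "d", "h", "H_uM"),
    "features": ("cell_id", "t_entry", "t_exit", "duration", "t_onset",
                 "lag", "entry_censored", "exit_censored", "onset_censored"),
    "aligned": ("rel_t_min", "foxo1_nf_median", "p53_median", "n_cells"),
    "acf": ("cell_id", "lag_min", "acf"),
    "quadrants": ("dose_uM", "n", "frac_both", "frac_foxo_only",
                  "frac_p53_only", "frac_neither"),
    "measures": ("cell_id", "channel", "nuc_mean", "ring_mean",
                 "nuclear_fraction"),
    "comparison": ("group", "metric", "median", "n", "statistic", "p_value"),
}


def _require_schema(kind: str) -> tuple[str, ...]:
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}; choose from "
                          f"{sorted(SCHEMAS)}")
    return SCHEMAS[kind]


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a CSV table, validating its header against the ``kind`` schema.

    Missing required columns raise :class:`SchemaError` naming the column;
    extra columns are kept (with a warning).  '#'-prefixed metadata lines
    are ignored.
    """
    required = _require_schema(kind)
    df = pd.read_csv(path, comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(
                f"table {path} is missing required column {col!r} "
                f"for kind {kind!r}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(
            f"table {path} has extra columns {extra}; preserved as-is",
            stacklevel=2)
    return df[[*required, *extra]]


def write_table(df: pd.DataFrame, path: str | Path, kind: str,
                metadata: dict | None = None) -> None:
    """Write a CSV table after schema validation, with '#' metadata lines."""
    required = _require_schema(kind)
    for col in required:
        if col not in df.columns:
            raise SchemaError(
                f"cannot write kind {kind!r}: missing column {col!r}")
    extra = [c for c in df.columns if c not in required]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df[[*required, *extra]].to_csv(fh, index=False)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a multi-channel intensity image as 16-bit TIFF (values clipped
    to the uint16 range and rounded)."""
    arr = np.clip(np.round(np.asarray(image)), 0, 65535).astype(np.uint16)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr, photometric="minisblack")


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF image as float64."""
    return tifffile.imread(path).astype(float)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a label mask as 16-bit TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16),
                     photometric="minisblack")


def read_labels(path: str | Path) -> np.ndarray:
    """Read a label mask as an integer array."""
    return tifffile.imread(path).astype(np.int64)
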