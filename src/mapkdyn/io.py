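"""Readers and writers for the pipeline's interchange formats.

Tabular data is CSV with fixed documented headers; z-stacks are multi-page
TIFF with a YAML sidecar carrying channel count and z scale; ground truth
is JSON. All writers/readers are lossless inverses on generated data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from mapkdyn.errors import ValidationError

log = logging.getLogger("mapkdyn")

#: tracking-table schema (column -> dtype kind)
TRACK_COLUMNS = {
    "cell_id": "str",
    "frame": "int",
    "time_min": "float",
    "x_um": "float",
    "y_um": "float",
    "nuc_ktr": "float",
    "cyt_ktr": "float",
    "nuc_loc": "float",
    "cyt_loc": "float",
    "population": "str",
    "valid": "bool",
}

EDU_COLUMNS = ["position", "condition", "population", "dox", "n_nuclei", "n_edu_positive"]


def write_track_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=list(TRACK_COLUMNS))


def read_track_table(path) -> pd.DataFrame:
    """Read and validate a tracking table.

    Rows with non-finite numeric fields or nonpositive reporter
    intensities are rejected and logged with their line numbers; a missing
    mandatory column raises :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {sorted(missing)}")
    numeric = ["frame", "time_min", "x_um", "y_um",
               "nuc_ktr", "cyt_ktr", "nuc_loc", "cyt_loc"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = ~np.isfinite(df[numeric]).all(axis=1)
    bad |= (df[["nuc_ktr", "cyt_ktr", "nuc_loc", "cyt_loc"]] <= 0).any(axis=1)
    if bad.any():
        for idx in df.index[bad]:
            # +2: header line and 1-based numbering
            log.warning("%s: rejected malformed row at line %d", path, idx + 2)
        df = df[~bad]
    df = df.reset_index(drop=True)
    df["frame"] = df["frame"].astype(int)
    df["valid"] = df["valid"].astype(bool)
    return df


def write_stack(
    stack: np.ndarray,
    path,
    z_step_um: float = 1.0,
    z_min_um: float = 0.0,
    channel_labels=("inducible", "all"),
) -> None:
    """Write a (C, Z, Y, X) stack as multi-page TIFF + YAML sidecar.

    Pages are stored channel-major (all z planes of channel 0, then
    channel 1, ...); the sidecar (same path with .yaml appended) records
    the channel count and z scale needed to reassemble the array.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValidationError("stack must be (C, Z, Y, X)")
    c, z, ny, nx = stack.shape
    tifffile.imwrite(path, stack.reshape(c * z, ny, nx),
                     photometric="minisblack")
    sidecar = {
        "n_channels": int(c),
        "n_z": int(z),
        "z_step_um": float(z_step_um),
        "z_min_um": float(z_min_um),
        "channel_labels": list(channel_labels),
        "page_order": "channel_major",
    }
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_stack(
    path,
    sidecar_path=None,
    z_step_um: float | None = None,
    n_channels: int | None = None,
):
    """Read a multi-page TIFF stack into (C, Z, Y, X) plus scale metadata.

    Metadata comes from the YAML sidecar (default: ``<path>.yaml``);
    explicit ``z_step_um``/``n_channels`` arguments take precedence over
    the sidecar (with a logged warning when both are present and differ,
    or when the sidecar is missing).
    """
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta = {}
    sc = Path(sidecar_path) if sidecar_path else Path(str(path) + ".yaml")
    if sc.exists():
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
    elif z_step_um is None or n_channels is None:
        raise ValidationError(f"{path}: no sidecar and no explicit metadata")
    else:
        log.warning("%s: sidecar missing, using explicit flags", path)
    if n_channels is not None:
        if meta.get("n_channels") not in (None, n_channels):
            log.warning("%s: explicit n_channels overrides sidecar", path)
        c = n_channels
    else:
        c = int(meta["n_channels"])
    if z_step_um is not None:
        if meta.get("z_step_um") not in (None, z_step_um):
            log.warning("%s: explicit z_step_um overrides sidecar", path)
        step = z_step_um
    else:
        step = float(meta.get("z_step_um", 1.0))
    if pages.shape[0] % c:
        raise ValidationError(
            f"{path}: page count {pages.shape[0]} not divisible by {c} channels"
        )
    z = pages.shape[0] // c
    stack = pages.reshape(c, z, *pages.shape[1:])
    out_meta = {
        "z_step_um": step,
        "z_min_um": float(meta.get("z_min_um", 0.0)),
        "channel_labels": meta.get("channel_labels", [str(i) for i in range(c)]),
    }
    return stack, out_meta


def write_edu_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=EDU_COLUMNS)


def read_edu_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EDU_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {sorted(missing)}")
    df["dox"] = df["dox"].astype(bool)
    return df
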