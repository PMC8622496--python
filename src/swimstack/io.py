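"""File-format plumbing: count tables, configs, image stacks.

Count tables travel as UTF-8 CSV with a header row and the fixed columns
``snapshot_index,time_s,slice_z_um,raw_count`` (one row per snapshot/slice
pair); an optional ``z_top_um`` column carries the evaporating surface
height.  Unknown extra columns are preserved in metadata.  Configs are YAML;
image stacks are multi-page TIFF.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ZStackCounts

log = logging.getLogger("swimstack")

REQUIRED_COLUMNS = ["snapshot_index", "time_s", "slice_z_um", "raw_count"]

__all__ = ["read_counts", "write_counts", "counts_to_dataframe",
           "counts_from_dataframe", "load_config", "save_config",
           "read_stack", "write_stack"]


def counts_to_dataframe(counts: ZStackCounts) -> pd.DataFrame:
    S, J = counts.counts.shape
    df = pd.DataFrame({
        "snapshot_index": np.repeat(np.arange(S), J),
        "time_s": np.repeat(counts.times, J),
        "slice_z_um": np.tile(counts.slice_z, S),
        "raw_count": counts.counts.ravel(),
        "z_top_um": np.repeat(counts.z_top, J),
    })
    if np.allclose(df["raw_count"], np.round(df["raw_count"])):
        df["raw_count"] = df["raw_count"].astype(int)
    return df


def counts_from_dataframe(df: pd.DataFrame) -> ZStackCounts:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table is missing columns: {missing}")
    bad = df.index[df["raw_count"] < 0]
    if len(bad):
        raise ValueError(f"negative count at line {int(bad[0]) + 2}")  # 1-based + header
    non_int = df.index[df["raw_count"] != np.round(df["raw_count"])]
    if len(non_int):
        raise ValueError(f"non-integer count at line {int(non_int[0]) + 2}")
    snaps = np.sort(df["snapshot_index"].unique())
    slices = np.sort(df["slice_z_um"].unique())
    pivot = df.pivot_table(index="snapshot_index", columns="slice_z_um",
                           values="raw_count", aggfunc="first")
    if pivot.isna().any().any():
        raise ValueError("count table is not a complete snapshot x slice grid")
    times = df.groupby("snapshot_index")["time_s"].first().loc[snaps].to_numpy()
    if "z_top_um" in df.columns:
        z_top = df.groupby("snapshot_index")["z_top_um"].first().loc[snaps].to_numpy()
    else:
        z_top = None
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS + ["z_top_um"]]
    metadata = {}
    if extra:
        warnings.warn(f"preserving unknown count-table columns in metadata: {extra}")
        metadata["extra_columns"] = {c: df[c].tolist() for c in extra}
    return ZStackCounts(pivot.loc[snaps, slices].to_numpy(), slices, times,
                        z_top=z_top, metadata=metadata)


def write_counts(counts: ZStackCounts, path) -> None:
    path = Path(path)
    counts_to_dataframe(counts).to_csv(path, index=False)
    truth = counts.metadata.get("ground_truth")
    if truth is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_counts(path) -> ZStackCounts:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed count table {path}: {exc}") from exc
    counts = counts_from_dataframe(df)
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        counts.metadata["ground_truth"] = json.loads(sidecar.read_text())
    return counts


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_stack(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
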