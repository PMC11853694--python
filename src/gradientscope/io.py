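"""Readers and writers for the pipeline's delimited-text interchange formats.

All matrices are tab-delimited with a header row and a leading ``region_id``
column (0-based).  The cohort manifest is CSV.  Gene sets use the standard
GMT layout (set name, description, then tab-separated gene symbols).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a region-indexed table as TSV with a ``region_id`` column."""
    out = frame.copy()
    out.index.name = "region_id"
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="region_id")


def write_series(series: np.ndarray, path: str | Path) -> None:
    n_regions, n_t = series.shape
    frame = pd.DataFrame(
        series, index=pd.RangeIndex(n_regions, name="region_id"),
        columns=[f"t{j}" for j in range(n_t)],
    )
    frame.to_csv(path, sep="\t")


def read_series(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col="region_id").to_numpy()


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"subject_id", "group"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(manifest["group"]) - {"control", "patient"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return manifest


def write_partition(labels, path: str | Path) -> None:
    frame = pd.DataFrame({"region_id": np.arange(len(labels)), "network": list(labels)})
    frame.to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> tuple[str, ...]:
    frame = pd.read_csv(path, sep="\t").sort_values("region_id")
    return tuple(frame["network"])


def write_coords(coords: pd.DataFrame, path: str | Path) -> None:
    coords.to_csv(path, sep="\t", index=False)


def read_coords(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("region_id", "x", "y", "z"):
        if col not in frame.columns:
            raise ValueError(f"coordinates file missing column {col!r}")
    return frame.sort_values("region_id").reset_index(drop=True)


def write_gmt(sets: Mapping[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line[:60]!r}")
            sets[parts[0]] = parts[2:]
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
        fh.write("\n")
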