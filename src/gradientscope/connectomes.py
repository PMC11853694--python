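"""Subject-level connectivity matrices: functional (FC) and morphometric (MSN).

FC is the Pearson correlation of region time series.  The MSN correlates
pairs of z-scored five-feature morphometric profiles (volume, thickness,
area, intrinsic and mean curvature).  Diagonals are stored as zero so that
downstream row-thresholding never selects self-connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConnectivityMatrix", "fc_matrix", "msn_matrix"]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region weights in [-1, 1] with zero diagonal."""

    values: np.ndarray
    kind: str  # "FC" or "MSN"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {vals.shape}")
        if not np.isfinite(vals).all():
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.abs(vals - vals.T).max() > 1e-10:
            raise ValueError("connectivity matrix is not symmetric")
        if np.abs(np.diag(vals)).max() != 0.0:
            raise ValueError("connectivity matrix diagonal must be exactly zero")
        if np.abs(vals).max() > 1.0:
            raise ValueError("connectivity entries must lie in [-1, 1]")
        if self.kind not in ("FC", "MSN"):
            raise ValueError(f"kind must be 'FC' or 'MSN', got {self.kind!r}")
        self.values = vals

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def _corr_rows(rows: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(rows)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return corr


def fc_matrix(series, subject_id: str | None = None) -> ConnectivityMatrix:
    """Pearson-correlation functional connectivity from region x timepoint series."""
    if isinstance(series, pd.DataFrame):
        region_names = list(series.index)
        values = series.to_numpy(dtype=float)
    else:
        values = np.asarray(series, dtype=float)
        region_names = list(range(values.shape[0]))
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValueError("series must be region x timepoint with >= 3 timepoints")
    sd = values.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"zero-variance time series for region(s) {[region_names[i] for i in flat]}")
    return ConnectivityMatrix(_corr_rows(values), "FC", subject_id)


def msn_matrix(features, subject_id: str | None = None) -> ConnectivityMatrix:
    """Morphometric similarity: correlation of z-scored feature profiles.

    Each feature column is z-scored across regions first, so the result is
    invariant to affine rescaling of any single feature.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        values = features.to_numpy(dtype=float)
    else:
        values = np.asarray(features, dtype=float)
        names = list(range(values.shape[1])) if values.ndim == 2 else []
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("features must be region x feature with >= 2 regions")
    if not np.isfinite(values).all():
        raise ValueError("morphometry table contains missing or non-finite values")
    sd = values.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant feature column(s): {[names[i] for i in flat]}")
    z = (values - values.mean(axis=0)) / sd
    return ConnectivityMatrix(_corr_rows(z), "MSN", subject_id)
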