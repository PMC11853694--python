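"""Synthetic cohorts with the statistical structure a gradient analysis assumes.

The generator emulates a two-group resting-state study: each cortical region
carries a latent coordinate ``g`` on the unimodal->transmodal axis, and
region-pair functional coupling decays with latent distance plus a
within-network elevation.  The patient group's latent axis may be compressed
(multiplied by a factor < 1) and shifted per network, which is the ground
truth every downstream stage is tested against.  Morphometry, spatially
autocorrelated gene expression and gene sets are generated from the same
latent geometry so the full pipeline runs without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NETWORK_LABELS",
    "FEATURE_NAMES",
    "InvalidSpecError",
    "SyntheticSpec",
    "NetworkPartition",
    "Cohort",
    "MorphometryCohort",
    "make_partition",
    "region_coords",
    "latent_axis",
    "population_correlation",
    "simulate_timeseries_cohort",
    "simulate_morphometry_cohort",
    "features_from_profile",
    "simulate_expression",
    "make_gene_sets",
]

#: Seven canonical resting-state systems (Yeo-style labels).
NETWORK_LABELS = (
    "visual",
    "sensorimotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)

#: Five morphometric features per region.
FEATURE_NAMES = (
    "gm_volume",
    "cortical_thickness",
    "surface_area",
    "intrinsic_curvature",
    "mean_curvature",
)

# Population coupling model constants: corr(i,j) = C0*exp(-|gi-gj|/ELL) + C1*[same network]
_C0 = 0.65
_C1 = 0.05
_ELL = 0.35

# Arc geometry for region coordinates (arbitrary mm-like units).
_ARC_RADIUS = 100.0

# Morphometric features are vertex averages over whole parcels, so their
# measurement noise is a fraction of the time-series noise scale.
_MORPH_NOISE_SCALE = 0.3

# Independent substreams per generator component.
_STREAMS = {
    "timeseries": 11,
    "morphometry": 12,
    "morpho_profile": 13,
    "expression": 14,
    "gene_sets": 15,
}


class InvalidSpecError(ValueError):
    """Raised when a :class:`SyntheticSpec` (or derived request) is inconsistent."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror a 400-region, seven-network resting-state study with
    72 patients and 74 controls scanned for 140 usable volumes.
    ``gradient_compression`` scales the patient group's latent axis;
    ``network_shift`` adds a per-network offset to it (ground-truth group
    effects).  ``noise_sd`` is measurement noise relative to unit-variance
    signal, shared by the time-series, morphometry and expression generators.
    """

    n_regions: int = 400
    n_networks: int = 7
    n_timepoints: int = 140
    n_patients: int = 72
    n_controls: int = 74
    gradient_compression: float = 1.0
    network_shift: Mapping[str, float] | None = None
    noise_sd: float = 1.0
    n_genes: int = 500
    n_signal_genes: int = 40
    signal_beta: float = 2.0
    sa_length_scale: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_regions": self.n_regions,
            "n_networks": self.n_networks,
            "n_timepoints": self.n_timepoints,
            "n_patients": self.n_patients,
            "n_controls": self.n_controls,
            "n_genes": self.n_genes,
            "n_signal_genes": self.n_signal_genes,
        }
        for name, value in counts.items():
            if int(value) != value or value < 2:
                raise InvalidSpecError(f"{name} must be an integer >= 2, got {value!r}")
        if not 0.0 < self.gradient_compression <= 1.0:
            raise InvalidSpecError(
                f"gradient_compression must lie in (0, 1], got {self.gradient_compression}"
            )
        if self.n_signal_genes > self.n_genes:
            raise InvalidSpecError("n_signal_genes cannot exceed n_genes")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")
        if self.sa_length_scale <= 0:
            raise InvalidSpecError("sa_length_scale must be positive")
        if self.n_networks > len(NETWORK_LABELS):
            raise InvalidSpecError(
                f"at most {len(NETWORK_LABELS)} networks supported, got {self.n_networks}"
            )
        if self.network_shift is not None:
            unknown = set(self.network_shift) - set(NETWORK_LABELS)
            if unknown:
                raise InvalidSpecError(f"unknown network labels in network_shift: {sorted(unknown)}")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of every region to exactly one network label."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = pd.Series(self.labels).value_counts()
        if (counts < 2).any():
            small = sorted(counts[counts < 2].index)
            raise InvalidSpecError(f"every network needs >= 2 regions; too small: {small}")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def names(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.labels)
        return tuple(seen)

    def members(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.labels) == label)
        if idx.size == 0:
            raise KeyError(f"no regions carry label {label!r}")
        return idx

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": np.arange(self.n_regions), "network": list(self.labels)}
        )


def make_partition(spec: SyntheticSpec) -> NetworkPartition:
    """Contiguous, near-equal blocks of regions assigned to network labels.

    Block sizes differ by at most one (``numpy.array_split`` semantics) and the
    assignment is deterministic for a fixed spec.
    """
    if spec.n_networks > spec.n_regions:
        raise InvalidSpecError("n_networks cannot exceed n_regions")
    blocks = np.array_split(np.arange(spec.n_regions), spec.n_networks)
    labels = [""] * spec.n_regions
    for name, block in zip(NETWORK_LABELS, blocks):
        for i in block:
            labels[i] = name
    return NetworkPartition(tuple(labels))


def region_coords(spec: SyntheticSpec) -> pd.DataFrame:
    """Region centroids on a one-dimensional arc embedded in 3-D.

    Regions are spaced uniformly along a half-circle of radius 100, so
    Euclidean distance is monotone in latent-axis distance; used only for the
    spatial-autocorrelation model.
    """
    theta = np.linspace(0.0, np.pi, spec.n_regions)
    return pd.DataFrame(
        {
            "region_id": np.arange(spec.n_regions),
            "x": _ARC_RADIUS * np.cos(theta),
            "y": _ARC_RADIUS * np.sin(theta),
            "z": np.zeros(spec.n_regions),
        }
    )


def latent_axis(spec: SyntheticSpec) -> np.ndarray:
    """Control-group latent coordinate per region, uniform on [-1, 1]."""
    return np.linspace(-1.0, 1.0, spec.n_regions)


def _patient_axis(spec: SyntheticSpec, g: np.ndarray, partition: NetworkPartition) -> np.ndarray:
    shift = spec.network_shift or {}
    offsets = np.array([shift.get(lab, 0.0) for lab in partition.labels])
    return g * spec.gradient_compression + offsets


def _nearest_corr(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at a small positive floor and the diagonal is
    rescaled to one (one-step Higham-style projection; adequate because the
    input is already close to PSD).
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, 1e-8, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def population_correlation(
    g: np.ndarray, partition: NetworkPartition, c0: float = _C0, c1: float = _C1, ell: float = _ELL
) -> np.ndarray:
    """Population region-pair correlation implied by a latent axis.

    ``corr(i, j) = c0 * exp(-|g_i - g_j| / ell) + c1 * [same network]``,
    projected to the nearest valid correlation matrix.
    """
    labels = np.asarray(partition.labels)
    same = (labels[:, None] == labels[None, :]).astype(float)
    corr = c0 * np.exp(-np.abs(g[:, None] - g[None, :]) / ell) + c1 * same
    np.fill_diagonal(corr, 1.0)
    return _nearest_corr(corr)


@dataclass
class CohortTruth:
    """Ground truth planted by the generator, for recovery tests."""

    latent_control: np.ndarray
    latent_patient: np.ndarray
    network_diff: dict[str, float]  # control minus patient mean latent score


@dataclass
class Cohort:
    spec: SyntheticSpec
    partition: NetworkPartition
    manifest: pd.DataFrame  # subject_id, group
    series: dict[str, np.ndarray]  # subject_id -> (n_regions, n_timepoints)
    truth: CohortTruth


def simulate_timeseries_cohort(
    spec: SyntheticSpec, partition: NetworkPartition | None = None
) -> Cohort:
    """Draw per-subject region x timepoint series for both groups.

    Each subject's series is multivariate Gaussian with the group's population
    correlation (controls: latent axis ``g``; patients: compressed/shifted
    axis), plus independent ``noise_sd`` white noise per sample.  No temporal
    autocorrelation is modelled: the downstream embedding depends only on the
    correlation structure.
    """
    if spec.n_timepoints < 3:
        raise InvalidSpecError("n_timepoints must be >= 3")
    if partition is None:
        partition = make_partition(spec)
    g = latent_axis(spec)
    g_pat = _patient_axis(spec, g, partition)

    rng = _rng(spec.seed, "timeseries")
    series: dict[str, np.ndarray] = {}
    rows = []
    for group, axis, n_sub, tag in (
        ("control", g, spec.n_controls, "con"),
        ("patient", g_pat, spec.n_patients, "pat"),
    ):
        corr = population_correlation(axis, partition)
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(spec.n_regions))
        for s in range(n_sub):
            sid = f"{tag}_{s:03d}"
            signal = chol @ rng.standard_normal((spec.n_regions, spec.n_timepoints))
            noise = spec.noise_sd * rng.standard_normal(signal.shape)
            series[sid] = signal + noise
            rows.append({"subject_id": sid, "group": group})

    diff = {
        lab: float(np.mean(g[partition.members(lab)]) - np.mean(g_pat[partition.members(lab)]))
        for lab in partition.names
    }
    manifest = pd.DataFrame(rows)
    return Cohort(spec, partition, manifest, series, CohortTruth(g, g_pat, diff))


def features_from_profile(
    profile: np.ndarray, loadings: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Morphometric features = latent profile @ loadings + white noise."""
    profile = np.asarray(profile, dtype=float)
    base = profile @ loadings
    return base + noise_sd * rng.standard_normal(base.shape)


@dataclass
class MorphometryCohort:
    spec: SyntheticSpec
    partition: NetworkPartition
    manifest: pd.DataFrame
    features: dict[str, pd.DataFrame]  # subject_id -> region x 5 features
    truth: CohortTruth


def simulate_morphometry_cohort(
    spec: SyntheticSpec, partition: NetworkPartition | None = None
) -> MorphometryCohort:
    """Per-subject region x 5 morphometry tables from a smooth latent profile.

    Each region's profile is (latent axis coordinate, secondary smooth field);
    five features are fixed linear combinations of the profile plus subject
    noise, so regions close on the latent axis carry similar feature vectors.
    Patient regions use the compressed/shifted axis, planting the same group
    effect as the time-series generator.
    """
    if partition is None:
        partition = make_partition(spec)
    g = latent_axis(spec)
    g_pat = _patient_axis(spec, g, partition)

    prof_rng = _rng(spec.seed, "morpho_profile")
    coords = region_coords(spec)[["x", "y", "z"]].to_numpy()
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = np.exp(-dist / spec.sa_length_scale)
    secondary = np.linalg.cholesky(cov + 1e-8 * np.eye(spec.n_regions)) @ prof_rng.standard_normal(
        spec.n_regions
    )
    # unit-norm loadings mixing the two profile axes at staggered angles, so
    # every feature carries comparable signal
    angles = (np.arange(len(FEATURE_NAMES)) + 0.5) * np.pi / len(FEATURE_NAMES)
    loadings = np.vstack([np.cos(angles), np.sin(angles)])

    def profile_for(axis: np.ndarray) -> np.ndarray:
        # two-axis latent profile: the group axis plus an offset, damped smooth
        # secondary field.  The offset keeps the profile direction away from
        # the origin, so feature-vector similarity decays smoothly with
        # latent-axis distance instead of flipping sign
        return np.column_stack([axis, 1.0 + 0.4 * secondary])

    rng = _rng(spec.seed, "morphometry")
    features: dict[str, pd.DataFrame] = {}
    rows = []
    for group, axis, n_sub, tag in (
        ("control", g, spec.n_controls, "con"),
        ("patient", g_pat, spec.n_patients, "pat"),
    ):
        profile = profile_for(axis)
        for s in range(n_sub):
            sid = f"{tag}_{s:03d}"
            vals = features_from_profile(profile, loadings, _MORPH_NOISE_SCALE * spec.noise_sd, rng)
            features[sid] = pd.DataFrame(
                vals, columns=list(FEATURE_NAMES), index=pd.RangeIndex(spec.n_regions, name="region_id")
            )
            rows.append({"subject_id": sid, "group": group})

    diff = {
        lab: float(np.mean(g[partition.members(lab)]) - np.mean(g_pat[partition.members(lab)]))
        for lab in partition.names
    }
    return MorphometryCohort(
        spec, partition, pd.DataFrame(rows), features, CohortTruth(g, g_pat, diff)
    )


def _sa_factor(spec: SyntheticSpec) -> np.ndarray:
    coords = region_coords(spec)[["x", "y", "z"]].to_numpy()
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = np.exp(-dist / spec.sa_length_scale)
    return np.linalg.cholesky(cov + 1e-8 * np.eye(spec.n_regions))


def simulate_expression(
    spec: SyntheticSpec, true_diff_map: np.ndarray
) -> tuple[pd.DataFrame, list[str]]:
    """Region x gene expression with a planted subset tracking the group map.

    Signal genes are ``signal_beta * standardized(true_diff_map)`` plus
    ``noise_sd`` x a spatially autocorrelated Gaussian field (exponential
    covariance over the arc coordinates); the remaining genes are unit-scale
    fields of the same family.  Columns are z-scored.  Returns the expression
    table (gene symbols in the header) and the planted signal gene symbols.
    """
    true_diff_map = np.asarray(true_diff_map, dtype=float)
    if true_diff_map.shape != (spec.n_regions,):
        raise InvalidSpecError(
            f"true_diff_map must have length n_regions={spec.n_regions}, got {true_diff_map.shape}"
        )
    if np.std(true_diff_map) == 0:
        raise InvalidSpecError("true_diff_map is constant; no group difference to encode")

    target = (true_diff_map - true_diff_map.mean()) / true_diff_map.std()
    rng = _rng(spec.seed, "expression")
    chol = _sa_factor(spec)
    fields = chol @ rng.standard_normal((spec.n_regions, spec.n_genes))

    symbols = [f"GENE{i:04d}" for i in range(spec.n_genes)]
    signal_idx = np.sort(rng.choice(spec.n_genes, size=spec.n_signal_genes, replace=False))
    expr = fields.copy()
    expr[:, signal_idx] = spec.signal_beta * target[:, None] + spec.noise_sd * fields[:, signal_idx]
    expr = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=1)

    frame = pd.DataFrame(expr, columns=symbols, index=pd.RangeIndex(spec.n_regions, name="region_id"))
    return frame, [symbols[i] for i in signal_idx]


def make_gene_sets(
    signal_ids: Sequence[str],
    universe: Sequence[str],
    n_sets: int,
    set_size: int,
    seed: int,
) -> dict[str, list[str]]:
    """Gene sets for enrichment: one planted pathway plus random sets.

    The first set (``signal_pathway``) contains every planted signal gene,
    padded with random genes up to ``set_size``; remaining sets are uniform
    draws from the universe.
    """
    universe = list(dict.fromkeys(universe))
    signal_ids = list(dict.fromkeys(signal_ids))
    if n_sets < 1:
        raise InvalidSpecError("n_sets must be >= 1")
    if set_size > len(universe):
        raise InvalidSpecError("set_size cannot exceed the universe size")
    if len(signal_ids) > set_size:
        raise InvalidSpecError("set_size too small to hold all signal genes")
    missing = set(signal_ids) - set(universe)
    if missing:
        raise InvalidSpecError(f"signal genes not in universe: {sorted(missing)[:5]}")

    rng = np.random.default_rng([int(seed), _STREAMS["gene_sets"]])
    sets: dict[str, list[str]] = {}
    non_signal = [gene for gene in universe if gene not in set(signal_ids)]
    pad = rng.choice(len(non_signal), size=set_size - len(signal_ids), replace=False)
    sets["signal_pathway"] = sorted(signal_ids) + sorted(non_signal[i] for i in pad)
    for k in range(1, n_sets):
        pick = rng.choice(len(universe), size=set_size, replace=False)
        sets[f"random_set_{k:03d}"] = sorted(universe[i] for i in pick)
    return sets
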