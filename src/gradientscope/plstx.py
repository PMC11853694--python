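"""PLS association of a group-difference z-map with regional gene expression.

Single-response (PLS1) regression extracts components whose expression
scores maximally covary with the z-map.  Significance uses a spatial-
autocorrelation-preserving permutation null: surrogate maps are permutations
of the z-map values rank-matched to smooth Gaussian fields whose binned
variogram matches the observed map.  Gene contributions are summarized by
bootstrap-corrected weights (weight / bootstrap SE) and VIP scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PlsResult",
    "SurrogateEnsemble",
    "PermutationTestResult",
    "BootstrapResult",
    "pls_fit",
    "score_map_correlation",
    "surrogate_maps",
    "sa_permutation_test",
    "bootstrap_gene_weights",
    "vip_scores",
    "rank_genes",
]


def _as_y(y) -> np.ndarray:
    if isinstance(y, pd.DataFrame):
        col = "z" if "z" in y.columns else y.columns[-1]
        return y[col].to_numpy(dtype=float)
    return np.asarray(y, dtype=float).ravel()


def _as_x(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


@dataclass
class PlsResult:
    """Fitted PLS1 model: weights, region scores, and variance explained."""

    x_weights: np.ndarray  # genes x components (unit-norm per component)
    scores: np.ndarray  # regions x components (orthogonal)
    y_loadings: np.ndarray  # per-component regression of y on the score
    r2_y: np.ndarray  # per-component fraction of y variance
    r2_y_cumulative: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r2_y_cumulative) < -1e-10):
            raise ValueError("cumulative r2 must be nondecreasing")
        if self.r2_y_cumulative[-1] > 1 + 1e-9:
            raise ValueError("cumulative r2 cannot exceed 1")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _standardize(a: np.ndarray, axis: int = 0) -> np.ndarray:
    sd = a.std(axis=axis, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance column encountered during standardization")
    return (a - a.mean(axis=axis, keepdims=True)) / sd


def pls_fit(X, y, n_components: int = 2) -> PlsResult:
    """Deflation-based PLS1 of a standardized z-map on standardized expression.

    Component weights are ``X_d^T y_d`` normalized (the closed-form solution
    for a single response); ``X`` and ``y`` are deflated by each component's
    score.  ``r2_y`` is obtained by regressing y on the cumulative scores.
    """
    x_raw, names = _as_x(X)
    y_vec = _as_y(y)
    n_regions, n_genes = x_raw.shape
    if y_vec.shape[0] != n_regions:
        raise ValueError("X and y must cover the same regions")
    if n_regions < n_components + 2:
        raise ValueError("need at least n_components + 2 regions")

    xd = _standardize(x_raw)
    yz = _standardize(y_vec[:, None]).ravel()
    yd = yz.copy()

    weights = np.zeros((n_genes, n_components))
    scores = np.zeros((n_regions, n_components))
    loadings_y = np.zeros(n_components)
    for k in range(n_components):
        w = xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(f"X has rank < {n_components}: no covariance left at component {k + 1}")
        w /= norm
        t = xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise ValueError(f"degenerate score at component {k + 1}")
        p = xd.T @ t / tt
        c = float(yd @ t) / tt
        xd = xd - np.outer(t, p)
        yd = yd - c * t
        weights[:, k], scores[:, k], loadings_y[k] = w, t, c

    # r2 of y on the cumulative scores (scores are orthogonal, but solve anyway)
    ss_tot = float(yz @ yz)
    r2_cum = np.zeros(n_components)
    for k in range(n_components):
        coef, *_ = np.linalg.lstsq(scores[:, : k + 1], yz, rcond=None)
        resid = yz - scores[:, : k + 1] @ coef
        r2_cum[k] = 1.0 - float(resid @ resid) / ss_tot
    r2 = np.diff(np.concatenate([[0.0], r2_cum]))
    return PlsResult(weights, scores, loadings_y, r2, r2_cum, names)


def score_map_correlation(result: PlsResult, y) -> np.ndarray:
    """Pearson correlation of each component's region scores with the map."""
    y_vec = _as_y(y)
    return np.array(
        [float(np.corrcoef(result.scores[:, k], y_vec)[0, 1]) for k in range(result.n_components)]
    )


def _variogram_setup(coords: pd.DataFrame | np.ndarray, n_bins: int):
    if isinstance(coords, pd.DataFrame):
        xyz = coords[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        xyz = np.asarray(coords, dtype=float)
    dist = squareform(pdist(xyz))
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, 1)
    dvec = dist[iu, ju]
    edges = np.linspace(0.0, dvec.max(), n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, dvec, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    counts[counts == 0] = np.nan
    return dist, iu, ju, bin_idx, counts


def _binned_variogram(values, iu, ju, bin_idx, counts, n_bins):
    sq = (values[iu] - values[ju]) ** 2
    return 0.5 * np.bincount(bin_idx, weights=sq, minlength=n_bins) / counts


@dataclass
class SurrogateEnsemble:
    """Spatial-autocorrelation-preserving permutations of a brain map."""

    maps: np.ndarray  # n_surrogates x regions
    method: str
    variogram_obs: np.ndarray
    variogram_error: np.ndarray  # mean relative error per surrogate
    length_scales: np.ndarray  # matched length scale per surrogate


def surrogate_maps(
    y,
    coords,
    n: int,
    seed: int = 0,
    n_bins: int = 10,
    n_candidates: int = 20,
    n_draws: int = 3,
) -> SurrogateEnsemble:
    """Variogram-matched permutations of a map's values.

    Each surrogate permutes the observed values by rank-matching them to a
    Gaussian field drawn from an exponential-covariance family over the
    region coordinates; among a grid of candidate length scales (including a
    near-white one), the field whose rank-matched permutation best matches
    the map's 10-bin empirical variogram is kept.  The value multiset is
    preserved exactly by construction.
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    y_vec = _as_y(y)
    dist, iu, ju, bin_idx, counts = _variogram_setup(coords, n_bins)
    if dist.shape[0] != y_vec.shape[0]:
        raise ValueError("coordinates must cover all regions of the map")
    gamma_obs = _binned_variogram(y_vec, iu, ju, bin_idx, counts, n_bins)
    denom = np.where(np.isnan(gamma_obs) | (gamma_obs == 0), np.nan, gamma_obs)

    dmax = dist.max()
    positive = dist[dist > 0]
    ls_grid = np.concatenate(
        [[positive.min() / 10.0], np.geomspace(positive.min(), 2.0 * dmax, n_candidates - 1)]
    )
    n_regions = y_vec.shape[0]
    rng = np.random.default_rng(seed)
    sorted_y = np.sort(y_vec)

    def rank_matched(field: np.ndarray) -> np.ndarray:
        surr = np.empty(n_regions)
        surr[np.argsort(field)] = sorted_y
        return surr

    def rel_err(surr: np.ndarray) -> float:
        gamma = _binned_variogram(surr, iu, ju, bin_idx, counts, n_bins)
        return float(np.nanmean(np.abs(gamma - gamma_obs) / denom))

    factors = []
    for ls in ls_grid:
        cov = np.exp(-dist / ls)
        factors.append(np.linalg.cholesky(cov + 1e-8 * np.eye(n_regions)))

    # per surrogate: rank-match a few random draws at every candidate
    # smoothness and keep the permutation whose realized variogram best
    # matches the map's (iterative re-ordering against smoothed fields)
    maps = np.empty((n, n_regions))
    errors = np.empty(n)
    scales = np.empty(n)
    for s in range(n):
        best_err, best_map, best_ls = np.inf, None, np.nan
        for _ in range(n_draws):
            z = rng.standard_normal(n_regions)
            for ls, factor in zip(ls_grid, factors):
                surr = rank_matched(factor @ z)
                err = rel_err(surr)
                if err < best_err:
                    best_err, best_map, best_ls = err, surr, ls
        maps[s], errors[s], scales[s] = best_map, best_err, best_ls
    return SurrogateEnsemble(maps, "variogram_matched_permutation", gamma_obs, errors, scales)


@dataclass
class PermutationTestResult:
    perm_p: np.ndarray  # per component
    observed_r2: np.ndarray  # cumulative r2 per component
    null_r2: np.ndarray  # n_perm x components, cumulative


def sa_permutation_test(
    X,
    y,
    coords,
    n_components: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation p per component against the spatially matched null.

    ``perm_p(k) = (1 + #{surrogates with cumulative r2(k) >= observed}) /
    (n_perm + 1)``, so p-values are never zero.
    """
    observed = pls_fit(X, y, n_components=n_components).r2_y_cumulative
    ensemble = surrogate_maps(y, coords, n_perm, seed=seed)
    null = np.empty((n_perm, n_components))
    for s in range(n_perm):
        null[s] = pls_fit(X, ensemble.maps[s], n_components=n_components).r2_y_cumulative
    exceed = (null >= observed[None, :] - 1e-12).sum(axis=0)
    perm_p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationTestResult(perm_p, observed, null)


@dataclass
class BootstrapResult:
    boot_z: np.ndarray  # genes x components
    weights: np.ndarray  # original weights, genes x components
    gene_names: list[str]
    n_dropped: int


def bootstrap_gene_weights(
    X,
    y,
    n_components: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap-corrected gene weights: original weight / bootstrap SE.

    Regions are resampled with replacement; each refit's weights are
    sign-aligned to the original fit by the dot-product rule (PLS weights are
    sign-indeterminate).  Replicates with a degenerate resample (a gene
    column constant in the resample) are dropped; more than 10% drops is an
    error.
    """
    x_raw, names = _as_x(X)
    y_vec = _as_y(y)
    base = pls_fit(x_raw, y_vec, n_components=n_components)
    n_regions = x_raw.shape[0]

    rng = np.random.default_rng(seed)
    reps = []
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_regions, size=n_regions)
        try:
            fit = pls_fit(x_raw[idx], y_vec[idx], n_components=n_components)
        except ValueError:
            dropped += 1
            continue
        w = fit.x_weights.copy()
        for k in range(n_components):
            if float(w[:, k] @ base.x_weights[:, k]) < 0:
                w[:, k] = -w[:, k]
        reps.append(w)
    if dropped > 0.10 * n_boot:
        raise ValueError(f"{dropped}/{n_boot} bootstrap replicates degenerate")
    stack = np.stack(reps)
    se = stack.std(axis=0, ddof=1)
    if np.any(se == 0):
        raise ValueError("zero bootstrap SE: resampling produced identical weights")
    return BootstrapResult(base.x_weights / se, base.x_weights, names, dropped)


def rank_genes(boot: BootstrapResult, component: int = 1) -> list[str]:
    """Gene symbols ordered by descending |bootstrap-corrected weight|."""
    z = np.abs(boot.boot_z[:, component - 1])
    order = np.argsort(-z, kind="stable")
    return [boot.gene_names[i] for i in order]


def vip_scores(result: PlsResult, threshold: float = 1.0) -> tuple[np.ndarray, list[str]]:
    """Variable influence on projection, and genes selected at VIP > threshold.

    ``VIP_j = sqrt( p * sum_k SSY_k (w_jk / ||w_k||)^2 / sum_k SSY_k )`` with
    ``p`` the gene count and ``SSY_k`` the y-variance explained by component
    ``k``; the squared VIPs average to one across genes.
    """
    ssy = result.r2_y
    if np.all(ssy <= 0):
        raise ValueError("no y-variance explained; VIP undefined")
    w = result.x_weights
    wnorm2 = (w**2).sum(axis=0)
    contrib = (w**2) / wnorm2
    p = w.shape[0]
    vip = np.sqrt(p * (contrib * ssy).sum(axis=1) / ssy.sum())
    selected = [g for g, v in zip(result.gene_names, vip) if v > threshold]
    return vip, selected
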