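"""Connectivity gradients: sparsify -> cosine affinity -> diffusion map -> alignment.

The embedding follows the diffusion-map convention: the affinity is
anisotropically normalized (``alpha`` exponent on the degree), converted to a
Markov operator, and eigendecomposed through its symmetric conjugate for a
guaranteed real spectrum.  The trivial constant eigenvector is dropped and
component ``k`` is scaled by ``lambda_k / (1 - lambda_k)`` at diffusion time
zero.  Individual embeddings are brought into register with iterative
(generalized) Procrustes rotation against a group template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectomes import ConnectivityMatrix

__all__ = [
    "AffinityMatrix",
    "GradientSet",
    "sparsify_rows",
    "cosine_affinity",
    "diffusion_embed",
    "embed_connectivity",
    "group_template",
    "procrustes_align",
    "mean_embedding",
]


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative region x region affinity with zero diagonal."""

    values: np.ndarray
    provenance: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"affinity must be square, got {vals.shape}")
        if np.abs(vals - vals.T).max() > 1e-10:
            raise ValueError("affinity must be symmetric")
        if vals.min() < 0 or vals.max() > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        if np.abs(np.diag(vals)).max() != 0.0:
            raise ValueError("affinity diagonal must be zero")
        self.values = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Region x component embedding with eigenvalues and variance fractions."""

    embedding: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    aligned: bool = False
    reference_id: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        emb = np.asarray(self.embedding, dtype=float)
        lams = np.asarray(self.eigenvalues, dtype=float)
        frac = np.asarray(self.variance_fraction, dtype=float)
        if emb.ndim != 2 or emb.shape[1] < 2:
            raise ValueError("embedding must be region x component with >= 2 components")
        if lams.shape != (emb.shape[1],) or frac.shape != (emb.shape[1],):
            raise ValueError("eigenvalues/variance fractions must match component count")
        if np.any(np.diff(lams) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")
        if frac.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must sum to <= 1")
        self.embedding, self.eigenvalues, self.variance_fraction = emb, lams, frac

    @property
    def n_components(self) -> int:
        return self.embedding.shape[1]


def _as_array(mat) -> np.ndarray:
    if isinstance(mat, ConnectivityMatrix):
        return mat.values
    if isinstance(mat, AffinityMatrix):
        return mat.values
    return np.asarray(mat, dtype=float)


def sparsify_rows(mat, density: float = 0.10) -> np.ndarray:
    """Keep the top ``density`` fraction of off-diagonal entries in each row.

    Per row, the ``k = ceil(density * (N - 1))`` largest off-diagonal values
    are retained with their signed values; everything else is zeroed.  Ties at
    the threshold are broken by value, then lower region index, so the result
    is deterministic.  The output is generally asymmetric.
    """
    values = _as_array(mat)
    n = values.shape[0]
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    k = math.ceil(density * (n - 1))
    if k < 1:
        raise ValueError(f"density {density} retains no connections for {n} regions")

    out = np.zeros_like(values)
    idx = np.arange(n)
    for i in range(n):
        row = values[i].copy()
        row[i] = -np.inf  # never select the self-connection
        order = np.lexsort((idx, -row))  # value desc, then index asc
        keep = order[:k]
        out[i, keep] = values[i, keep]
    return out


def cosine_affinity(sparse_mat) -> AffinityMatrix:
    """Nonnegative cosine similarity of connectivity profiles.

    Entry (i, j) is ``max(0, cos(row_i, row_j))`` of the (row-sparsified)
    connectivity profiles; negative cosines are clipped so the affinity stays
    a valid nonnegative kernel.
    """
    rows = _as_array(sparse_mat)
    norms = np.linalg.norm(rows, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"all-zero connectivity profile for region(s) {zero.tolist()}")
    cos = (rows @ rows.T) / np.outer(norms, norms)
    cos = np.clip((cos + cos.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(cos, 0.0)
    return AffinityMatrix(cos)


def diffusion_embed(
    aff,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0,
    subject_id: str | None = None,
) -> GradientSet:
    """Diffusion map embedding of an affinity matrix.

    The affinity is renormalized as ``W' = D^-alpha W D^-alpha``, turned into
    the Markov operator ``P`` (row-normalized), and eigendecomposed through
    the symmetric conjugate ``S = D'^-1/2 W' D'^-1/2``.  The constant
    eigenvector at ``lambda = 1`` is dropped; gradient ``k`` is eigenvector
    ``k`` scaled by ``lambda_k / (1 - lambda_k)`` (diffusion time 0) or
    ``lambda_k ** t`` otherwise.  Variance fractions are eigenvalue ratios
    over the retained components.

    Eigenvectors follow the diffusion-map normalization: unit norm in the
    stationary-distribution inner product, which makes the trivial
    eigenvector exactly the all-ones vector.
    """
    w = _as_array(aff)
    n = w.shape[0]
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    if n_components + 1 > n:
        raise ValueError(f"n_components={n_components} too large for {n} regions")

    n_comp, comp_labels = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp_labels).tolist()
        raise ValueError(f"affinity graph is disconnected (component sizes {sizes})")

    d = w.sum(axis=1)
    w_aniso = w / np.outer(d**alpha, d**alpha)
    d_prime = w_aniso.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d_prime)
    sym = w_aniso * np.outer(inv_sqrt, inv_sqrt)
    lams, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
    order = np.argsort(lams)[::-1]
    lams, vecs = lams[order], vecs[:, order]

    if np.count_nonzero(np.abs(lams) > 1e-12) < n_components + 1:
        raise ValueError(
            f"affinity spectrum has fewer than {n_components + 1} nonzero eigenvalues"
        )

    lams = np.clip(lams, -1.0, 1.0)
    phi = vecs * inv_sqrt[:, None]  # right eigenvectors of P
    psi = phi / phi[:, :1]  # trivial eigenvector becomes all-ones
    retained = lams[1 : n_components + 1]
    if diffusion_time == 0:
        scale = retained / (1.0 - np.clip(retained, None, 1.0 - 1e-12))
    else:
        scale = retained**diffusion_time
    embedding = psi[:, 1 : n_components + 1] * scale
    variance = retained / retained.sum()
    return GradientSet(embedding, retained, variance, subject_id=subject_id)


def embed_connectivity(
    mat,
    density: float = 0.10,
    n_components: int = 10,
    alpha: float = 0.5,
    subject_id: str | None = None,
) -> GradientSet:
    """Full per-subject pipeline: sparsify rows, cosine affinity, diffusion map."""
    sid = subject_id
    if sid is None and isinstance(mat, ConnectivityMatrix):
        sid = mat.subject_id
    aff = cosine_affinity(sparsify_rows(mat, density))
    return diffusion_embed(aff, n_components=n_components, alpha=alpha, subject_id=sid)


def group_template(
    mats: list,
    density: float = 0.10,
    n_components: int = 10,
    alpha: float = 0.5,
    orient: bool = True,
) -> GradientSet:
    """Template gradients from the element-wise mean connectivity matrix.

    The mean is taken over all supplied subjects (both groups), so alignment
    treats the groups symmetrically.  With ``orient`` (default), each template
    gradient is flipped to correlate positively with region index — a fixed
    sign convention (eigenvector signs are arbitrary) that individual
    embeddings inherit through alignment, making group-difference signs
    comparable across cohorts.
    """
    if not mats:
        raise ValueError("need at least one connectivity matrix")
    mean = np.mean([_as_array(m) for m in mats], axis=0)
    template = embed_connectivity(mean, density=density, n_components=n_components, alpha=alpha)
    if orient:
        emb = template.embedding.copy()
        idx = np.arange(emb.shape[0]) - (emb.shape[0] - 1) / 2.0
        for k in range(emb.shape[1]):
            if float((emb[:, k] - emb[:, k].mean()) @ idx) < 0:
                emb[:, k] = -emb[:, k]
        template = _dc_replace(template, embedding=emb)
    return _dc_replace(template, subject_id="template")


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def procrustes_align(
    gradient_sets: list[GradientSet],
    reference: GradientSet,
    n_iter: int = 10,
    tol: float = 1e-8,
) -> list[GradientSet]:
    """Iterative Procrustes alignment of embeddings to a reference.

    Each embedding is column-centered and rotated (orthogonal transform, no
    scaling) to the current reference in the least-squares sense; the
    reference is replaced by the mean of the aligned embeddings each
    iteration, until ``n_iter`` iterations or mean squared reference change
    below ``tol``.  Finally each aligned column's sign is fixed so it
    correlates nonnegatively with the reference column.
    """
    shapes = {gs.embedding.shape for gs in gradient_sets}
    if len(shapes) > 1 or (shapes and shapes.pop() != reference.embedding.shape):
        raise ValueError("all embeddings must share the reference's shape")

    ref = _center(reference.embedding)
    centered = [_center(gs.embedding) for gs in gradient_sets]

    def rotate_all(target):
        out = []
        for x in centered:
            u, _, vt = np.linalg.svd(x.T @ target)
            out.append(x @ (u @ vt))
        return out

    for _ in range(n_iter):
        aligned = rotate_all(ref)
        new_ref = np.mean(aligned, axis=0)
        change = float(np.mean((new_ref - ref) ** 2))
        ref = new_ref
        if change < tol:
            break
    # final pass so every embedding is optimally rotated to the converged reference
    aligned = rotate_all(ref)

    out = []
    for gs, emb in zip(gradient_sets, aligned):
        emb = emb.copy()
        for k in range(emb.shape[1]):
            ref_col = ref[:, k] - ref[:, k].mean()
            if float(emb[:, k] @ ref_col) < 0:
                emb[:, k] = -emb[:, k]
        out.append(
            GradientSet(
                emb,
                gs.eigenvalues,
                gs.variance_fraction,
                aligned=True,
                reference_id=reference.subject_id or "reference",
                subject_id=gs.subject_id,
            )
        )
    return out


def mean_embedding(gradient_sets: list[GradientSet]) -> GradientSet:
    """Mean of a list of embeddings, reusing the first set's spectrum summary."""
    if not gradient_sets:
        raise ValueError("need at least one gradient set")
    emb = np.mean([gs.embedding for gs in gradient_sets], axis=0)
    first = gradient_sets[0]
    return GradientSet(emb, first.eigenvalues, first.variance_fraction, subject_id="mean")
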