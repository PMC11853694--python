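"""End-to-end convenience drivers tying the pipeline stages together.

These are thin orchestration helpers used by the analysis scripts and the
replicate simulations in the test-suite; all computation lives in the stage
modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectomes import ConnectivityMatrix, fc_matrix, msn_matrix
from .gradients import GradientSet, embed_connectivity, group_template, procrustes_align
from .synthcohort import Cohort, MorphometryCohort

__all__ = [
    "align_cohort",
    "fc_cohort_gradients",
    "msn_cohort_gradients",
    "gradient_range_by_group",
]


def align_cohort(
    matrices: dict[str, ConnectivityMatrix],
    density: float = 0.10,
    n_components: int = 10,
) -> tuple[GradientSet, dict[str, GradientSet]]:
    """Template from the mean matrix, per-subject embeddings, Procrustes alignment."""
    template = group_template(list(matrices.values()), density=density, n_components=n_components)
    raw = {
        sid: embed_connectivity(mat, density=density, n_components=n_components, subject_id=sid)
        for sid, mat in matrices.items()
    }
    aligned_list = procrustes_align(list(raw.values()), template)
    aligned = {gs.subject_id: gs for gs in aligned_list}
    return template, aligned


def fc_cohort_gradients(
    cohort: Cohort, density: float = 0.10, n_components: int = 10
) -> tuple[GradientSet, dict[str, GradientSet]]:
    """Functional-connectivity gradients for every subject of a cohort."""
    matrices = {sid: fc_matrix(series, sid) for sid, series in cohort.series.items()}
    return align_cohort(matrices, density=density, n_components=n_components)


def msn_cohort_gradients(
    cohort: MorphometryCohort, density: float = 0.10, n_components: int = 10
) -> tuple[GradientSet, dict[str, GradientSet]]:
    """Morphometric-similarity gradients for every subject of a cohort."""
    matrices = {sid: msn_matrix(feat, sid) for sid, feat in cohort.features.items()}
    return align_cohort(matrices, density=density, n_components=n_components)


def gradient_range_by_group(
    aligned: dict[str, GradientSet], manifest: pd.DataFrame, gradient: int = 1
) -> dict[str, float]:
    """Mean per-subject range (max - min) of one aligned gradient, by group."""
    group_of = dict(zip(manifest["subject_id"], manifest["group"]))
    ranges: dict[str, list[float]] = {}
    for sid, gs in aligned.items():
        col = gs.embedding[:, gradient - 1]
        ranges.setdefault(group_of[sid], []).append(float(col.max() - col.min()))
    return {group: float(np.mean(vals)) for group, vals in ranges.items()}
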