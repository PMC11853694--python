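"""Network-level group comparison of gradient scores.

Aggregates aligned gradients into per-subject network means, compares groups
with pooled two-sample t-tests (orientation: control minus patient),
corrects with Benjamini-Hochberg FDR, and reports Cohen's d together with
the analytic power of the observed effect from the noncentral t
distribution.  Also builds the region-wise z-map that feeds the
transcriptomic association stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gradients import GradientSet
from .synthcohort import NetworkPartition

__all__ = [
    "network_scores",
    "two_sample_t",
    "bh_fdr",
    "cohens_d",
    "t_test_power",
    "compare_networks",
    "zmap_from_t",
    "region_t_map",
]


def network_scores(
    aligned: dict[str, GradientSet],
    partition: NetworkPartition,
    manifest: pd.DataFrame,
    gradients: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Per-subject unweighted mean gradient score within each network.

    Returns a long table with columns ``subject_id, group, network, gradient,
    score``; ``gradient`` is 1-based (gradient 1 = principal).
    """
    group_of = dict(zip(manifest["subject_id"], manifest["group"]))
    members = {lab: partition.members(lab) for lab in partition.names}
    rows = []
    for sid, gs in aligned.items():
        if gs.embedding.shape[0] != partition.n_regions:
            raise ValueError(f"embedding for {sid} does not cover the partition")
        for grad in gradients:
            col = gs.embedding[:, grad - 1]
            for lab, idx in members.items():
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group_of[sid],
                        "network": lab,
                        "gradient": grad,
                        "score": float(col[idx].mean()),
                    }
                )
    table = pd.DataFrame(rows)
    if not np.isfinite(table["score"]).all():
        raise ValueError("non-finite network scores")
    return table


def _pooled_sd(control: np.ndarray, patient: np.ndarray) -> float:
    n1, n2 = len(control), len(patient)
    pooled_var = (
        (n1 - 1) * control.var(ddof=1) + (n2 - 1) * patient.var(ddof=1)
    ) / (n1 + n2 - 2)
    return float(np.sqrt(pooled_var))


def two_sample_t(control_scores, patient_scores) -> tuple[float, float]:
    """Pooled-variance Student t (control minus patient) and two-sided p."""
    control = np.asarray(control_scores, dtype=float)
    patient = np.asarray(patient_scores, dtype=float)
    if len(control) < 2 or len(patient) < 2:
        raise ValueError("each group needs >= 2 observations")
    if not (np.isfinite(control).all() and np.isfinite(patient).all()):
        raise ValueError("non-finite scores")
    sd = _pooled_sd(control, patient)
    if sd == 0:
        raise ValueError("zero pooled variance")
    n1, n2 = len(control), len(patient)
    se = sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    t = float((control.mean() - patient.mean()) / se)
    df = n1 + n2 - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(control_scores, patient_scores) -> float:
    """Cohen's d (control minus patient) with df-weighted pooled SD."""
    control = np.asarray(control_scores, dtype=float)
    patient = np.asarray(patient_scores, dtype=float)
    if len(control) < 2 or len(patient) < 2:
        raise ValueError("each group needs >= 2 observations")
    sd = _pooled_sd(control, patient)
    if sd == 0:
        raise ValueError("zero pooled SD")
    return float((control.mean() - patient.mean()) / sd)


def t_test_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided pooled two-sample t-test.

    Noncentrality ``delta = |d| * sqrt(n1 n2 / (n1 + n2))`` with
    ``df = n1 + n2 - 2``; power is the noncentral-t mass beyond the two-sided
    critical values.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    delta = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    # lower tail via the symmetric form; nct.cdf underflows for large delta
    power = stats.nct.sf(t_crit, df, delta) + stats.nct.sf(t_crit, df, -delta)
    return float(min(power, 1.0))


def compare_networks(
    scores: pd.DataFrame, alpha: float = 0.05, fdr_per_gradient: bool = True
) -> pd.DataFrame:
    """Group comparison per network with t, p, BH q, Cohen's d and power.

    The FDR family is one gradient x all networks (seven tests) by default.
    """
    results = []
    for grad, grad_table in scores.groupby("gradient", sort=True):
        rows = []
        for lab, net_table in grad_table.groupby("network", sort=False):
            control = net_table.loc[net_table["group"] == "control", "score"].to_numpy()
            patient = net_table.loc[net_table["group"] == "patient", "score"].to_numpy()
            t, p = two_sample_t(control, patient)
            d = cohens_d(control, patient)
            power = t_test_power(d, len(control), len(patient), alpha=alpha)
            rows.append(
                {
                    "network": lab,
                    "gradient": grad,
                    "t": t,
                    "p": p,
                    "d": d,
                    "power": power,
                    "n_control": len(control),
                    "n_patient": len(patient),
                }
            )
        frame = pd.DataFrame(rows)
        frame["q"] = bh_fdr(frame["p"].to_numpy())
        results.append(frame)
    out = pd.concat(results, ignore_index=True)
    if not fdr_per_gradient:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["network", "gradient", "t", "p", "q", "d", "power", "n_control", "n_patient"]]


def region_t_map(
    aligned: dict[str, GradientSet], manifest: pd.DataFrame, gradient: int = 1
) -> np.ndarray:
    """Region-wise pooled two-sample t (control minus patient) of one gradient."""
    group_of = dict(zip(manifest["subject_id"], manifest["group"]))
    control = np.array(
        [gs.embedding[:, gradient - 1] for sid, gs in aligned.items() if group_of[sid] == "control"]
    )
    patient = np.array(
        [gs.embedding[:, gradient - 1] for sid, gs in aligned.items() if group_of[sid] == "patient"]
    )
    return np.array(
        [two_sample_t(control[:, i], patient[:, i])[0] for i in range(control.shape[1])]
    )


def zmap_from_t(region_t) -> pd.DataFrame:
    """Standardize region-wise t-values to a z-map (sample-SD convention)."""
    t = np.asarray(region_t, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 regions")
    sd = t.std(ddof=1)
    if sd == 0:
        raise ValueError("constant t vector: z-map undefined")
    z = (t - t.mean()) / sd
    return pd.DataFrame({"region_id": np.arange(t.size), "t": t, "z": z})
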