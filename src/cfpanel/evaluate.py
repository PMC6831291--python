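"""ROC/AUROC, cross-cohort validation, cluster concordance and PCA.

The ROC curve is built over all distinct score thresholds (tied scores
collapse to a single step) and AUROC is its trapezoidal area.  With this
tie convention AUROC equals the tie-corrected Mann-Whitney U statistic
divided by n1*n0 — the probability that a random tumor sample outscores
a random nontumor sample, ties counting one half.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .data_model import BetaMatrix, CohortBundle

__all__ = ["RocCurve", "roc", "auroc", "cross_cohort_validate",
           "cluster_concordance", "pca_embed", "PCAResult"]


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def roc(scores, labels) -> RocCurve:
    """ROC curve and trapezoidal AUROC; labels coded {0, 1}."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # collapse tied scores to one threshold step
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, area)


def auroc(scores, labels) -> float:
    return roc(scores, labels).auroc


def cross_cohort_validate(panel, cohorts: Sequence[CohortBundle]
                          ) -> Dict[str, RocCurve]:
    """Score a frozen panel (no refit) in each cohort and compute ROC.

    Raises if any panel probe is absent from a cohort, naming both.
    """
    from .panel import additive_score  # local import avoids a cycle

    out: Dict[str, RocCurve] = {}
    for bundle in cohorts:
        missing = [p for p in panel.probes
                   if p not in bundle.beta.values.columns]
        if missing:
            raise KeyError(f"cohort {bundle.name!r} lacks panel probes "
                           f"{missing}")
        scores = additive_score(panel, bundle.beta)
        out[bundle.name] = roc(scores.to_numpy(), bundle.beta.labels01())
    return out


def cluster_concordance(beta: BetaMatrix, probes,
                        method: str = "average",
                        metric: str = "euclidean") -> dict:
    """Two-cluster hierarchical cut vs disease group, chi-square tested.

    Average-linkage clustering on Euclidean distance over the probe
    subset; the 2x2 cluster-by-group table is tested with a 1-df
    chi-square, no continuity correction.  A degenerate cut (empty
    cluster or zero marginal) reports chi-square 0, p 1 on the realized
    table.
    """
    probes = list(probes)
    if len(probes) < 1:
        raise ValueError("need at least one probe")
    counts = beta.group.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 samples per group")
    X = beta.values.loc[:, probes].to_numpy(dtype=float)
    Z = linkage(X, method=method, metric=metric)
    assign = fcluster(Z, t=2, criterion="maxclust")
    table = pd.crosstab(pd.Series(assign, index=beta.values.index,
                                  name="cluster"), beta.group)
    if table.shape != (2, 2) or (table.sum(0) == 0).any() or \
            (table.sum(1) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(),
                                               correction=False)
    return {"assignment": pd.Series(assign, index=beta.values.index,
                                    name="cluster"),
            "table": table, "chi_square": float(chi2), "p_value": float(p)}


@dataclass
class PCAResult:
    coordinates: pd.DataFrame       # samples x components
    loadings: pd.DataFrame          # probes x components
    explained_variance_ratio: np.ndarray


def pca_embed(beta: BetaMatrix, n_components: int = 2) -> PCAResult:
    """Column-centered SVD; components ordered by variance, the
    largest-magnitude loading of each component made positive."""
    if beta.n_samples < 2:
        raise ValueError("need >= 2 samples")
    X = beta.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    for comp in range(k):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0
    coords = U[:, :k] * S[:k]
    var = S ** 2
    ratio = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        pd.DataFrame(coords, index=beta.values.index, columns=cols),
        pd.DataFrame(Vt[:k].T, index=beta.values.columns, columns=cols),
        ratio)
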