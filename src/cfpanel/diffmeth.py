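"""Differential methylation between nontumor and tumor groups.

Per CpG, the biological effect is the group-mean difference
``delta_beta = mean(beta | tumor) - mean(beta | nontumor)`` and the
statistical evidence is a two-sided Welch two-sample t-test (unequal
variances; standard practice for 450k beta values).  An event passes the
dual cutoff when |delta_beta| exceeds the biological threshold *and* the
p-value is below the statistical threshold, both strictly.  No
multiple-testing correction is applied: the dual cutoff is a pre-filter
feeding penalized regression, not an inferential endpoint.

An M-value mode (``log2(beta / (1 - beta))`` with beta clamped to
[0.001, 0.999]) is available for the test statistic; delta_beta is always
reported on the beta scale.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BetaMatrix, ProbeAnnotation, FEATURES

__all__ = ["compute_differential", "call_events", "global_mean_profile",
           "feature_distribution", "top_variable_probes", "MAGNITUDE_BINS"]

MAGNITUDE_BINS = ("<0.05", "0.05-0.1", "0.1-0.15", "0.15-0.20", ">0.20")

_P_FLOOR = 1e-300  # p-values live in (0, 1]


def _m_values(b: np.ndarray) -> np.ndarray:
    c = np.clip(b, 0.001, 0.999)
    return np.log2(c / (1.0 - c))


def _welch(x1: np.ndarray, x0: np.ndarray):
    """Vectorized two-sided Welch t over columns; returns (t, p).

    Probes constant in both groups get p = 1 when the means agree; a
    zero-variance probe with differing means is perfectly separated and
    gets the p floor.
    """
    n1, n0 = x1.shape[0], x0.shape[0]
    m1, m0 = x1.mean(axis=0), x0.mean(axis=0)
    v1, v0 = x1.var(axis=0, ddof=1), x0.var(axis=0, ddof=1)
    se2 = v1 / n1 + v0 / n0
    degenerate = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    p = np.ones_like(t)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[degenerate & (m1 != m0)] = _P_FLOOR
    p = np.clip(p, _P_FLOOR, 1.0)
    return t, p


def _bin_magnitude(abs_delta: np.ndarray) -> np.ndarray:
    edges = [0.05, 0.1, 0.15, 0.20]
    idx = np.searchsorted(edges, abs_delta, side="right")
    return np.asarray(MAGNITUDE_BINS, dtype=object)[idx]


def compute_differential(beta: BetaMatrix, delta_cut: float = 0.1,
                         p_cut: float = 0.05,
                         use_m_values: bool = False) -> pd.DataFrame:
    """Per-probe delta_beta, Welch p-value, direction call and magnitude bin.

    Returns a DataFrame indexed by probe id with columns ``delta_beta``,
    ``p_value``, ``direction`` (``hyper``/``hypo``/``none`` under the
    dual cutoff at ``delta_cut``/``p_cut``) and ``magnitude_bin``.
    """
    tum = beta.group_values("tumor").to_numpy(dtype=float)
    non = beta.group_values("nontumor").to_numpy(dtype=float)
    if tum.shape[0] < 2 or non.shape[0] < 2:
        raise ValueError("both groups need at least 2 samples")

    delta = tum.mean(axis=0) - non.mean(axis=0)
    if use_m_values:
        _, p = _welch(_m_values(tum), _m_values(non))
    else:
        _, p = _welch(tum, non)

    direction = np.where((delta > delta_cut) & (p < p_cut), "hyper",
                         np.where((delta < -delta_cut) & (p < p_cut),
                                  "hypo", "none"))
    return pd.DataFrame({
        "delta_beta": delta,
        "p_value": p,
        "direction": direction,
        "magnitude_bin": _bin_magnitude(np.abs(delta)),
    }, index=pd.Index(beta.probe_ids, name="probe_id"))


def call_events(results: pd.DataFrame, delta_cut: float, p_cut: float,
                direction: str = "both") -> list[str]:
    """Probe ids passing the dual cutoff, strict inequalities.

    ``direction`` is ``hyper`` (delta_beta > delta_cut), ``hypo``
    (delta_beta < -delta_cut) or ``both``.
    """
    if delta_cut <= 0 or p_cut <= 0:
        raise ValueError("thresholds must be positive")
    if direction not in ("hyper", "hypo", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    sig = results["p_value"] < p_cut
    if direction == "hyper":
        mask = (results["delta_beta"] > delta_cut) & sig
    elif direction == "hypo":
        mask = (results["delta_beta"] < -delta_cut) & sig
    else:
        mask = (results["delta_beta"].abs() > delta_cut) & sig
    return list(results.index[mask])


def global_mean_profile(beta: BetaMatrix):
    """Per-sample mean beta over probes, and per-group mean of those
    sample means (the overall-methylation bar chart)."""
    if beta.n_probes == 0:
        raise ValueError("empty probe set")
    sample_means = beta.values.mean(axis=1).rename("mean_beta")
    group_means = sample_means.groupby(beta.group).mean().rename("mean_beta")
    return sample_means, group_means


def feature_distribution(events, ann: ProbeAnnotation) -> pd.Series:
    """Proportion of event probes per genic feature; sums to 1."""
    events = list(events)
    if not events:
        raise ValueError("empty event set")
    feats = ann.table.loc[events, "feature"]
    counts = feats.value_counts().reindex(FEATURES, fill_value=0)
    return (counts / counts.sum()).rename("proportion")


def top_variable_probes(beta: BetaMatrix, k: int) -> list[str]:
    """The k probes with largest across-sample variance, descending;
    ties broken lexicographically by probe id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    var = beta.values.var(axis=0, ddof=1)
    order = sorted(var.index, key=lambda p: (-var.loc[p], p))
    return order[:k]
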