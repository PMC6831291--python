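"""Greedy additive-score CpG panels.

A panel is a small ordered set of CpGs with frozen weights (the
selection-stage coefficients); a sample's diagnostic score is the
weighted sum of its beta values, s_i = sum_j w_j * beta_ij, so that a
higher score means tumor for every member (hypomethylation markers
carry negative weights).  Panels are grown by greedy forward selection:
start from the single candidate with the best individual AUROC of
w_j * beta_j, then repeatedly add the candidate that most improves the
additive score's AUROC, stopping at the size cap (default 5, guarding
against overfitting) or when no candidate improves by at least
``min_gain``.  Ties break by larger |coefficient|, then probe id.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import BetaMatrix
from .evaluate import auroc
from .selection import SelectionResult

__all__ = ["Panel", "additive_score", "greedy_panel_search",
           "combine_panels", "youden_threshold"]

log = logging.getLogger(__name__)

MAX_PANEL_SIZE = 5


@dataclass
class Panel:
    probes: list[str]
    weights: np.ndarray
    direction: str  # hyper | hypo | combined
    trace: list[float] = field(default_factory=list)  # training AUROC per step

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.probes) < 1:
            raise ValueError("panel needs at least one probe")
        if self.weights.shape[0] != len(self.probes):
            raise ValueError("weights and probes differ in length")
        if np.any(self.weights == 0.0):
            raise ValueError("panel weights must be nonzero")
        if self.trace and np.any(np.diff(self.trace) < 0):
            raise ValueError("training AUROC trace must be non-decreasing")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "probes": self.probes,
            "weights": [float(w) for w in self.weights],
            "direction": self.direction,
            "trace": [float(t) for t in self.trace],
        }, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "Panel":
        d = json.loads(Path(path).read_text())
        return cls(d["probes"], np.array(d["weights"]), d["direction"],
                   d["trace"])


def additive_score(panel: Panel, beta: BetaMatrix) -> pd.Series:
    """Per-sample weighted beta sum; errors loudly on missing probes."""
    missing = [p for p in panel.probes if p not in beta.values.columns]
    if missing:
        raise KeyError(f"panel probes missing from matrix: {missing}")
    vals = beta.values.loc[:, panel.probes].to_numpy(dtype=float)
    return pd.Series(vals @ panel.weights, index=beta.values.index,
                     name="score")


def _pool_from(candidates) -> pd.Series:
    """Nonzero candidate weights from a SelectionResult or a Series."""
    if isinstance(candidates, SelectionResult):
        weights = candidates.weights()
    else:
        weights = pd.Series(candidates, dtype=float)
    weights = weights[weights != 0.0]
    if weights.empty:
        raise ValueError("empty candidate set (no nonzero weights)")
    return weights


def greedy_panel_search(candidates, beta: BetaMatrix,
                        max_size: int = MAX_PANEL_SIZE,
                        min_gain: float = 0.0,
                        direction: str | None = None) -> Panel:
    """Greedy forward search maximizing training AUROC of the additive
    score.  ``candidates`` is a SelectionResult or a probe -> weight
    mapping."""
    weights = _pool_from(candidates)
    if direction is None:
        direction = getattr(candidates, "direction", "combined")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    y = beta.labels01()
    X = beta.values.loc[:, list(weights.index)]

    def panel_auroc(probe_list) -> float:
        s = X.loc[:, probe_list].to_numpy() @ weights.loc[probe_list].to_numpy()
        return auroc(s, y)

    def sort_key(p):  # ties: larger |coefficient|, then probe id
        return (-abs(weights.loc[p]), p)

    # candidates pre-sorted by the tie-break order, so every argmax scan
    # below resolves ties by larger |coefficient|, then probe id
    remaining = sorted(weights.index, key=sort_key)
    indiv = {p: panel_auroc([p]) for p in remaining}
    best_val = max(indiv.values())
    seed = next(p for p in remaining if indiv[p] == best_val)

    chosen = [seed]
    trace = [indiv[seed]]
    remaining = [p for p in remaining if p != seed]
    while remaining and len(chosen) < max_size:
        gains = {p: panel_auroc(chosen + [p]) for p in remaining}
        best_val = max(gains.values())
        if best_val - trace[-1] < min_gain:
            break
        pick = next(p for p in remaining if gains[p] == best_val)
        if best_val < trace[-1]:  # never let the trace decrease
            break
        chosen.append(pick)
        trace.append(best_val)
        remaining.remove(pick)
    return Panel(chosen, weights.loc[chosen].to_numpy(), direction, trace)


def combine_panels(hyper: SelectionResult, hypo: SelectionResult,
                   beta: BetaMatrix, max_size: int = MAX_PANEL_SIZE,
                   min_gain: float = 0.0) -> Panel:
    """Greedy search over the union of hyper and hypo marker pools.

    Hypo markers enter with negative weights (their selection-stage
    coefficients), so a higher combined score means tumor for every
    member.  Probes whose coefficient sign contradicts their direction
    are dropped with a logged warning.
    """
    pools = []
    for res, sign in ((hyper, 1.0), (hypo, -1.0)):
        w = res.weights()
        bad = w.index[np.sign(w.to_numpy()) != sign]
        if len(bad):
            log.warning("combine_panels: dropping %d %s probes with "
                        "direction-inconsistent coefficients", len(bad),
                        res.direction)
            w = w.drop(bad)
        pools.append(w)
    union = pd.concat(pools)
    if union.empty:
        raise ValueError("no direction-consistent candidates to combine")
    return greedy_panel_search(union, beta, max_size, min_gain,
                               direction="combined")


def youden_threshold(scores, labels) -> float:
    """Score threshold maximizing sensitivity + specificity - 1 on
    training data (for reporting a binary operating point)."""
    from .evaluate import roc as _roc

    curve = _roc(np.asarray(scores, dtype=float), np.asarray(labels))
    j = curve.tpr - curve.fpr
    return float(curve.thresholds[int(np.argmax(j))])
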