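"""Reference-based concordance filters for candidate markers.

cfDNA is dominated by leukocyte-derived fragments, so a CpG that looks
tumor-hypermethylated in plasma may simply track blood cell composition.
The leukocyte concordance filter keeps a hypermethylation candidate only
if its mean beta in HCC cfDNA is strictly above the *maximum* per-cell-
type mean in a sorted leukocyte reference (the most conservative
reading; a margin can be added), and mirrors this for hypomethylation.
The tissue concordance filter keeps candidates whose tumor-vs-nontumor
shift in primary tissue has the same sign as the claimed direction.

Both filters only remove candidates (output is a subset of the input,
order preserved) and they commute.
"""
from __future__ import annotations

import logging

import numpy as np

from .data_model import BetaMatrix

__all__ = ["leukocyte_concordance_filter", "tissue_concordance_filter"]

log = logging.getLogger(__name__)


def _check_direction(direction: str) -> None:
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be hyper or hypo, got {direction!r}")


def leukocyte_concordance_filter(candidates, direction: str,
                                 hcc_cfdna: BetaMatrix,
                                 leukocyte: BetaMatrix,
                                 margin: float = 0.0) -> list[str]:
    """Keep candidates whose HCC-cfDNA mean clears every leukocyte
    cell-type mean in the claimed direction.

    ``hcc_cfdna`` may be a full disease cohort (only its ``tumor``
    samples are used) or an HCC-only matrix.  Candidates absent from the
    leukocyte reference are dropped with a logged warning.
    """
    _check_direction(direction)
    candidates = list(candidates)
    if (hcc_cfdna.group == "tumor").any():
        hcc_values = hcc_cfdna.group_values("tumor")
    else:
        hcc_values = hcc_cfdna.values
    cell_means = leukocyte.per_group_means()  # cell types x probes

    kept, n_missing = [], 0
    for p in candidates:
        if p not in hcc_cfdna.values.columns or p not in cell_means.columns:
            n_missing += 1
            continue
        hcc_mean = float(hcc_values[p].mean())
        if direction == "hyper":
            if hcc_mean > float(cell_means[p].max()) + margin:
                kept.append(p)
        else:
            if hcc_mean < float(cell_means[p].min()) - margin:
                kept.append(p)
    if n_missing:
        log.warning("leukocyte filter: %d candidates missing from the "
                    "reference, dropped", n_missing)
    return kept


def tissue_concordance_filter(candidates, direction: str,
                              tissue: BetaMatrix) -> list[str]:
    """Keep candidates whose primary-tissue delta_beta sign matches the
    claimed direction (hyper: > 0; hypo: < 0, strictly)."""
    _check_direction(direction)
    candidates = list(candidates)
    tum = tissue.group_values("tumor")
    non = tissue.group_values("nontumor")
    if tum.shape[0] == 0 or non.shape[0] == 0:
        raise ValueError("tissue matrix must contain both disease groups")

    kept, n_missing = [], 0
    for p in candidates:
        if p not in tissue.values.columns:
            n_missing += 1
            continue
        delta = float(tum[p].mean() - non[p].mean())
        if (direction == "hyper" and delta > 0) or \
           (direction == "hypo" and delta < 0):
            kept.append(p)
    if n_missing:
        log.warning("tissue filter: %d candidates missing from the tissue "
                    "matrix, dropped", n_missing)
    return kept
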