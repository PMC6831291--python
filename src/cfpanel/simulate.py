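"""Synthetic methylome and cfDNA-mixture cohort generator.

Emulates the study design of a cfDNA methylation biomarker screen for
hepatocellular carcinoma on a cirrhotic background: three compartment
methylomes (leukocyte, cirrhotic liver, tumor), tissue cohorts sampled
around the liver baselines, and cfDNA cohorts in which each sample is a
convex mixture

    E[beta] = f_leuk * beta_leuk
              + (1 - f_leuk) * [f_tumor * beta_tumor + (1 - f_tumor) * beta_cirr]

with ``f_tumor`` the tumor-derived fraction of the *liver-derived*
portion of cfDNA (zero in non-tumor patients).  Observed values are
beta-distributed around the expected value with concentration ``kappa``,
which keeps draws in [0, 1] and reproduces the heteroscedastic noise of
450k beta values.

Markers are planted as tumor-vs-cirrhotic shifts of size ``effect_delta``
at tissue level; the cfDNA shift is attenuated by the mixture, with
closed-form mean attenuation ``E[1 - f_leuk] * E[f_tumor]`` (see
:func:`expected_attenuation`).  A configurable fraction of markers is
"leukocyte-confounded" (leukocyte baseline on the wrong side of the
tumor baseline) so the leukocyte concordance filter has real work to do.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

from .data_model import (BetaMatrix, CohortBundle, ProbeAnnotation)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_baselines",
           "generate_tissue_cohort", "generate_cfdna_cohort",
           "generate_leukocyte_reference", "generate_study",
           "expected_attenuation", "expected_cfdna_mean"]

# substream labels: every stage draws from default_rng([seed, _SUB[stage], k])
_SUB = {"baselines": 1, "annotation": 2, "tissue": 3, "cfdna": 4,
        "leukocyte": 5}

_LEUKOCYTE_CELL_TYPES = ("cd4t", "cd8t", "b_cell")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror a 22-vs-22 cfDNA discovery cohort over 5,000 probes
    with 50 planted markers of tissue-level effect 0.3, plasma that is
    60-90% leukocyte-derived, a tumor fraction of 5-35% of the
    liver-derived portion, and 20% of markers confounded by leukocyte
    methylation.
    """

    n_probes: int = 5000
    n_hyper_markers: int = 25
    n_hypo_markers: int = 25
    effect_delta: float = 0.3
    precision_kappa: float = 100.0        # tissue / leukocyte noise
    precision_kappa_cfdna: float = 150.0  # cfDNA arrays average many genomes
    n_nontumor: int = 22
    n_tumor: int = 22
    leukocyte_fraction_range: tuple = (0.6, 0.9)
    tumor_fraction_range: tuple = (0.05, 0.35)
    frac_markers_leukocyte_confounded: float = 0.2
    n_leukocyte_samples_per_type: int = 6
    frac_probes_allosomal: float = 0.02
    frac_probes_snp: float = 0.02
    frac_probes_detection_fail: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hyper_markers + self.n_hypo_markers > self.n_probes:
            raise ValueError("more markers than probes")
        if self.precision_kappa <= 0 or self.precision_kappa_cfdna <= 0:
            raise ValueError("precision_kappa must be > 0")
        for rng_ in (self.leukocyte_fraction_range, self.tumor_fraction_range):
            lo, hi = rng_
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"fraction range {rng_} outside [0, 1]")
        if not 0.0 <= self.frac_markers_leukocyte_confounded <= 1.0:
            raise ValueError("confounded fraction outside [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study.

    ``baselines`` has one row per probe and columns ``leukocyte``,
    ``cirrhotic``, ``tumor``; ``markers`` maps marker probe id ->
    direction (``hyper``/``hypo``); ``confounded`` flags markers whose
    leukocyte baseline violates the concordance filter.  Per-sample
    mixing fractions of each generated cfDNA cohort are recorded in
    ``sample_fractions`` keyed by cohort name.
    """

    baselines: pd.DataFrame
    markers: pd.Series
    confounded: pd.Series
    annotation: ProbeAnnotation
    detection_ok: pd.Series
    sample_fractions: Dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    def clean_markers(self, direction: str | None = None) -> list[str]:
        ids = [p for p in self.markers.index if not self.confounded.loc[p]]
        if direction is not None:
            ids = [p for p in ids if self.markers.loc[p] == direction]
        return ids


def _trimodal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Baseline betas from the classic bimodal-plus-shoulder 450k shape:
    low ~ 0.1, mid ~ 0.5, high ~ 0.9 modes."""
    mode = rng.choice(3, size=n, p=[0.35, 0.30, 0.35])
    a = np.where(mode == 0, 2.0, np.where(mode == 1, 10.0, 18.0))
    b = np.where(mode == 0, 18.0, np.where(mode == 1, 10.0, 2.0))
    return rng.beta(a, b, size=n)


def _beta_noise(rng: np.random.Generator, mean: np.ndarray,
                kappa: float) -> np.ndarray:
    mu = np.clip(mean, 1e-3, 1.0 - 1e-3)
    return rng.beta(mu * kappa, (1.0 - mu) * kappa)


def expected_attenuation(cfg: SyntheticConfig) -> float:
    """Closed-form mean ratio of cfDNA marker shift to tissue shift,
    E[1 - f_leuk] * E[f_tumor] under independent uniform fractions."""
    fl = 1.0 - 0.5 * sum(cfg.leukocyte_fraction_range)
    ft = 0.5 * sum(cfg.tumor_fraction_range)
    return fl * ft


def expected_cfdna_mean(beta_leuk, beta_cirr, beta_tumor,
                        f_leuk, f_tumor):
    """Expected cfDNA beta for given compartment baselines and fractions."""
    liver = f_tumor * np.asarray(beta_tumor) + (1.0 - f_tumor) * np.asarray(beta_cirr)
    return f_leuk * np.asarray(beta_leuk) + (1.0 - f_leuk) * liver


# ---------------------------------------------------------------------
# baselines + annotation
# ---------------------------------------------------------------------

def generate_baselines(cfg: SyntheticConfig) -> GroundTruth:
    """Draw compartment baselines, plant markers, assign annotation.

    Marker cirrhotic baselines are resampled until the full +/- delta
    shift fits inside [0.02, 0.98], so the planted effect is exactly
    ``effect_delta`` (never silently truncated).  Clean hyper markers get
    a leukocyte baseline 0.15-0.35 below the cirrhotic one (so the
    mixture stays above leukocyte levels in HCC plasma); confounded
    hyper markers get a leukocyte baseline above the tumor one.  Hypo
    markers mirror this.
    """
    rng = np.random.default_rng([cfg.seed, _SUB["baselines"]])
    n = cfg.n_probes
    probes = [f"cg{i:08d}" for i in range(n)]
    delta = cfg.effect_delta

    cirr = _trimodal(rng, n)
    tumor = cirr.copy()

    # non-marker leukocyte baseline: mostly shared with liver, some
    # cell-type-specific probes for realistic background structure
    leuk = cirr.copy()
    indep = rng.random(n) < 0.30
    leuk[indep] = _trimodal(rng, int(indep.sum()))

    marker_idx = rng.choice(n, size=cfg.n_hyper_markers + cfg.n_hypo_markers,
                            replace=False)
    hyper_idx = marker_idx[:cfg.n_hyper_markers]
    hypo_idx = marker_idx[cfg.n_hyper_markers:]

    directions, confounded = {}, {}

    def n_conf(n_markers: int) -> int:
        return int(round(cfg.frac_markers_leukocyte_confounded * n_markers))

    for sign, idxs in (("hyper", hyper_idx), ("hypo", hypo_idx)):
        k_conf = n_conf(len(idxs))
        conf_set = set(rng.choice(idxs, size=k_conf, replace=False)) if k_conf else set()
        for i in idxs:
            # feasible cirrhotic baseline: full shift fits, and room for a
            # leukocyte gap on the clean side
            lo, hi = (0.20, 0.98 - delta) if sign == "hyper" else (0.02 + delta, 0.80)
            c = cirr[i]
            while not (lo <= c <= hi):
                c = _trimodal(rng, 1)[0]
            cirr[i] = c
            tumor[i] = c + delta if sign == "hyper" else c - delta
            gap = rng.uniform(0.15, 0.35)
            bump = rng.uniform(0.05, 0.15)
            if i in conf_set:
                leuk[i] = (min(tumor[i] + bump, 0.98) if sign == "hyper"
                           else max(tumor[i] - bump, 0.02))
            else:
                leuk[i] = (max(c - gap, 0.02) if sign == "hyper"
                           else min(c + gap, 0.98))
            pid = probes[i]
            directions[pid] = sign
            confounded[pid] = i in conf_set

    baselines = pd.DataFrame({"leukocyte": leuk, "cirrhotic": cirr,
                              "tumor": tumor}, index=pd.Index(probes, name="probe_id"))
    markers = pd.Series(directions, name="direction")
    conf = pd.Series(confounded, name="confounded").reindex(markers.index)

    ann, detection_ok = _generate_annotation(cfg, probes, markers)
    return GroundTruth(baselines, markers, conf, ann, detection_ok)


def _generate_annotation(cfg: SyntheticConfig, probes: list[str],
                         markers: pd.Series):
    """Genomic context with the observed enrichment pattern: hyper
    markers favor promoters, hypo markers favor gene bodies and
    intergenic space.  Markers are kept autosomal, SNP-free and
    detected, so QC never removes planted signal."""
    rng = np.random.default_rng([cfg.seed, _SUB["annotation"]])
    n = len(probes)
    is_marker = pd.Index(probes).isin(markers.index)

    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)], dtype=object)
    snp = rng.random(n) < cfg.frac_probes_snp
    det_fail = rng.random(n) < cfg.frac_probes_detection_fail
    allo = rng.random(n) < cfg.frac_probes_allosomal
    chrom[allo] = rng.choice(["chrX", "chrY"], size=int(allo.sum()), p=[0.7, 0.3])
    # planted markers must survive QC masking
    chrom[is_marker] = [f"chr{c}" for c in rng.integers(1, 23, size=int(is_marker.sum()))]
    snp[is_marker] = False
    det_fail[is_marker] = False

    feature = rng.choice(["promoter", "gene_body", "intergenic"],
                         size=n, p=[0.30, 0.40, 0.30])
    for i, pid in enumerate(probes):
        if pid in markers.index:
            if markers.loc[pid] == "hyper":
                feature[i] = ("promoter" if rng.random() < 0.6 else
                              rng.choice(["gene_body", "intergenic"]))
            else:
                feature[i] = (rng.choice(["gene_body", "intergenic"])
                              if rng.random() < 0.8 else "promoter")

    dist = np.empty(n, dtype=int)
    for i in range(n):
        if feature[i] == "promoter":
            dist[i] = int(rng.integers(-1500, 501))
        elif feature[i] == "gene_body":
            dist[i] = int(rng.integers(500, 50001))
        else:
            dist[i] = int(rng.integers(10000, 500001)) * int(rng.choice([-1, 1]))

    table = pd.DataFrame({
        "chromosome": chrom,
        "position": rng.integers(1, 250_000_000, size=n),
        "feature": feature,
        "distance_to_tss": dist,
        "snp_associated": snp,
    }, index=pd.Index(probes, name="probe_id"))
    detection_ok = pd.Series(~det_fail, index=table.index, name="detection_ok")
    return ProbeAnnotation(table), detection_ok


# ---------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------

def generate_tissue_cohort(cfg: SyntheticConfig, truth: GroundTruth,
                           name: str = "tissue_set_1",
                           role: str = "tissue_set_1",
                           stream: int = 0) -> CohortBundle:
    """Tissue samples: beta noise of concentration kappa around the
    cirrhotic (nontumor) or tumor (tumor) baseline."""
    if cfg.precision_kappa <= 0:
        raise ValueError("precision_kappa must be > 0")
    rng = np.random.default_rng([cfg.seed, _SUB["tissue"], stream])
    probes = truth.baselines.index
    rows, groups, ids = [], [], []
    for g, base, n_g in (("nontumor", truth.baselines["cirrhotic"], cfg.n_nontumor),
                         ("tumor", truth.baselines["tumor"], cfg.n_tumor)):
        for i in range(n_g):
            rows.append(_beta_noise(rng, base.to_numpy(), cfg.precision_kappa))
            groups.append(g)
            ids.append(f"{name}_{'nt' if g == 'nontumor' else 'tu'}{i:03d}")
    values = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                          columns=probes)
    beta = BetaMatrix(values,
                      pd.Series(groups, index=values.index, name="group"),
                      pd.Series("tissue", index=values.index, name="substrate"))
    return CohortBundle(name, beta, truth.annotation, role)


def generate_cfdna_cohort(cfg: SyntheticConfig, truth: GroundTruth,
                          name: str = "discovery_cfdna",
                          stream: int = 0) -> CohortBundle:
    """cfDNA samples as leukocyte/cirrhotic/tumor convex mixtures.

    Each sample draws its own leukocyte fraction; tumor samples
    additionally draw a tumor fraction of the liver-derived portion.
    The drawn fractions are recorded in ``truth.sample_fractions[name]``.
    """
    rng = np.random.default_rng([cfg.seed, _SUB["cfdna"], stream])
    bl = truth.baselines
    b_leuk = bl["leukocyte"].to_numpy()
    b_cirr = bl["cirrhotic"].to_numpy()
    b_tum = bl["tumor"].to_numpy()

    rows, groups, ids, fl_list, ft_list = [], [], [], [], []
    for g, n_g in (("nontumor", cfg.n_nontumor), ("tumor", cfg.n_tumor)):
        for i in range(n_g):
            f_leuk = rng.uniform(*cfg.leukocyte_fraction_range)
            f_tumor = rng.uniform(*cfg.tumor_fraction_range) if g == "tumor" else 0.0
            mean = expected_cfdna_mean(b_leuk, b_cirr, b_tum, f_leuk, f_tumor)
            rows.append(_beta_noise(rng, mean, cfg.precision_kappa_cfdna))
            groups.append(g)
            ids.append(f"{name}_{'nt' if g == 'nontumor' else 'tu'}{i:03d}")
            fl_list.append(f_leuk)
            ft_list.append(f_tumor)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                          columns=bl.index)
    beta = BetaMatrix(values,
                      pd.Series(groups, index=values.index, name="group"),
                      pd.Series("cfdna", index=values.index, name="substrate"))
    truth.sample_fractions[name] = pd.DataFrame(
        {"leukocyte_fraction": fl_list, "tumor_fraction": ft_list},
        index=values.index)
    return CohortBundle(name, beta, truth.annotation, "discovery_cfdna")


def generate_leukocyte_reference(cfg: SyntheticConfig,
                                 truth: GroundTruth) -> CohortBundle:
    """Sorted blood cell types around the leukocyte baseline, with a
    small per-cell-type offset (cell types are similar but not
    identical)."""
    rng = np.random.default_rng([cfg.seed, _SUB["leukocyte"]])
    base = truth.baselines["leukocyte"].to_numpy()
    rows, groups, ids = [], [], []
    for ct in _LEUKOCYTE_CELL_TYPES:
        ct_base = np.clip(base + rng.normal(0.0, 0.02, size=base.size),
                          0.01, 0.99)
        for i in range(cfg.n_leukocyte_samples_per_type):
            rows.append(_beta_noise(rng, ct_base, cfg.precision_kappa))
            groups.append(ct)
            ids.append(f"leuk_{ct}_{i:02d}")
    values = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                          columns=truth.baselines.index)
    beta = BetaMatrix(values,
                      pd.Series(groups, index=values.index, name="group"),
                      pd.Series("leukocyte", index=values.index,
                                name="substrate"))
    return CohortBundle("leukocyte_reference", beta, truth.annotation,
                        "leukocyte_reference")


def generate_study(cfg: SyntheticConfig):
    """Full study: discovery cfDNA, two tissue validation sets, a
    leukocyte reference, and the ground truth behind them."""
    truth = generate_baselines(cfg)
    bundles = {
        "discovery_cfdna": generate_cfdna_cohort(cfg, truth, "discovery_cfdna",
                                                 stream=0),
        "tissue_set_1": generate_tissue_cohort(cfg, truth, "tissue_set_1",
                                               "tissue_set_1", stream=1),
        "tissue_set_2": generate_tissue_cohort(cfg, truth, "tissue_set_2",
                                               "tissue_set_2", stream=2),
        "leukocyte_reference": generate_leukocyte_reference(cfg, truth),
    }
    return bundles, truth
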