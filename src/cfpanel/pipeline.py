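"""End-to-end discovery pipeline: differential calling -> reference
filtering -> bootstrap selection -> greedy panels -> cross-cohort
validation, driven by a single config with one root seed.

The default operating point is the published one: dual cutoffs
delta_beta 0.1 (hyper) / 0.15 (hypo) with p < 0.05, elastic-net mixing
0.05, 100 bootstraps, 95% confidence intervals, panel cap 5.  For
simulated studies the delta cutoffs can be rescaled by the generator's
closed-form mean cfDNA dilution (``attenuation_scaled`` config flag),
since a mixture that is mostly leukocyte-derived shrinks every marker
shift by E[1 - f_leuk] * E[f_tumor]; the p-value leg is scale-free and
stays at 0.05.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import diffmeth, filters
from .data_model import qc_filter_probes, read_cohort_bundle
from .evaluate import cross_cohort_validate
from .panel import Panel, combine_panels, greedy_panel_search
from .selection import SelectionResult, bootstrap_select
from .simulate import SyntheticConfig, expected_attenuation, generate_study

__all__ = ["PipelineConfig", "PipelineResult", "run_discovery",
           "DEFAULT_OPERATING_POINT"]

log = logging.getLogger(__name__)

#: the published operating point; config defaults must equal this
DEFAULT_OPERATING_POINT = {
    "delta_cut_hyper": 0.1,
    "delta_cut_hypo": 0.15,
    "p_cut": 0.05,
    "mixing": 0.05,
    "bootstraps": 100,
    "ci_level": 0.95,
    "max_panel": 5,
}

STATUS_OK = "ok"
STATUS_NO_EVENTS = "no differential events"
STATUS_NO_MARKERS = "no markers selected"


@dataclass
class PipelineConfig:
    delta_cut_hyper: float = 0.1
    delta_cut_hypo: float = 0.15
    p_cut: float = 0.05
    mixing: float = 0.05
    bootstraps: int = 100
    ci_level: float = 0.95
    max_panel: int = 5
    seed: int = 0
    reselect_lambda: bool = True
    k_folds: int = 5
    #: rescale delta cutoffs by the generator's mean cfDNA dilution
    attenuation_scaled: bool = False
    simulate: Optional[SyntheticConfig] = None
    cohort_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = SyntheticConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in sim.items()})
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class PipelineResult:
    status: str
    config: PipelineConfig
    events: Dict[str, list] = field(default_factory=dict)
    filtered: Dict[str, list] = field(default_factory=dict)
    selections: Dict[str, SelectionResult] = field(default_factory=dict)
    panels: Dict[str, Panel] = field(default_factory=dict)
    validation: Optional[pd.DataFrame] = None
    funnel: list = field(default_factory=list)
    differential: Optional[pd.DataFrame] = None


def _load_cohorts(config: PipelineConfig):
    if config.simulate is not None:
        bundles, truth = generate_study(config.simulate)
        detection_ok = truth.detection_ok
        return bundles, truth, detection_ok
    if config.cohort_dir is None:
        raise ValueError("config needs a simulate block or a cohort_dir")
    bundles = {}
    for name in ("discovery_cfdna", "tissue_set_1", "tissue_set_2",
                 "leukocyte_reference"):
        bundles[name] = read_cohort_bundle(name, config.cohort_dir)
    ann = bundles["discovery_cfdna"].annotation
    detection_ok = pd.Series(True, index=ann.table.index)
    return bundles, None, detection_ok


def _delta_cuts(config: PipelineConfig) -> tuple[float, float]:
    hyper, hypo = config.delta_cut_hyper, config.delta_cut_hypo
    if config.attenuation_scaled:
        if config.simulate is None:
            raise ValueError("attenuation_scaled needs a simulate block")
        a = expected_attenuation(config.simulate)
        hyper, hypo = hyper * a, hypo * a
        log.info("delta cutoffs rescaled by mean cfDNA dilution %.4f -> "
                 "%.5f / %.5f", a, hyper, hypo)
    return hyper, hypo


def run_discovery(config: PipelineConfig,
                  out_dir: Optional[str] = None) -> PipelineResult:
    """Run the full discovery flow for both directions plus the
    combined panel; deterministic given the config (one root seed)."""
    t0 = time.time()
    result = PipelineResult(STATUS_OK, config)
    funnel = result.funnel

    def stage(msg: str) -> None:
        # wall time goes to the logger only; funnel lines (and run.log)
        # stay bit-identical across reruns of the same config
        funnel.append(msg)
        log.info("[%7.2fs] %s", time.time() - t0, msg)

    bundles, truth, detection_ok = _load_cohorts(config)
    discovery = bundles["discovery_cfdna"]
    stage(f"cohorts loaded: discovery {discovery.beta.n_samples} samples x "
          f"{discovery.beta.n_probes} probes")

    beta_qc = qc_filter_probes(discovery.beta, discovery.annotation,
                               detection_ok)
    stage(f"qc masking: {discovery.beta.n_probes} -> {beta_qc.n_probes} probes")

    cut_hyper, cut_hypo = _delta_cuts(config)
    diff = diffmeth.compute_differential(beta_qc, delta_cut=cut_hyper,
                                         p_cut=config.p_cut)
    result.differential = diff
    events = {
        "hyper": diffmeth.call_events(diff, cut_hyper, config.p_cut, "hyper"),
        "hypo": diffmeth.call_events(diff, cut_hypo, config.p_cut, "hypo"),
    }
    result.events = events
    stage(f"dual-cutoff events: {len(events['hyper'])} hyper, "
          f"{len(events['hypo'])} hypo")
    if not events["hyper"] and not events["hypo"]:
        result.status = STATUS_NO_EVENTS
        stage("terminating: " + STATUS_NO_EVENTS)
        _write_outputs(result, out_dir)
        return result

    leuk = bundles["leukocyte_reference"].beta
    tissue1 = bundles["tissue_set_1"].beta
    for direction in ("hyper", "hypo"):
        cand = events[direction]
        cand = filters.leukocyte_concordance_filter(cand, direction,
                                                    beta_qc, leuk)
        n_leuk = len(cand)
        cand = filters.tissue_concordance_filter(cand, direction, tissue1)
        result.filtered[direction] = cand
        stage(f"{direction}: {len(events[direction])} events -> {n_leuk} "
              f"after leukocyte filter -> {len(cand)} after tissue filter")

    seeds = {"hyper": config.seed * 2 + 11, "hypo": config.seed * 2 + 12}
    for direction in ("hyper", "hypo"):
        cand = result.filtered[direction]
        if not cand:
            continue
        X = beta_qc.values.loc[:, cand]
        y = beta_qc.labels01()
        sel = bootstrap_select(X, y, direction, mixing=config.mixing,
                               B=config.bootstraps, ci_level=config.ci_level,
                               seed=seeds[direction] % (2 ** 31),
                               reselect_lambda=config.reselect_lambda,
                               k_folds=config.k_folds)
        result.selections[direction] = sel
        stage(f"{direction}: bootstrap selection kept "
              f"{len(sel.selected_probes)} / {len(cand)} candidates")

    any_selected = any(len(s.selected_probes) > 0
                       for s in result.selections.values())
    if not any_selected:
        result.status = STATUS_NO_MARKERS
        stage("terminating: " + STATUS_NO_MARKERS)
        _write_outputs(result, out_dir)
        return result

    for direction, sel in result.selections.items():
        if sel.selected_probes:
            result.panels[direction] = greedy_panel_search(
                sel, beta_qc, max_size=config.max_panel)
            stage(f"{direction} panel: {result.panels[direction].probes} "
                  f"training AUROC {result.panels[direction].trace[-1]:.4f}")
    if all(d in result.selections and
           result.selections[d].selected_probes for d in ("hyper", "hypo")):
        result.panels["combined"] = combine_panels(
            result.selections["hyper"], result.selections["hypo"],
            beta_qc, max_size=config.max_panel)
        stage(f"combined panel: {result.panels['combined'].probes} "
              f"training AUROC {result.panels['combined'].trace[-1]:.4f}")

    disease_cohorts = [bundles[n] for n in
                       ("discovery_cfdna", "tissue_set_1", "tissue_set_2")]
    rows = []
    for name, pan in result.panels.items():
        curves = cross_cohort_validate(pan, disease_cohorts)
        for cohort, curve in curves.items():
            rows.append({"panel": name, "cohort": cohort,
                         "n_probes": len(pan.probes),
                         "auroc": curve.auroc})
    result.validation = pd.DataFrame(rows)
    stage("validation:\n" + result.validation.to_string(index=False))

    _write_outputs(result, out_dir)
    if out_dir is not None and config.simulate is not None:
        _write_truth(truth, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.differential is not None:
        ev = result.differential[result.differential["direction"] != "none"]
        ev.to_csv(out / "events.tsv", sep="\t", float_format="%.17g")
    flt = [{"direction": d, "probe_id": p}
           for d, probes in result.filtered.items() for p in probes]
    pd.DataFrame(flt, columns=["direction", "probe_id"]).to_csv(
        out / "filtered.tsv", sep="\t", index=False)
    for direction, sel in result.selections.items():
        sel.table.to_csv(out / f"selection_{direction}.tsv", sep="\t",
                         float_format="%.17g")
    for name, pan in result.panels.items():
        pan.to_json(out / f"panel_{name}.json")
    if result.validation is not None:
        result.validation.to_csv(out / "validation_report.tsv", sep="\t",
                                 index=False, float_format="%.17g")
    (out / "run.log").write_text(
        f"status: {result.status}\n" + "\n".join(result.funnel) + "\n")


def _write_truth(truth, out_dir) -> None:
    # planted markers only; full per-probe baselines stay with the
    # simulated cohort bundles
    out = Path(out_dir)
    gt = truth.baselines.loc[truth.markers.index].copy()
    gt["direction"] = truth.markers
    gt["confounded"] = truth.confounded.astype(bool)
    gt.to_csv(out / "ground_truth.tsv", sep="\t", float_format="%.17g")
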