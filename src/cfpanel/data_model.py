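"""Core containers and text I/O for 450k-style methylation data.

A beta value is a methylation fraction at one CpG in one sample
(methylated signal / total signal, in [0, 1]).  Everything downstream —
differential calling, reference filtering, penalized selection, panel
scoring — consumes the :class:`BetaMatrix` defined here, so this module
is the single place where value bounds, label consistency and the TSV
dialect are enforced.

File dialect: probes as rows, samples as columns, tab-separated, header
row of sample ids, ``NA`` for missing values.  Genomic coordinates in the
probe annotation are 1-based inclusive (450k manifest convention).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DISEASE_GROUPS = ("nontumor", "tumor")
SUBSTRATES = ("cfdna", "tissue", "leukocyte")
FEATURES = ("promoter", "gene_body", "intergenic")
COHORT_ROLES = ("discovery_cfdna", "tissue_set_1", "tissue_set_2",
                "leukocyte_reference")

#: slack when checking that beta values lie in [0, 1]
BOUND_TOL = 1e-9

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


class DataModelError(ValueError):
    """Raised on malformed beta matrices, annotation or metadata."""


@dataclass
class BetaMatrix:
    """Samples x probes matrix of methylation fractions with sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are CpG probe ids.  Values
        are beta fractions in [0, 1]; NaN marks missing.
    group
        Per-sample label.  ``nontumor``/``tumor`` for disease cohorts; for
        a leukocyte reference the group carries the sorted cell type
        (e.g. ``cd4t``).
    substrate
        Per-sample source material: ``cfdna``, ``tissue`` or ``leukocyte``.
    """

    values: pd.DataFrame
    group: pd.Series
    substrate: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise DataModelError(f"duplicate sample id {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise DataModelError(f"duplicate probe id {dup!r}")
        for name, lab in (("group", self.group), ("substrate", self.substrate)):
            if not lab.index.equals(v.index):
                raise DataModelError(
                    f"{name} labels do not match sample ids of the matrix")
        bad = set(self.substrate.unique()) - set(SUBSTRATES)
        if bad:
            raise DataModelError(f"unknown substrate label(s): {sorted(bad)}")
        arr = v.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            off = (arr < -BOUND_TOL) | (arr > 1.0 + BOUND_TOL)
        if off.any():
            i, j = np.argwhere(off)[0]
            raise DataModelError(
                f"beta value {arr[i, j]!r} out of [0, 1] at probe "
                f"{v.columns[j]!r}, sample {v.index[i]!r}")

    # -- basic views ---------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.values.columns]
        if missing:
            raise DataModelError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[:, list(probe_ids)],
                          self.group, self.substrate)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        idx = list(sample_ids)
        return BetaMatrix(self.values.loc[idx],
                          self.group.loc[idx], self.substrate.loc[idx])

    # -- disease-label helpers ----------------------------------------
    def labels01(self) -> np.ndarray:
        """Disease labels coded 0 = nontumor, 1 = tumor."""
        bad = set(self.group.unique()) - set(DISEASE_GROUPS)
        if bad:
            raise DataModelError(
                f"labels01 needs nontumor/tumor groups, found {sorted(bad)}")
        return (self.group == "tumor").to_numpy(dtype=int)

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values.loc[self.group == group]

    def per_group_means(self) -> pd.DataFrame:
        """Mean beta per group (rows) and probe (columns)."""
        return self.values.groupby(self.group).mean()


@dataclass
class ProbeAnnotation:
    """Per-CpG genomic context: chromosome, 1-based position, genic
    feature (promoter / gene_body / intergenic), signed distance to the
    nearest TSS, and whether a known SNP overlaps the probe."""

    table: pd.DataFrame  # indexed by probe_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise DataModelError("duplicate probe id in annotation")
        required = {"chromosome", "position", "feature",
                    "distance_to_tss", "snp_associated"}
        missing = required - set(t.columns)
        if missing:
            raise DataModelError(f"annotation missing columns {sorted(missing)}")
        if (t["position"] < 1).any():
            raise DataModelError("annotation positions must be >= 1")
        bad = set(t["feature"].unique()) - set(FEATURES)
        if bad:
            raise DataModelError(f"unknown feature label(s): {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, probe_ids) -> "ProbeAnnotation":
        return ProbeAnnotation(self.table.loc[list(probe_ids)])


@dataclass
class CohortBundle:
    """A named cohort: beta matrix + annotation + its role in the study."""

    name: str
    beta: BetaMatrix
    annotation: ProbeAnnotation
    role: str

    def __post_init__(self) -> None:
        if self.role not in COHORT_ROLES:
            raise DataModelError(f"unknown cohort role {self.role!r}")
        missing = set(self.beta.probe_ids) - set(self.annotation.table.index)
        if missing:
            raise DataModelError(
                f"{len(missing)} probes in beta lack annotation rows, "
                f"e.g. {sorted(missing)[:3]}")


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def read_beta_matrix(path, metadata_path) -> BetaMatrix:
    """Read a probes-as-rows TSV plus a sample metadata TSV.

    The metadata table must contain columns ``sample_id``, ``group`` and
    ``substrate``.  Probes with any missing value are dropped (the
    pipeline keeps only probes measured in every sample of a cohort);
    a sample present in the matrix but absent from the metadata is a
    hard error, as are duplicate ids or out-of-range values.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if raw.index.duplicated().any():
        raise DataModelError(f"duplicate probe id in {path}")
    if raw.columns.duplicated().any():
        raise DataModelError(f"duplicate sample id in {path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise DataModelError("metadata needs a sample_id column")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise DataModelError("duplicate sample id in metadata")
    absent = [s for s in raw.columns if s not in meta.index]
    if absent:
        raise DataModelError(f"samples missing from metadata: {absent[:5]}")

    values = raw.T.astype(float)  # samples x probes
    n_before = values.shape[1]
    values = values.dropna(axis=1)
    n_dropped = n_before - values.shape[1]
    if n_dropped:
        log.info("dropped %d probes with missing values at load", n_dropped)
    meta = meta.loc[values.index]
    return BetaMatrix(values, meta["group"].rename("group"),
                      meta["substrate"].rename("substrate"))


def write_beta_matrix(beta: BetaMatrix, path, metadata_path) -> None:
    """Write the TSV pair that :func:`read_beta_matrix` consumes."""
    beta.values.T.to_csv(path, sep="\t", index_label="probe_id",
                         na_rep="NA", float_format=_FLOAT_FMT)
    meta = pd.DataFrame({"sample_id": beta.sample_ids,
                         "group": beta.group.to_numpy(),
                         "substrate": beta.substrate.to_numpy()})
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_probe_annotation(path) -> ProbeAnnotation:
    t = pd.read_csv(path, sep="\t", index_col="probe_id",
                    dtype={"chromosome": str, "feature": str})
    t["position"] = t["position"].astype(int)
    t["distance_to_tss"] = t["distance_to_tss"].astype(int)
    t["snp_associated"] = t["snp_associated"].astype(str).str.lower().isin(
        ["true", "1", "yes"])
    return ProbeAnnotation(t)


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="probe_id")


def write_cohort_bundle(bundle: CohortBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(bundle.beta, out / f"{bundle.name}.beta.tsv",
                      out / f"{bundle.name}.meta.tsv")
    write_probe_annotation(bundle.annotation,
                           out / f"{bundle.name}.annotation.tsv")
    (out / f"{bundle.name}.role.txt").write_text(bundle.role + "\n")


def read_cohort_bundle(name: str, in_dir) -> CohortBundle:
    d = Path(in_dir)
    beta = read_beta_matrix(d / f"{name}.beta.tsv", d / f"{name}.meta.tsv")
    ann = read_probe_annotation(d / f"{name}.annotation.tsv")
    role = (d / f"{name}.role.txt").read_text().strip()
    return CohortBundle(name, beta, ann.subset(beta.probe_ids), role)


# ---------------------------------------------------------------------
# QC masking
# ---------------------------------------------------------------------

def qc_filter_probes(beta: BetaMatrix, ann: ProbeAnnotation,
                     detection_ok: pd.Series) -> BetaMatrix:
    """Drop allosomal, SNP-overlapping and detection-failed probes.

    ``detection_ok`` is a per-probe boolean standing in for "detection
    p-value significant in all samples" (raw IDAT-level detection calls
    are upstream of this pipeline).  Probe order is preserved.
    """
    keep = []
    tab = ann.table
    for p in beta.probe_ids:
        if p not in tab.index:
            raise DataModelError(f"probe {p!r} lacks annotation")
        if p not in detection_ok.index:
            raise DataModelError(f"probe {p!r} lacks a detection_ok flag")
        row = tab.loc[p]
        if row["chromosome"] in ("chrX", "chrY"):
            continue
        if bool(row["snp_associated"]):
            continue
        if not bool(detection_ok.loc[p]):
            continue
        keep.append(p)
    if not keep:
        raise DataModelError("all probes filtered")
    return beta.subset_probes(keep)
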