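"""Tissue-first marker discovery and its transfer to cfDNA.

Calls dual-cutoff differential CpGs in the primary-tissue cohort,
confirms the two disease states separate by hierarchical clustering
(chi-square on the 2x2 cluster-by-group table), then compares each
tissue-derived marker's single-CpG AUROC in tissue against the same
CpG's AUROC in cfDNA — the transfer loss that motivates discovering
markers directly in plasma.

Usage: python analysis/03_tissue_markers.py
"""
import argparse
from pathlib import Path

import pandas as pd

from cfpanel.data_model import read_cohort_bundle
from cfpanel.diffmeth import call_events, compute_differential
from cfpanel.evaluate import auroc, cluster_concordance


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="scratch/cohorts")
    ap.add_argument("--out", default="results")
    ap.add_argument("--top", type=int, default=200,
                    help="strongest tissue CpGs carried into the "
                         "transfer comparison")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    tissue = read_cohort_bundle("tissue_set_1", args.cohort_dir).beta
    cfdna = read_cohort_bundle("discovery_cfdna", args.cohort_dir).beta

    diff = compute_differential(tissue)
    events = call_events(diff, 0.1, 0.05, "both")
    print(f"tissue dual-cutoff events (|delta|>0.1, p<0.05): {len(events)}")

    top = (diff.loc[events]
           .assign(rank=lambda d: d["delta_beta"].abs())
           .sort_values(["rank", "p_value"], ascending=[False, True])
           .head(args.top).index.tolist())

    cc = cluster_concordance(tissue, top)
    print(f"cluster concordance on top {len(top)} CpGs: "
          f"chi2={cc['chi_square']:.2f}, p={cc['p_value']:.3e}")

    y_t, y_c = tissue.labels01(), cfdna.labels01()
    rows = []
    for p in top:
        sign = 1.0 if diff.loc[p, "delta_beta"] > 0 else -1.0
        rows.append({
            "probe_id": p,
            "delta_beta_tissue": diff.loc[p, "delta_beta"],
            "auroc_tissue": auroc(sign * tissue.values[p].to_numpy(), y_t),
            "auroc_cfdna": auroc(sign * cfdna.values[p].to_numpy(), y_c),
        })
    table = pd.DataFrame(rows)
    table.to_csv(out / "tissue_marker_transfer.tsv", sep="\t", index=False,
                 float_format="%.6g")

    n_good_tissue = (table["auroc_tissue"] > 0.75).sum()
    n_good_cfdna = (table["auroc_cfdna"] > 0.75).sum()
    print(f"CpGs with AUROC > 0.75: {n_good_tissue} in tissue vs "
          f"{n_good_cfdna} of the same CpGs in cfDNA")
    print(f"median transfer loss: "
          f"{(table['auroc_tissue'] - table['auroc_cfdna']).median():.3f}")

    pd.DataFrame([{"n_events": len(events),
                   "chi_square": cc["chi_square"],
                   "p_value": cc["p_value"],
                   "n_auroc_gt_075_tissue": n_good_tissue,
                   "n_auroc_gt_075_cfdna": n_good_cfdna}]).to_csv(
        out / "tissue_marker_summary.tsv", sep="\t", index=False,
        float_format="%.6g")


if __name__ == "__main__":
    main()
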