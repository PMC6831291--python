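"""Global methylome landscape of the simulated cohorts: PCA separation
of disease states, per-group mean methylation, the volcano-style
magnitude-bin census of differential changes, and the genic-feature
distribution of hyper vs hypo events.

Reads the cohorts written by 01_simulate_cohorts.py.

Usage: python analysis/02_methylome_landscape.py
"""
import argparse
from pathlib import Path

import pandas as pd

from cfpanel.data_model import read_cohort_bundle
from cfpanel.diffmeth import (call_events, compute_differential,
                              feature_distribution, global_mean_profile)
from cfpanel.evaluate import pca_embed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="scratch/cohorts")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    pca_rows, mean_rows, bin_rows, feat_rows = [], [], [], []
    for name in ("discovery_cfdna", "tissue_set_1"):
        bundle = read_cohort_bundle(name, args.cohort_dir)
        beta = bundle.beta

        res = pca_embed(beta, n_components=2)
        for sid in res.coordinates.index:
            pca_rows.append({"cohort": name, "sample_id": sid,
                             "group": beta.group.loc[sid],
                             "PC1": res.coordinates.loc[sid, "PC1"],
                             "PC2": res.coordinates.loc[sid, "PC2"]})

        sample_means, group_means = global_mean_profile(beta)
        for g, v in group_means.items():
            mean_rows.append({"cohort": name, "group": g, "mean_beta": v})

        diff = compute_differential(beta)
        counts = diff["magnitude_bin"].value_counts()
        for b, c in counts.items():
            bin_rows.append({"cohort": name, "magnitude_bin": b, "n_cpgs": c})

        # feature distribution of events at the tissue-scale cutoff; the
        # cfDNA cohort is too dilute for 0.1-scale events, so use the
        # p-filter there with a nominal delta floor
        delta_cut = 0.1 if name == "tissue_set_1" else 0.005
        for direction in ("hyper", "hypo"):
            events = call_events(diff, delta_cut, 0.05, direction)
            if not events:
                continue
            props = feature_distribution(events, bundle.annotation)
            for f, p in props.items():
                feat_rows.append({"cohort": name, "direction": direction,
                                  "feature": f, "proportion": p,
                                  "n_events": len(events)})

    pd.DataFrame(pca_rows).to_csv(out / "pca_coordinates.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    means = pd.DataFrame(mean_rows)
    means.to_csv(out / "global_means.tsv", sep="\t", index=False,
                 float_format="%.6g")
    pd.DataFrame(bin_rows).to_csv(out / "volcano_bins.tsv", sep="\t",
                                  index=False)
    feats = pd.DataFrame(feat_rows)
    feats.to_csv(out / "feature_distribution.tsv", sep="\t", index=False,
                 float_format="%.4g")

    print("group mean beta:")
    print(means.to_string(index=False))
    print("\nfeature distribution of dual-cutoff events:")
    print(feats.to_string(index=False))


if __name__ == "__main__":
    main()
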