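"""How much cfDNA dilution costs: the marker shift observed in plasma
versus the tumor fraction of liver-derived cfDNA.

Sweeps a 5-point tumor-fraction grid at fixed leukocyte background,
measures the mean cfDNA delta-beta over planted markers, fits the
linear relationship, and contrasts it with the undiluted tissue shift
— quantifying why tissue-scale delta cutoffs find nothing in a
leukocyte-dominated mixture.

Usage: python analysis/05_attenuation_analysis.py [--seed 1]
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cfpanel.simulate import (SyntheticConfig, expected_attenuation,
                              generate_baselines, generate_cfdna_cohort,
                              generate_tissue_cohort)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    grid = [0.05, 0.125, 0.2, 0.275, 0.35]
    rows = []
    tissue_delta = None
    for f in grid:
        cfg = SyntheticConfig(n_probes=300, n_hyper_markers=25,
                              n_hypo_markers=0, n_nontumor=50, n_tumor=50,
                              tumor_fraction_range=(f, f),
                              precision_kappa_cfdna=100.0, seed=args.seed)
        truth = generate_baselines(cfg)
        beta = generate_cfdna_cohort(cfg, truth).beta
        d = (beta.group_values("tumor").mean(axis=0) -
             beta.group_values("nontumor").mean(axis=0))
        if tissue_delta is None:
            tb = generate_tissue_cohort(cfg, truth).beta
            dt = (tb.group_values("tumor").mean(axis=0) -
                  tb.group_values("nontumor").mean(axis=0))
            tissue_delta = float(dt[truth.marker_ids].mean())
        rows.append({"tumor_fraction": f,
                     "mean_cfdna_delta": float(d[truth.marker_ids].mean()),
                     "predicted_delta": (1 - 0.75) * f * cfg.effect_delta})

    table = pd.DataFrame(rows)
    slope, intercept = np.polyfit(table["tumor_fraction"],
                                  table["mean_cfdna_delta"], 1)
    r2 = np.corrcoef(table["tumor_fraction"],
                     table["mean_cfdna_delta"])[0, 1] ** 2
    table.to_csv(out / "attenuation.tsv", sep="\t", index=False,
                 float_format="%.6g")

    print(table.to_string(index=False))
    print(f"\nlinear fit: delta = {slope:.4f} * f_tumor + {intercept:.5f} "
          f"(R^2 = {r2:.4f})")
    print(f"tissue-level marker shift: {tissue_delta:.3f}")
    cfg0 = SyntheticConfig(seed=args.seed)
    print(f"at the default fraction ranges the mean dilution factor is "
          f"{expected_attenuation(cfg0):.3f}: a 0.3 tissue shift appears "
          f"as ~{expected_attenuation(cfg0) * 0.3:.4f} in plasma")


if __name__ == "__main__":
    main()
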