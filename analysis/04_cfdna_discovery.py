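"""The headline analysis: marker discovery directly in cfDNA.

Runs the full funnel — QC masking, dual-cutoff differential calling
(delta cutoffs rescaled by the mixture's known mean dilution),
leukocyte and tissue concordance filters, bootstrap elastic-net
selection, greedy panel construction for the hyper, hypo and combined
pools — then validates every panel, frozen, in the discovery cfDNA and
both tissue cohorts.

Usage: python analysis/04_cfdna_discovery.py [--seed 1]
"""
import argparse

from cfpanel.pipeline import PipelineConfig, run_discovery
from cfpanel.simulate import SyntheticConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/discovery")
    args = ap.parse_args()

    config = PipelineConfig(seed=args.seed, attenuation_scaled=True,
                            simulate=SyntheticConfig(seed=args.seed))
    result = run_discovery(config, out_dir=args.out)

    print(f"status: {result.status}")
    for line in result.funnel:
        print("  " + line.replace("\n", "\n  "))
    if result.validation is not None:
        print("\ncross-cohort validation (frozen panels):")
        print(result.validation.to_string(index=False))


if __name__ == "__main__":
    main()
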