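"""GO-term statistics over the classified orthogroups.

Per-class Fisher enrichment (BH-FDR 0.10, with uncorrected p < 0.05
trends), per-GO-term Wilcoxon tests of member k values against 1, and
hypergeometric overlap expectations between selection classes.
"""

import argparse
import json

import pandas as pd

from omegak.pipeline import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = RunConfig(outdir=args.outdir, seed=args.seed, stages=["enrich"])
    run_pipeline(cfg)

    for label in ("relaxed", "intensified"):
        tab = pd.read_csv(f"{args.outdir}/enrichment_{label}.tsv", sep="\t")
        top = tab.head(3)[["term", "in_selected", "in_universe", "p", "q"]]
        print(f"top {label} enrichment:\n{top}\n")
    overlaps = json.load(open(f"{args.outdir}/overlap.json"))
    for name, o in overlaps.items():
        print(
            f"{name}: observed {o['observed']} vs expected {o['expected']:.2f} "
            f"(p = {o['fisher_p']:.3g})"
        )


if __name__ == "__main__":
    main()
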