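"""Classify orthogroups and test the k distribution.

Flags relaxed (k < 1, q < FDR), intensified (k > 1, q < FDR), and
diversifying (branch-site q < FDR) orthogroups; tests the k
distribution against the neutral expectation of 1 (one-sample Wilcoxon)
and compares the k<1 vs k>1 counts.
"""

import argparse
import json

from omegak.pipeline import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--fdr", type=float, default=0.10)
    args = ap.parse_args()

    cfg = RunConfig(outdir=args.outdir, seed=args.seed, fdr=args.fdr, stages=["classify"])
    run_pipeline(cfg)

    summary = json.load(open(f"{args.outdir}/selection_summary.json"))
    print(
        f"{summary['n_orthogroups']} orthogroups: median k = {summary['median_k']:.3f}, "
        f"Wilcoxon V = {summary['wilcoxon_V']:.0f} (p = {summary['wilcoxon_p']:.3g})"
    )
    print(
        f"relaxed {summary['n_relaxed']}, intensified {summary['n_intensified']}, "
        f"diversifying {summary['n_diversifying']} at FDR < {summary['fdr']}"
    )


if __name__ == "__main__":
    main()
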