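"""Epigenetic state of region-specific genes in astrocytes.

Reads the ChIP-qPCR Ct table, converts IP/input Cts into percent-input
(1% input dilution), forms the log2 H3K4me3/H3K27me3 bivalency ratio per
replicate, calls each promoter active / poised / repressed (band 0.5),
compares thalamic vs cortical ratios per gene with unpaired t tests, and
summarizes RT-qPCR expression relative to Gapdh (delta-Ct, 1/delta-Ct).

Usage: python analysis/06_chromatin_states.py [--results results]
"""

import argparse
from pathlib import Path

import pandas as pd

from regiosig.chromatin import chip_table_analysis, compare_ratios, rt_table_analysis


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--dilution", type=float, default=0.01)
    ap.add_argument("--epsilon", type=float, default=0.5)
    args = ap.parse_args()

    chip = pd.read_csv(args.results / "data" / "chip_ct.tsv", sep="\t")
    rep, summary = chip_table_analysis(chip, args.dilution, args.epsilon)
    summary.to_csv(args.results / "chip_summary.tsv", sep="\t", index=False)

    print("promoter states (log2 K4me3/K27me3, band +-%.2f):" % args.epsilon)
    for row in summary.itertuples():
        print(f"  {row.gene:8s} {row.region:3s}: ratio {row.ratio_mean:+.2f} "
              f"-> {row.state}")

    print("\nthalamus vs cortex ratio comparisons (unpaired t):")
    for gene, grp in rep.groupby("gene"):
        th = grp.loc[grp.region == "Th", "ratio"]
        ctx = grp.loc[grp.region == "Ctx", "ratio"]
        if len(th) >= 2 and len(ctx) >= 2:
            r = compare_ratios(th, ctx)
            print(f"  {gene:8s}: t = {r['t']:+.2f}, df = {r['df']}, "
                  f"p = {r['p']:.3g}")

    rt = pd.read_csv(args.results / "data" / "rt_ct.tsv", sep="\t")
    pieces = []
    for region, grp in rt.groupby("region"):
        ex = rt_table_analysis(grp)
        ex.insert(0, "region", region)
        pieces.append(ex)
    expr = pd.concat(pieces, ignore_index=True)
    expr.to_csv(args.results / "expression_summary.tsv", sep="\t", index=False)
    print(f"\nexpression summary -> {args.results / 'expression_summary.tsv'}")


if __name__ == "__main__":
    main()
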