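"""Differential expression between thalamic and cortical populations.

Reads the simulated bulk counts (see 01_simulate_inputs.py), runs the
NB-Wald test separately for astrocytes and neurons, applies the printed
thresholds (BH-adjusted p < 0.1; optionally |log2FC| > 0.322), ranks the
top-400 most differentially enriched neuronal genes, and writes DEG tables
and gene sets (GMT). Prints the DEG counts per population.

Usage: python analysis/02_region_de_bulk.py [--results results]
"""

import argparse
from pathlib import Path

from regiosig import io as rio
from regiosig.containers import GeneSet
from regiosig.diffexpr import deg_filter, nb_wald_test, top_n_enriched


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.1)
    ap.add_argument("--min-lfc", type=float, default=0.0)
    ap.add_argument("--restrictive-lfc", type=float, default=0.322)
    ap.add_argument("--top-n", type=int, default=400)
    args = ap.parse_args()

    data = args.results / "data"
    bulk = rio.read_counts_tsv(data / "bulk_region_counts.tsv",
                               data / "bulk_region_meta.tsv")
    sets = []
    for ct, tag in (("astrocyte", "As"), ("neuron", "Ns")):
        th = list(bulk.samples.index[(bulk.samples.region == "Th")
                                     & (bulk.samples.cell_type == ct)])
        ctx = list(bulk.samples.index[(bulk.samples.region == "Ctx")
                                      & (bulk.samples.cell_type == ct)])
        res = nb_wald_test(bulk, ctx, th)  # log2FC > 0 = thalamus-enriched
        res.table.to_csv(args.results / f"de_bulk_{ct}.tsv", sep="\t")
        up, down = deg_filter(res, args.alpha, args.min_lfc)
        up_r, down_r = deg_filter(res, args.alpha, args.restrictive_lfc)
        sets += [GeneSet(f"{tag}-Th", up.genes, up.provenance),
                 GeneSet(f"{tag}-Ctx", down.genes, down.provenance)]
        print(f"{ct}: {len(up)} thalamus-enriched vs {len(down)} "
              f"cortex-enriched DEGs (adj p < {args.alpha}); restrictive "
              f"|log2FC| > {args.restrictive_lfc}: {len(up_r)} vs {len(down_r)}")

    ns_th = bulk.subset_samples(
        bulk.samples.index[(bulk.samples.region == "Th")
                           & (bulk.samples.cell_type == "neuron")])
    ns_ctx = bulk.subset_samples(
        bulk.samples.index[(bulk.samples.region == "Ctx")
                           & (bulk.samples.cell_type == "neuron")])
    top_th, top_ctx = top_n_enriched(ns_th, ns_ctx, n=args.top_n)
    sets += [GeneSet("Ns-Th-top", top_th.genes, top_th.provenance),
             GeneSet("Ns-Ctx-top", top_ctx.genes, top_ctx.provenance)]
    print(f"top-{args.top_n} neuronal enrichment rankings computed")

    rio.write_gmt(sets, args.results / "region_gene_sets.gmt")
    rio.write_gene_list(bulk.gene_ids, args.results / "bulk_universe.txt")
    print(f"gene sets -> {args.results / 'region_gene_sets.gmt'}")


if __name__ == "__main__":
    main()
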