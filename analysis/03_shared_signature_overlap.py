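"""Do astrocytes share their region's neuronal signature?

Reads the gene sets from 02_region_de_bulk.py, computes the percentage of
the top-400 neuronal genes of each region found among the astrocyte DEGs
of the same versus the other region, and tests each overlap with the
one-sided hypergeometric (Fisher exact) test, reporting both odds-ratio
estimators. Repeats the comparison at nucleus resolution (dLG/VPM/MGv,
one-vs-rest DE on the nuclei matrix) as a 3x3 comparison matrix.

Usage: python analysis/03_shared_signature_overlap.py [--results results]
"""

import argparse
from pathlib import Path

from regiosig import io as rio
from regiosig.containers import GeneSet, NUCLEI
from regiosig.diffexpr import deg_filter, nb_wald_test
from regiosig.overlap import comparison_matrix, overlap_test, percent_shared


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    sets = {s.name: s for s in rio.read_gmt(args.results / "region_gene_sets.gmt")}
    universe = GeneSet("universe",
                       rio.read_gene_list(args.results / "bulk_universe.txt"))

    print("top-400 neuronal genes shared with astrocyte DEG lists:")
    for top, astro in [("Ns-Th-top", "As-Th"), ("Ns-Th-top", "As-Ctx"),
                       ("Ns-Ctx-top", "As-Ctx"), ("Ns-Ctx-top", "As-Th")]:
        pct = percent_shared(sets[top], sets[astro], "A")
        r = overlap_test(sets[top], sets[astro], universe)
        print(f"  {top} in {astro}: {pct:5.2f}% shared "
              f"(p = {r.p_one_sided:.3g}, OR sample {r.or_sample:.3g}, "
              f"OR cMLE {r.or_cmle:.3g})")

    data = args.results / "data"
    nuc = rio.read_counts_tsv(data / "bulk_nuclei_counts.tsv",
                              data / "bulk_nuclei_meta.tsv")
    nsets = {}
    for ct, tag in (("astrocyte", "As"), ("neuron", "Ns")):
        for nucleus in NUCLEI:
            own = list(nuc.samples.index[(nuc.samples.region == nucleus)
                                         & (nuc.samples.cell_type == ct)])
            rest = list(nuc.samples.index[(nuc.samples.region != nucleus)
                                          & (nuc.samples.cell_type == ct)])
            up, _ = deg_filter(nb_wald_test(nuc, rest, own), 0.1, 0.0)
            nsets[f"{tag}-{nucleus}"] = GeneSet(f"{tag}-{nucleus}", up.genes)

    cm = comparison_matrix([nsets[f"As-{n}"] for n in NUCLEI],
                           [nsets[f"Ns-{n}"] for n in NUCLEI],
                           GeneSet("nuc_universe", list(nuc.gene_ids)))
    cm.to_long_frame().to_csv(args.results / "overlap_nuclei.tsv",
                              sep="\t", index=False)
    print("\n3x3 nucleus comparison matrix (hypergeometric p):")
    print(cm.p_values().map(lambda p: f"{p:.2g}").to_string())
    p = cm.p_values().to_numpy()
    import numpy as np

    sep = bool(np.diag(p).max() < p[~np.eye(3, dtype=bool)].min())
    print(f"on-diagonal overlaps all more significant than off-diagonal: {sep}")


if __name__ == "__main__":
    main()
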