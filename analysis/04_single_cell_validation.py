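"""Single-cell confirmation of the shared regional signature.

Reads the simulated single-cell matrix (MTX), applies the QC filter
(> 600 UMIs, mitochondrial fraction < 5%), runs the Wilcoxon rank-sum DE
(natural-log fold-change pre-filter 0.1, min.pct 0) between thalamic and
cortical cells of each type, and tests the overlap of the resulting DEG
sets between astrocytes and neurons.

Usage: python analysis/04_single_cell_validation.py [--results results]
"""

import argparse
from pathlib import Path

from regiosig import io as rio
from regiosig.containers import GeneSet
from regiosig.diffexpr import deg_filter, sc_qc_filter, wilcoxon_de
from regiosig.overlap import overlap_test


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    sc = rio.read_mtx_dir(args.results / "data" / "sc")
    kept = sc_qc_filter(sc, min_umi=600, max_mito=0.05)
    print(f"QC: kept {kept.n_samples} of {sc.n_samples} cells "
          f"(>600 UMIs and <5% mitochondrial)")

    sets = {}
    for ct, tag in (("astrocyte", "As"), ("neuron", "Ns")):
        th = list(kept.samples.index[(kept.samples.region == "Th")
                                     & (kept.samples.cell_type == ct)])
        ctx = list(kept.samples.index[(kept.samples.region == "Ctx")
                                      & (kept.samples.cell_type == ct)])
        res = wilcoxon_de(kept, th, ctx, logfc_threshold=0.1, min_pct=0.0)
        res.table.to_csv(args.results / f"de_sc_{ct}.tsv", sep="\t")
        up, down = deg_filter(res, alpha=0.1, min_abs_lfc=0.1)
        sets[f"{tag}-Th"], sets[f"{tag}-Ctx"] = up, down
        print(f"{ct}: {len(up)} thalamic vs {len(down)} cortical DEGs "
              f"(adj p < 0.1, |logFC| > 0.1)")

    universe = GeneSet("sc_universe", list(kept.gene_ids))
    for a, b in [("As-Th", "Ns-Th"), ("As-Ctx", "Ns-Ctx"),
                 ("As-Th", "Ns-Ctx"), ("As-Ctx", "Ns-Th")]:
        A = GeneSet(a, sets[a].genes)
        B = GeneSet(b, sets[b].genes)
        r = overlap_test(A, B, universe)
        print(f"  {a} vs {b}: {r.a} shared, p = {r.p_one_sided:.3g}, "
              f"OR = {r.or_sample:.3g}")


if __name__ == "__main__":
    main()
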