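# regiosig

Astrocytes and neurons born in the same brain region inherit a common,
region-specific transcriptional program: thalamic astrocytes express (at
attenuated levels) many of the genes that define thalamic neurons, cortical
astrocytes those of cortical neurons, and the same holds one level down,
between the sensory thalamic nuclei (dLG, VPM, MGv). `regiosig` is a
reproducible re-implementation of the computational core of that analysis
for people who want to run, stress-test or extend it: differential
expression on bulk and single-cell counts, gene-set overlap testing,
clone inference from combinatorial fluorophore barcodes, and ChIP-qPCR
chromatin-state scoring — all driven by a synthetic-data generator with
known ground truth, so every stage is testable without any sequencing or
imaging data.

## What it computes

**Differential expression.** Bulk counts are normalized by median-of-ratios
size factors (reference for gene *i* is its geometric mean across samples;
*s<sub>j</sub>* = median<sub>i</sub> *k<sub>ij</sub>*/ref<sub>i</sub>) and
tested with a negative-binomial Wald test: per-gene moment dispersions
pooled across genes, log2 fold change with a delta-method standard error
from Var(*k*) = *μ* + *αμ*², two-sided normal p, Benjamini–Hochberg
adjustment. DEGs use the strict thresholds adj *p* < 0.1 and |log2FC| > 0
(restrictive variant > 0.322); the top-400 ranking scores each gene by the
difference of group means of log2-normalized counts. Single-cell matrices
are QC-filtered (> 600 UMIs, mitochondrial fraction < 5%, both strict) and
tested with a Wilcoxon rank-sum (logFC pre-filter 0.1 on the natural-log
scale, min.pct 0), exact by permutation enumeration for small groups.

**Gene-set overlap.** Sharing between astrocyte and neuron DEG sets is the
2×2 table (*a*, *b*, *c*, *d*) in a universe of *N* jointly testable genes,
tested one-sidedly with the hypergeometric tail P[X ≥ *a*] (the one-sided
Fisher exact test, accumulated in log space) and summarized by the sample
odds ratio *ad/bc* plus its conditional-MLE counterpart.

**Clones.** Cells carry 12 reporter channels (6 fluorophores ×
cytoplasmic/nuclear); presence/absence forms a 12-bit code, cells of one
animal with one code form a clone. Retained clones have ≥ 3 cells and > 1
reporter. Clones are typed by NeuN (mixed / neurons only / non-neuronal
only) and their dispersion across dLG/VPM/MGv is compared with
Kruskal–Wallis + Dunn tests. Recovery against simulated ground truth is
scored with the adjusted Rand index next to the analytic code-collision
probability.

**Chromatin.** ChIP-qPCR Cts become percent-input
(100 · 2^(adjusted input Ct − IP Ct), 1% input), promoters are scored by
the log2 H3K4me3/H3K27me3 ratio and called active / poised / repressed
around a ±0.5 band; expression is ΔCt to Gapdh with 2^−ΔCt and 1/ΔCt.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
inputs (script 01 writes them under `results/data/`):

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_region_de_bulk.py
python analysis/03_shared_signature_overlap.py
```

Script 03 prints, for seed 1:

```
top-400 neuronal genes shared with astrocyte DEG lists:
  Ns-Th-top in As-Th: 48.75% shared (p = 5.51e-200, OR sample 284, OR cMLE 283)
  Ns-Th-top in As-Ctx:  0.00% shared (p = 1, OR sample 0, OR cMLE 0)
  Ns-Ctx-top in As-Ctx: 53.00% shared (p = 1.07e-216, OR sample 253, OR cMLE 251)
  Ns-Ctx-top in As-Th:  0.00% shared (p = 1, OR sample 0, OR cMLE 0)

3x3 nucleus comparison matrix (hypergeometric p):
          Ns-dLG    Ns-VPM    Ns-MGv
As-dLG  1.3e-212         1         1
As-VPM         1  5.5e-218         1
As-MGv         1         1  3.1e-227
```

Reading: about half of the top-400 thalamic neuronal genes are recovered
among thalamic-astrocyte DEGs while essentially none appear in cortical
astrocytes, and at nucleus resolution only the matched astrocyte/neuron
pairs overlap — the simulated shared programs are recovered exactly where
they were planted. Scripts 04–06 add the single-cell confirmation, the
clonal dispersion analysis (e.g. `VPM-home clones (n=63): median 88.9% of
cells in VPM`) and the chromatin state calls (`Gbx2 Th: ratio +3.10 ->
active`, `Gbx2 Ctx: ratio -2.86 -> repressed`).

The same stages are available as a library (`regiosig.diffexpr`,
`.overlap`, `.clones`, `.chromatin`, `.synthdata`), as one orchestrated
run (`regiosig.pipeline.run_pipeline`, byte-reproducible given config +
seed), and as a CLI (`regiosig run --seed 1 --out results/pipeline`).

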