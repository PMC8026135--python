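# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `regiosig`. The package is an analysis pipeline over
simulated data: the generators in `regiosig.synthdata` define the study
conditions, and every downstream claim in the tests is a statement about
what the pipeline recovers from those conditions.

## Count simulation

Bulk counts are negative binomial with mean
μ<sub>ij</sub> = depth<sub>j</sub> · baseline<sub>i</sub> · 2^effect and
variance μ + αμ². Baselines are log-normal(0, 1) proportions (a realistic
several-orders-of-magnitude expression range, which deliberately includes
weakly expressed genes with little detection power); per-sample depths are
uniform in `lib_size_range` (default 0.5–1.5 million), so size-factor
recovery is a meaningful exercise rather than a no-op. α = 0 degenerates to
Poisson (verified by a variance/mean check over 10⁴ draws).

Gene classes are disjoint: a fraction `frac_region_genes` (default 0.15)
carries a region program split evenly across regions at `region_lfc`
(default 1.5 log2 units); `frac_celltype_genes` (0.10) separates cell
types at `celltype_lfc` (2.0); the rest are null. Region effects are
expressed in neurons at full strength. In astrocytes a fraction
`astro_shared_frac` of each program appears at
`astro_attenuation × region_lfc` (default attenuation 0.5 — shared genes
are present but weaker), and `astro_cross_frac` of each program leaks into
astrocytes of each other region, which is how partially shared and
spuriously shared programs are modeled in the recovery experiments
(30% within-region, 2% cross-region).

The single-cell generator draws per-cell totals from a configurable law
(default NB, mean 3000, dispersion 0.3), a mitochondrial fraction from a
Beta(2, 60) (most cells well below 5%), routes a Binomial(total, fraction)
share into a dedicated `mt-` gene block and distributes the remainder
multinomially under the cell's group profile. Region and type labels are
attached directly; clustering and embedding are out of scope, so passing
tests say nothing about label-assignment error in real data.

The clone generator gives each progenitor a 12-bit code by independent
Bernoulli(`p_integrate`) draws per channel, redrawing all-zero codes
(unlabeled progenitors are invisible). Collisions between progenitors are
*not* prevented — they are the method's intrinsic ambiguity, quantified by
the closed form
((p²+q²)¹² − q²⁴)/(1 − q¹²)², q = 1 − p, which the simulation matches
within Monte-Carlo error. Defaults: 50 progenitors per experiment in the
recovery studies, clone sizes Poisson(8) (clones below 3 cells exist and
are filtered, matching the analysis rule), home-nucleus frequencies
(0.18, 0.56, 0.26) for dLG/VPM/MGv (the approximate relative clone counts
of the imaging dataset), `dispersion_eps` 0.15 (cells stray from the home
nucleus ~15% of the time, consistent with reported 78–90% confinement
intervals), 39% pure clones, p(neuron) 0.5 in mixed lineages. Reporter
intensities are optional log-normal on/off levels; no quantitative
intensity noise model is claimed — boolean channels are the default and
the intensity path is a convenience for thresholding tests.

The qPCR generator inverts the percent-input identity exactly:
ct<sub>IP</sub> = ct<sub>input</sub> − log2(truth/(100·dilution)) + ε,
ε ~ N(0, `ct_noise_sd`), so at zero noise the analysis round-trips to the
configured enrichments to machine precision; replicate tables default to
12 replicates and 0.25 Ct noise (a typical qPCR repeatability figure).

## Differential expression

Size factors are textbook median-of-ratios; an error is raised when no
gene is positive in every sample. The log transform is
log2(normalized + 1): a deliberately simple, monotone stand-in for
variance-stabilizing transforms whose shrinkage behavior is tool-internal;
the top-N contract (rank by difference of group means of transformed
values) is preserved, and scores are rounded to 9 decimals before ranking
so genuine ties fall through to the documented lexicographic tie-break.

The Wald test estimates the per-gene moment dispersion
max(0, (pooled within-group variance − mean)/mean²) on normalized counts
and reports it, but the standard error uses these estimates pooled across
genes (mean over genes with normalized mean ≥ 1). With 4 samples per group
a per-gene variance estimate has ~6 degrees of freedom, and judging it
against a normal reference inflates the nominal 0.05 rate to ~0.10; the
cross-gene pool is nearly noise-free and restores calibration (measured
null false-positive rate 0.051 against the 0.049 floor obtained with the
true dispersion). The cost is that genuinely gene-specific dispersion is
ignored — acceptable here because the simulator is homoscedastic in α and
the biological pipeline logic lives in the thresholds, not the variance
model. No shrinkage of fold changes is applied; thresholds are strict
exactly as printed (adj p < 0.1, |log2FC| > 0, > 0.322 restrictive).

Single-cell DE scales each cell to 10,000 counts (configurable), tests
genes passing the natural-log fold-change pre-filter (0.1) and detection
pre-filter (min.pct 0 — i.e. none), and computes the rank-sum p exactly by
enumerating all C(n, n_A) assignments whenever that count is ≤ 1000,
otherwise by the tie-corrected normal approximation. The two-sided exact p
doubles the smaller tail, capped at 1. Normalized values are rounded to 6
decimals before ranking: scaling by reciprocals makes mathematically equal
values differ in the last bit, and undetected ties would silently change
exact p-values. The natural-log convention for the fold change follows the
upstream single-cell toolchain generation this pipeline mirrors; note that
later versions switched to log2.

## Overlap testing

The hypergeometric tail is summed in log space (log-pmf + logsumexp); a
tail that underflows to zero is reported as the smallest positive float
with an `underflow` flag, never silently as 0. The universe is explicit
everywhere: percent-shared is universe-invariant, the p-value is not, and
both facts are asserted in tests. Because the provenance of the study's
printed odds ratios is ambiguous, both the sample estimator ad/bc (∞ and
0/0 → NaN edge cases preserved) and the conditional-MLE under Fisher's
noncentral hypergeometric model (bracketed root-finding on the conditional
mean equation, exact boundary values 0/∞ at the support edges) are always
reported; neither is asserted against printed values. Comparison matrices
apply no multiplicity correction across cells by default (matching the
source analysis); BH across the grid is available but off.

## Clone analysis

Clone identity requires same animal AND same code — codes are not
comparable across electroporated animals. NeuN is deliberately excluded
from the identity code; it types cells within clones. Retention filters
are exact: size ≥ 3 and popcount ≥ 2. Dispersion profiles are percentages
over the fixed nucleus order (dLG, VPM, MGv); home-nucleus ties break by
that order and set a degeneracy flag. Dunn's pairwise z tests use the
pooled tie-corrected rank variance with the classical Bonferroni-style
multiplication over pairs; post-hoc software differs in its default
adjustment, so pairwise adjusted p-values may diverge numerically from
other implementations while z statistics agree. Clones are pooled across
animals for the Kruskal–Wallis comparisons, with per-animal breakdowns
available from the clone table.

## Chromatin

Percent input is 100 · 2^(adjusted input Ct − IP Ct) with the input
dilution's log2 offset (1% kept as input → offset log2 100); the formula
is the standard one, adopted because the source protocol specifies the
dilution but not the arithmetic. IgG is carried alongside and not
subtracted by default (no subtraction rule is specified; a subtraction
mode is a one-line change on the replicate table). Bivalency ratios are
computed per replicate and then averaged (the alternative — ratio of
averaged percent-inputs — is available via `per_replicate=False`). The
poised band ε = 0.5 log2 units is an explicit user-facing choice: the
equality line is the only anchor the source defines, and ±0.5 (a 1.4-fold
mark imbalance) is small against the ≥ 4-fold separations of clearly
active/repressed promoters. 1/ΔCt is undefined at ΔCt = 0 and returned as
NaN with a flag rather than raised.

## Pipeline and problem sizes

One global seed expands into per-stage child seeds through
`SeedSequence(seed).generate_state(8) % 2**31` in a fixed stage order, so
stages can be re-run in isolation. Reports echo every effective parameter
and carry sha256 checksums of all written files; identical config + seed
reproduces every byte.

Default problem sizes — 4000 genes, 4 samples per group (matching the
3–6-replicate design of the study the pipeline mirrors), 150 cells per
single-cell group, 120 progenitors over 4 animals, 12 qPCR replicates —
were chosen so a full run completes in seconds while keeping every
statistical regime of interest (low-count genes, small-sample DE, clone
filters, QC boundaries) populated. Calibration and recovery experiments
use 2000 genes and 20 seeded replicates.

## What passing tests do and do not show

The simulators are deliberately idealized: no batch effects, no ambient
RNA or doublets in the single-cell model, no spatial structure beyond the
nucleus label, no segmentation error in the clone tables, homoscedastic NB
dispersion. Green tests therefore demonstrate that the statistical
machinery is correct and calibrated under its stated model — not that the
model captures every failure mode of real sequencing, imaging or qPCR
data. GO/pathway enrichment, graph clustering/UMAP, read alignment and
genome-wide ChIP analysis are out of scope.
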