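"""Normalization and differential expression for bulk and single-cell counts.

Bulk pipeline: median-of-ratios size factors, a log2(normalized + 1)
transform, and a negative-binomial Wald test (method-of-moments dispersion,
delta-method standard error on the log2 fold change). The Wald engine is the
package's own DE procedure, validated by type-I calibration and recovery on
simulations with known truth; it deliberately omits dispersion shrinkage
across genes.

Single-cell pipeline: QC on UMI totals and mitochondrial fraction (strict
thresholds, defaults >600 UMIs and <5%), library-size normalization to a
common target total, and a Wilcoxon rank-sum test with a natural-log
fold-change pre-filter (default threshold 0.1) and detection-fraction
pre-filter (default 0, i.e. off). For small groups the rank-sum p-value is
computed by exact enumeration of the permutation distribution (ties
included); larger groups use the tie-corrected normal approximation.

All threshold inequalities are strict exactly as stated in their defaults:
adjusted p < alpha, |log2FC| > cutoff, UMIs > minimum, mito < maximum.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigError, CountMatrix, DEResult, GeneSet, SizeFactors

__all__ = [
    "size_factors_median_of_ratios",
    "log_normalize",
    "nb_wald_test",
    "bh_adjust",
    "deg_filter",
    "top_n_enriched",
    "sc_qc_filter",
    "wilcoxon_de",
]

_LN2 = np.log(2.0)


def size_factors_median_of_ratios(m: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    The reference for gene i is its geometric mean across samples, taken
    over genes with strictly positive counts in every sample; the size
    factor of sample j is the median over those genes of ``k_ij / ref_i``.
    """
    counts = np.asarray(m.counts, dtype=float)
    all_positive = np.all(counts > 0, axis=1)
    if not all_positive.any():
        raise ValueError("no reference genes: no gene has positive counts in every sample")
    ref_counts = counts[all_positive]
    log_ref = np.mean(np.log(ref_counts), axis=1)
    ratios = np.log(ref_counts) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return SizeFactors(
        factors=factors,
        sample_ids=m.sample_ids,
        n_reference_genes=int(all_positive.sum()),
    )


def normalized_counts(m: CountMatrix, s: SizeFactors | None = None) -> np.ndarray:
    """Counts divided by their median-of-ratios size factors."""
    if s is None:
        s = size_factors_median_of_ratios(m)
    if len(s.factors) != m.n_samples:
        raise ConfigError("size factors do not match the matrix's samples")
    return np.asarray(m.counts, dtype=float) / s.factors[None, :]


def log_normalize(m: CountMatrix, s: SizeFactors | None = None,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """``log2(count / size_factor + pseudocount)`` per entry."""
    if not pseudocount > 0:
        raise ConfigError("pseudocount: must be > 0")
    values = np.log2(normalized_counts(m, s) + pseudocount)
    return pd.DataFrame(values, index=m.gene_ids, columns=m.sample_ids)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (textbook definition)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(m: CountMatrix, group_a, group_b,
                 pseudocount: float = 1.0) -> DEResult:
    """Two-group negative-binomial Wald test on a bulk count matrix.

    Size factors are estimated on the two groups jointly. The per-gene
    method-of-moments dispersion
    ``max(0, (pooled within-group variance - mean) / mean^2)`` on normalized
    counts is reported, but the Wald standard error uses these moment
    estimates pooled across genes (their mean over genes with normalized
    mean >= 1): with a handful of replicates the per-gene estimate has so
    few degrees of freedom that a normal reference would be badly
    anticonservative, while the cross-gene pool is nearly noise-free. The
    log2 fold change is ``log2((mean_B + pc) / (mean_A + pc))`` with its
    standard error from the NB variance ``(mu + alpha mu^2) / n`` per group
    propagated through the log; the two-sided p-value is normal.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ConfigError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ConfigError("each group needs at least 2 samples")
    if not pseudocount > 0:
        raise ConfigError("pseudocount: must be > 0")

    sub = m.subset_samples(group_a + group_b)
    norm = normalized_counts(sub)
    na, nb = len(group_a), len(group_b)
    xa, xb = norm[:, :na], norm[:, na:]

    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    var_pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    mean_pooled = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(
            mean_pooled > 0,
            (var_pooled - mean_pooled) / np.maximum(mean_pooled, 1e-300) ** 2,
            0.0,
        )
    alpha = np.maximum(0.0, raw)
    pool_mask = mean_pooled >= 1.0
    alpha_pooled = max(0.0, float(raw[pool_mask].mean())) if pool_mask.any() else 0.0

    lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    var_mean_a = (mean_a + alpha_pooled * mean_a**2) / na
    var_mean_b = (mean_b + alpha_pooled * mean_b**2) / nb
    var_lfc = (
        var_mean_a / ((mean_a + pseudocount) ** 2)
        + var_mean_b / ((mean_b + pseudocount) ** 2)
    ) / _LN2**2
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / se, 0.0)
    p_raw = 2.0 * stats.norm.sf(np.abs(stat))
    p_raw = np.clip(p_raw, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "dispersion": alpha,
            "stat": stat,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "pct_a": np.nan,
            "pct_b": np.nan,
        },
        index=sub.gene_ids,
    )
    return DEResult(table=table, group_a=tuple(group_a), group_b=tuple(group_b),
                    method="nb_wald")


def deg_filter(r: DEResult, alpha: float = 0.1,
               min_abs_lfc: float = 0.0) -> tuple:
    """Split a DE result into up-/down-regulated gene sets.

    Strict inequalities exactly as printed: ``p_adj < alpha`` and
    ``|log2FC| > min_abs_lfc``; the up set holds positive fold changes
    (enriched in group B), the down set negative ones. Sets are ordered by
    raw p then gene id.
    """
    if alpha < 0 or min_abs_lfc < 0:
        raise ConfigError("thresholds must be >= 0")
    t = r.table
    lfc_col = "logfc" if "logfc" in t.columns else "log2fc"
    sig = t[t["p_adj"] < alpha]
    up = sig[sig[lfc_col] > min_abs_lfc]
    down = sig[sig[lfc_col] < -min_abs_lfc]
    prov = {
        "alpha": alpha,
        "min_abs_lfc": min_abs_lfc,
        "method": r.method,
        "group_a": list(r.group_a),
        "group_b": list(r.group_b),
    }

    def ordered(df: pd.DataFrame, name: str) -> GeneSet:
        order = np.lexsort((df.index.to_numpy(), df["p_raw"].to_numpy()))
        return GeneSet(name=name, genes=list(df.index[order]), provenance=dict(prov))

    return ordered(up, "up"), ordered(down, "down")


def top_n_enriched(mA: CountMatrix, mB: CountMatrix, n: int = 400,
                   pseudocount: float = 1.0) -> tuple:
    """Top-N most differentially enriched genes between two datasets.

    Both matrices are joined on their shared gene universe and normalized
    jointly (median-of-ratios across all columns); each gene is scored by
    the difference of group means of the log2-transformed normalized
    counts. ``topA`` holds the ``n`` highest scores, ``topB`` the ``n``
    lowest; ties break by lexicographic gene id and a degenerate all-tied
    score vector is flagged in the provenance.
    """
    shared = mA.gene_ids.intersection(mB.gene_ids)
    if n > len(shared):
        raise ConfigError(f"n={n} exceeds the shared gene universe ({len(shared)})")
    a = mA.subset_genes(shared)
    b = mB.subset_genes(shared)
    joint = CountMatrix(
        counts=np.concatenate([a.counts, b.counts], axis=1),
        gene_ids=shared,
        samples=pd.concat([a.samples, b.samples]),
    )
    logn = log_normalize(joint, pseudocount=pseudocount)
    score = (
        logn.iloc[:, : a.n_samples].mean(axis=1)
        - logn.iloc[:, a.n_samples:].mean(axis=1)
    )
    # round so that genuine ties (e.g. permuted replicates) rank by the
    # documented lexicographic tie-break instead of summation round-off
    score = score.round(9)
    degenerate = bool(np.allclose(score, score.iloc[0]))
    order_a = score.iloc[np.lexsort((score.index.to_numpy(), -score.to_numpy()))]
    order_b = score.iloc[np.lexsort((score.index.to_numpy(), score.to_numpy()))]
    prov = {"n": n, "universe_size": int(len(shared)), "degenerate_ties": degenerate}
    top_a = GeneSet("topA", list(order_a.index[:n]), dict(prov))
    top_b = GeneSet("topB", list(order_b.index[:n]), dict(prov))
    return top_a, top_b


def sc_qc_filter(m: CountMatrix, min_umi: int = 600,
                 max_mito: float = 0.05) -> CountMatrix:
    """Keep cells with total UMIs strictly above ``min_umi`` and
    mitochondrial fraction strictly below ``max_mito``.

    Totals and fractions come from the cell metadata when present, else are
    computed from the matrix (mitochondrial genes identified by an ``mt-``
    id prefix; absence of both metadata and prefix is an error).
    """
    meta = m.samples
    if "total_umis" in meta.columns:
        totals = meta["total_umis"].to_numpy(dtype=float)
    else:
        totals = m.counts.sum(axis=0).astype(float)
    if "mito_fraction" in meta.columns:
        mito = meta["mito_fraction"].to_numpy(dtype=float)
    else:
        is_mito = m.gene_ids.str.lower().str.startswith("mt-")
        if not is_mito.any():
            raise ConfigError(
                "mito_fraction absent and no genes with an 'mt-' prefix to compute it"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            mito = np.where(totals > 0, m.counts[is_mito].sum(axis=0) / totals, 0.0)
    keep = (totals > min_umi) & (mito < max_mito)
    return m.subset_samples(m.sample_ids[keep])


def _exact_ranksum_p(ranks: np.ndarray, na: int) -> float:
    """Two-sided exact permutation p for the rank-sum of the first group.

    Enumerates all C(n, na) assignments of the observed (tie-adjusted)
    ranks; the two-sided p doubles the smaller tail, capped at 1.
    """
    n = len(ranks)
    w_obs = ranks[:na].sum()
    lo = hi = 0
    total = comb(n, na)
    for idx in combinations(range(n), na):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_de(m: CountMatrix, group_a, group_b,
                logfc_threshold: float = 0.1, min_pct: float = 0.0,
                target_sum: float = 1e4, pseudocount: float = 1.0,
                exact_limit: int = 1000) -> DEResult:
    """Wilcoxon rank-sum DE on library-size-normalized single-cell counts.

    Each cell is scaled to ``target_sum`` total counts. Genes enter the test
    only when ``|logFC| >= logfc_threshold`` (natural log of the ratio of
    pseudocounted group means) and the detection fraction reaches
    ``min_pct`` in at least one group. P-values are exact (permutation
    enumeration, ties included) when the number of group assignments
    ``C(n, n_A)`` is at most ``exact_limit``, else tie-corrected normal;
    BH adjustment runs over the tested genes. Normalized values are rounded
    to 6 decimals before ranking so that ties survive floating-point
    round-off in the per-cell scaling.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ConfigError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ConfigError("groups overlap")

    sub = m.subset_samples(group_a + group_b)
    counts = np.asarray(sub.counts, dtype=float)
    totals = counts.sum(axis=0)
    scale = np.where(totals > 0, target_sum / np.where(totals > 0, totals, 1.0), 0.0)
    norm = counts * scale[None, :]

    na, nb = len(group_a), len(group_b)
    xa, xb = norm[:, :na], norm[:, na:]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    pct_a = (xa > 0).mean(axis=1)
    pct_b = (xb > 0).mean(axis=1)
    logfc = np.log(mean_a + pseudocount) - np.log(mean_b + pseudocount)

    tested = (np.abs(logfc) >= logfc_threshold) & (
        np.maximum(pct_a, pct_b) >= min_pct
    )
    n = na + nb
    use_exact = comb(n, na) <= exact_limit

    stat = np.full(sub.n_genes, np.nan)
    p_raw = np.full(sub.n_genes, np.nan)
    mu_w = na * (n + 1) / 2.0
    norm_rank = np.round(norm, 6)  # stabilize ties against scaling round-off
    for i in np.flatnonzero(tested):
        ranks = stats.rankdata(norm_rank[i])
        w = ranks[:na].sum()
        if use_exact:
            p = _exact_ranksum_p(ranks, na)
            z = w - mu_w
        else:
            _, tie_counts = np.unique(norm_rank[i], return_counts=True)
            tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
            var_w = na * nb / 12.0 * ((n + 1) - tie_term)
            if var_w <= 0:
                p, z = 1.0, 0.0
            else:
                z = (w - mu_w) / np.sqrt(var_w)
                p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        stat[i], p_raw[i] = z, p

    p_adj = np.full(sub.n_genes, np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(p_raw[tested])

    table = pd.DataFrame(
        {
            "logfc": logfc,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "dispersion": np.nan,
            "stat": stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "tested": tested,
        },
        index=sub.gene_ids,
    )
    return DEResult(table=table, group_a=tuple(group_a), group_b=tuple(group_b),
                    method="wilcoxon")
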