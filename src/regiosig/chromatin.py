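"""ChIP-qPCR percent-input, bivalency ratios and qPCR expression metrics.

ChIP enrichment is expressed as percent of the diluted input chromatin:
with an input kept at dilution ``f`` (default 1%), the input Ct is first
adjusted by ``log2(1/f)`` and then

    percent_input = 100 * 2 ** (adjusted_input_ct - ip_ct).

The epigenetic state of a promoter is scored by the log2 ratio of the
activating (H3K4me3) to the repressive (H3K27me3) percent-input; a ratio
near zero (within a band of +-epsilon, default 0.5 log2 units) is called
poised, above it active, below it repressed. The IgG control is carried
alongside but not subtracted by default. Expression is summarized relative
to a reference transcript (Gapdh) as delta-Ct, 2^-delta-Ct and 1/delta-Ct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError

__all__ = [
    "percent_input", "bivalency_ratio", "classify_state",
    "expression_metrics", "compare_ratios", "ExprMeasure",
    "chip_table_analysis", "rt_table_analysis",
]


def percent_input(ct_ip, ct_input, input_dilution: float = 0.01):
    """Percent-input enrichment from IP and input Ct values."""
    if not 0.0 < input_dilution <= 1.0:
        raise ConfigError("input_dilution: must lie in (0, 1]")
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    if np.any(~np.isfinite(ct_ip)) or np.any(~np.isfinite(ct_input)):
        raise ConfigError("Ct values must be finite")
    adjusted = ct_input - math.log2(1.0 / input_dilution)
    out = 100.0 * np.exp2(adjusted - ct_ip)
    return float(out) if out.ndim == 0 else out


def bivalency_ratio(pi_k4, pi_k27):
    """``log2(percent_input_K4me3 / percent_input_K27me3)``."""
    pi_k4 = np.asarray(pi_k4, dtype=float)
    pi_k27 = np.asarray(pi_k27, dtype=float)
    if np.any(pi_k4 <= 0) or np.any(pi_k27 <= 0):
        raise ConfigError("percent-input values must be > 0")
    out = np.log2(pi_k4) - np.log2(pi_k27)
    return float(out) if out.ndim == 0 else out


def classify_state(ratio, poised_band: float = 0.5):
    """active if ratio > +band, repressed if ratio < -band, else poised."""
    if poised_band < 0:
        raise ConfigError("poised_band: must be >= 0")
    ratio = np.asarray(ratio, dtype=float)
    labels = np.where(
        ratio > poised_band, "active",
        np.where(ratio < -poised_band, "repressed", "poised"),
    )
    return str(labels) if labels.ndim == 0 else labels


@dataclass
class ExprMeasure:
    """qPCR expression metrics relative to a reference transcript."""

    ct_gene: float
    ct_ref: float
    delta_ct: float
    rel_expr: float
    inv_dct: float  # NaN when delta_ct == 0
    inv_dct_defined: bool


def expression_metrics(ct_gene: float, ct_ref: float) -> ExprMeasure:
    """delta-Ct, relative expression 2^-dCt and 1/dCt versus the reference.

    ``1/dCt`` is undefined at dCt = 0 and returned as NaN with a flag
    rather than raising.
    """
    if not (np.isfinite(ct_gene) and np.isfinite(ct_ref)):
        raise ConfigError("Ct values must be finite")
    dct = float(ct_gene) - float(ct_ref)
    defined = dct != 0.0
    return ExprMeasure(
        ct_gene=float(ct_gene), ct_ref=float(ct_ref), delta_ct=dct,
        rel_expr=float(2.0 ** (-dct)),
        inv_dct=(1.0 / dct) if defined else float("nan"),
        inv_dct_defined=defined,
    )


def compare_ratios(group_a, group_b, paired: bool = False) -> dict:
    """Two-sided Student t test between two samples of log2 ratios.

    Unpaired uses the classical pooled-variance statistic with
    ``n_a + n_b - 2`` degrees of freedom; paired requires equal n in
    matched order and uses ``n - 1``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ConfigError("paired comparison requires equal group sizes")
        res = stats.ttest_rel(a, b)
        df = len(a) - 1
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    t = float(res.statistic)
    p = 1.0 if np.isnan(t) else float(res.pvalue)
    if np.isnan(t):  # identical constant groups: no evidence of difference
        t = 0.0
    return {"t": t, "p": p, "df": df, "paired": paired,
            "n_a": len(a), "n_b": len(b)}


def chip_table_analysis(chip: pd.DataFrame, input_dilution: float = 0.01,
                        poised_band: float = 0.5,
                        per_replicate: bool = True) -> tuple:
    """Resolve a long ChIP Ct table into per-replicate and per-gene results.

    ``chip`` columns: gene, region, mark (H3K4me3 / H3K27me3 / IgG /
    input), replicate, ct. By default the bivalency ratio is computed per
    replicate and then summarized; ``per_replicate=False`` instead forms
    the ratio of replicate-averaged percent-inputs.

    Returns ``(replicates, summary)``: the replicate-level table with
    percent-inputs and ratio, and the per-gene/region summary with the
    mean ratio, its state call, and IgG percent-input alongside.
    """
    required = {"gene", "mark", "replicate", "ct"}
    if not required <= set(chip.columns):
        raise ConfigError(f"chip table needs columns {sorted(required)}")
    chip = chip.copy()
    if "region" not in chip.columns:
        chip["region"] = "NA"
    wide = chip.pivot_table(
        index=["gene", "region", "replicate"], columns="mark", values="ct",
        aggfunc="mean",
    )
    for mark in ("H3K4me3", "H3K27me3", "input"):
        if mark not in wide.columns:
            raise ConfigError(f"chip table lacks mark {mark!r}")
    rep = pd.DataFrame(index=wide.index)
    rep["pi_k4"] = percent_input(wide["H3K4me3"], wide["input"], input_dilution)
    rep["pi_k27"] = percent_input(wide["H3K27me3"], wide["input"], input_dilution)
    if "IgG" in wide.columns:
        rep["pi_igg"] = percent_input(wide["IgG"], wide["input"], input_dilution)
    rep["ratio"] = bivalency_ratio(rep["pi_k4"], rep["pi_k27"])
    rep = rep.reset_index()

    rows = []
    for (gene, region), grp in rep.groupby(["gene", "region"], sort=True):
        if per_replicate:
            mean_ratio = float(grp["ratio"].mean())
        else:
            mean_ratio = float(
                bivalency_ratio(grp["pi_k4"].mean(), grp["pi_k27"].mean())
            )
        rows.append(
            {
                "gene": gene, "region": region, "n": len(grp),
                "pi_k4_mean": float(grp["pi_k4"].mean()),
                "pi_k27_mean": float(grp["pi_k27"].mean()),
                "pi_igg_mean": float(grp["pi_igg"].mean()) if "pi_igg" in grp else np.nan,
                "ratio_mean": mean_ratio,
                "ratio_sem": float(grp["ratio"].sem()) if len(grp) > 1 else np.nan,
                "state": classify_state(mean_ratio, poised_band),
            }
        )
    return rep, pd.DataFrame(rows)


def rt_table_analysis(rt: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression metrics from a long RT-qPCR table.

    ``rt`` columns: gene, replicate, ct_gene, ct_ref. Metrics are computed
    per replicate and averaged; ``inv_dct_mean`` averages only replicates
    where 1/dCt is defined.
    """
    required = {"gene", "ct_gene", "ct_ref"}
    if not required <= set(rt.columns):
        raise ConfigError(f"rt table needs columns {sorted(required)}")
    rows = []
    for gene, grp in rt.groupby("gene", sort=True):
        measures = [
            expression_metrics(g, r)
            for g, r in zip(grp["ct_gene"], grp["ct_ref"])
        ]
        dcts = np.array([m.delta_ct for m in measures])
        rels = np.array([m.rel_expr for m in measures])
        invs = np.array([m.inv_dct for m in measures if m.inv_dct_defined])
        rows.append(
            {
                "gene": gene, "n": len(measures),
                "delta_ct_mean": float(dcts.mean()),
                "rel_expr_mean": float(rels.mean()),
                "inv_dct_mean": float(invs.mean()) if len(invs) else np.nan,
                "n_inv_dct_undefined": len(measures) - len(invs),
            }
        )
    return pd.DataFrame(rows)
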