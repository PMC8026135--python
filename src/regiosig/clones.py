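"""Clone inference from combinatorial reporter codes and dispersion analysis.

Cells labeled with 12 reporter channels (6 fluorophores, each cytoplasmic
or nuclear) are assigned a 12-bit binary code; cells of the same animal
sharing a code are grouped into a clone (codes are not comparable across
animals). Retained clones have at least three cells and more than one
reporter present (popcount >= 2). The NeuN flag types cells as neuronal but
is never part of the clone-identity code. Per clone we quantify the
percentage of member cells in each thalamic nucleus (dLG/VPM/MGv), the
modal home nucleus, and the composition class (mixed / neurons only /
non-neuronal only). Group comparisons use the tie-corrected Kruskal-Wallis
test with Dunn's pairwise z tests (classical Bonferroni-style adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .containers import ConfigError, NUCLEI
from .synthdata import CHANNEL_NAMES

__all__ = [
    "Clone", "call_codes", "group_clones", "classify_clone",
    "dispersion_profile", "kruskal_dunn", "partition_recovery_score",
    "clone_summary",
]


@dataclass
class Clone:
    """Cells of one animal sharing one reporter code."""

    animal_id: str
    code: str
    cell_ids: list
    size: int
    composition: str | None = None
    dispersion: pd.Series | None = None
    home_nucleus: str | None = None
    home_tie: bool = False
    neun_flags: list = field(default_factory=list)
    nuclei: list = field(default_factory=list)

    @property
    def popcount(self) -> int:
        return self.code.count("1")


def _channel_columns(cells: pd.DataFrame, channels=None) -> list:
    if channels is not None:
        cols = list(channels)
    else:
        cols = [c for c in CHANNEL_NAMES if c in cells.columns]
        if not cols:
            cols = [c for c in cells.columns if c.startswith("ch")]
    if len(cols) != 12:
        raise ConfigError(f"expected 12 reporter channels, found {len(cols)}")
    return cols


def call_codes(cells: pd.DataFrame, threshold: float | None = None,
               channels=None) -> pd.DataFrame:
    """Assign each cell its binary reporter code.

    Channels must be either all boolean (passed through; ``threshold``
    ignored) or all numeric intensities (bit = intensity > threshold).
    NeuN is not a code channel. Returns a copy with a ``code`` column of
    12-character bit strings in the documented channel order.
    """
    cols = _channel_columns(cells, channels)
    sub = cells[cols]
    dtype_bool = [pd.api.types.is_bool_dtype(sub[c]) for c in cols]
    if all(dtype_bool):
        bits = sub.to_numpy()
    elif any(dtype_bool):
        raise ConfigError("channels mix boolean and intensity values")
    else:  # all numeric
        if threshold is not None:
            bits = sub.to_numpy(dtype=float) > threshold
        elif (sub.isin([0, 1]).all(axis=None)):
            bits = sub.astype(bool).to_numpy()  # 0/1 table read from disk
        else:
            raise ConfigError("intensity channels require a threshold")
    out = cells.copy()
    out["code"] = ["".join("1" if b else "0" for b in row) for row in bits]
    return out


def classify_clone(neun_flags) -> str:
    """mixed if both NeuN+ and NeuN- members are present, else pure."""
    flags = set(bool(x) for x in neun_flags)
    if flags == {True, False}:
        return "mixed"
    return "neurons_only" if flags == {True} else "nonneuronal_only"


def dispersion_profile(nuclei) -> tuple:
    """Percent of member cells per nucleus, the home (modal) nucleus and a
    tie flag. Ties break by the fixed order dLG > VPM > MGv."""
    s = pd.Series(list(nuclei))
    unknown = set(s) - set(NUCLEI)
    if unknown:
        raise ConfigError(f"unknown nucleus labels {sorted(unknown)}; expected {NUCLEI}")
    pct = pd.Series(
        [100.0 * (s == n).mean() for n in NUCLEI], index=list(NUCLEI), name="pct"
    )
    top = pct.max()
    winners = [n for n in NUCLEI if pct[n] == top]
    return pct, winners[0], len(winners) > 1


def group_clones(cells: pd.DataFrame, min_size: int = 3,
                 min_reporters: int = 2) -> tuple:
    """Partition coded cells into clones and apply the retention filters.

    Clone identity is (animal, code). Retained clones have
    ``size >= min_size`` and ``popcount >= min_reporters`` (defaults: at
    least three cells, more than one reporter). Returns ``(clones,
    discarded)`` where ``discarded`` counts filtered clones and cells.
    """
    if "code" not in cells.columns:
        raise ConfigError("cells need a 'code' column; run call_codes first")
    clones: list = []
    discarded = {"clones_small": 0, "clones_few_reporters": 0, "cells": 0}
    for (animal, code), grp in cells.groupby(["animal_id", "code"], sort=True):
        size = len(grp)
        popcount = code.count("1")
        if size < min_size or popcount < min_reporters:
            if size < min_size:
                discarded["clones_small"] += 1
            else:
                discarded["clones_few_reporters"] += 1
            discarded["cells"] += size
            continue
        clone = Clone(
            animal_id=animal, code=code,
            cell_ids=list(grp["cell_id"]) if "cell_id" in grp else list(grp.index),
            size=size,
        )
        if "neun" in grp.columns:
            clone.neun_flags = list(grp["neun"].astype(bool))
            clone.composition = classify_clone(clone.neun_flags)
        if "nucleus" in grp.columns:
            clone.nuclei = list(grp["nucleus"])
            clone.dispersion, clone.home_nucleus, clone.home_tie = (
                dispersion_profile(clone.nuclei)
            )
        clones.append(clone)
    return clones, discarded


@dataclass
class KruskalDunnResult:
    """Omnibus Kruskal-Wallis H/p plus Dunn pairwise z and adjusted p."""

    h_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame  # columns: group_1, group_2, z, p_raw, p_adj
    group_sizes: dict


def kruskal_dunn(groups: dict) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn's multiple comparisons.

    ``groups`` maps label -> 1-D sample of values. The omnibus H uses the
    standard tie correction; Dunn's pairwise z statistics compare mean
    ranks with the pooled tie-corrected variance and are adjusted by the
    classical Bonferroni-style multiplication over all pairs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ConfigError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(a) == 0 for a in arrays):
        raise ConfigError("all groups must be nonempty")

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)

    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    sizes = [len(a) for a in arrays]
    mean_ranks, offset = [], 0
    for sz in sizes:
        mean_ranks.append(ranks[offset:offset + sz].mean())
        offset += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))

    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (
            1.0 / sizes[i] + 1.0 / sizes[j]
        )
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var) if var > 0 else 0.0
        p_raw = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "group_1": labels[i], "group_2": labels[j],
                "z": z, "p_raw": p_raw, "p_adj": min(1.0, p_raw * m),
            }
        )
    return KruskalDunnResult(
        h_statistic=float(h), p_omnibus=float(p),
        pairwise=pd.DataFrame(rows),
        group_sizes={g: len(a) for g, a in zip(labels, arrays)},
    )


def partition_recovery_score(clones: list, truth: pd.Series) -> float:
    """Adjusted Rand index between inferred clones and the true partition.

    ``truth`` maps cell id -> progenitor id. The score is computed over the
    cells present in both partitions; code collisions that merge distinct
    progenitors lower it. Report alongside
    :func:`regiosig.synthdata.analytic_code_collision_prob`.
    """
    inferred = {}
    for k, clone in enumerate(clones):
        for cell in clone.cell_ids:
            inferred[cell] = k
    shared = [c for c in inferred if c in truth.index]
    if not shared:
        raise ConfigError("no cells shared between inferred and true partitions")
    pred = [inferred[c] for c in shared]
    true = [truth.loc[c] for c in shared]
    return float(adjusted_rand_score(true, pred))


def clone_summary(clones: list) -> dict:
    """Composition fractions, per-home-nucleus dispersion quartiles, counts."""
    comp = pd.Series([c.composition for c in clones]).value_counts().to_dict()
    n = len(clones)
    home_pct = {}
    for nucleus in NUCLEI:
        vals = [
            float(c.dispersion[nucleus]) for c in clones
            if c.home_nucleus == nucleus and c.dispersion is not None
        ]
        if vals:
            q = np.percentile(vals, [25, 50, 75])
            home_pct[nucleus] = {
                "n_clones": len(vals),
                "q25": float(q[0]), "median": float(q[1]), "q75": float(q[2]),
            }
    pure = sum(v for k, v in comp.items() if k in ("neurons_only", "nonneuronal_only"))
    return {
        "n_clones": n,
        "composition_counts": comp,
        "frac_pure": pure / n if n else float("nan"),
        "home_nucleus_dispersion": home_pct,
    }
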