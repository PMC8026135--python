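"""Gene-set overlap statistics: hypergeometric tests and odds ratios.

Sharing between two gene sets A and B inside a universe of N jointly
testable genes is summarized by the 2x2 table (a = |A&B|, b = |A\\B|,
c = |B\\A|, d = remainder) and tested one-sidedly against the
hypergeometric null P[X >= a], X ~ Hypergeom(N, |A|, |B|) — the one-sided
Fisher exact test. The tail is accumulated in log space; underflow to zero
is reported as the smallest positive float with a flag, never silently.

Two odds-ratio estimators are reported: the sample cross-product ad/bc and
the conditional maximum-likelihood estimate under Fisher's noncentral
hypergeometric model (solved by bracketed root finding on the conditional
mean equation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .containers import ConfigError, GeneSet

__all__ = ["OverlapResult", "ComparisonMatrix", "overlap_test",
           "percent_shared", "comparison_matrix"]


@dataclass
class OverlapResult:
    """2x2 overlap contingency with one-sided hypergeometric p and odds ratios."""

    a: int
    b: int
    c: int
    d: int
    N: int
    p_one_sided: float
    or_sample: float
    or_cmle: float
    pct_shared_of_a: float
    pct_shared_of_b: float
    underflow: bool = False
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        if self.a + self.b + self.c + self.d != self.N:
            raise ConfigError("contingency cells must sum to the universe size")
        if not 0.0 <= self.p_one_sided <= 1.0:
            raise ConfigError("p_one_sided outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "set_a": self.name_a, "set_b": self.name_b,
            "a": self.a, "b": self.b, "c": self.c, "d": self.d, "N": self.N,
            "p_one_sided": self.p_one_sided,
            "or_sample": self.or_sample, "or_cmle": self.or_cmle,
            "pct_shared_of_a": self.pct_shared_of_a,
            "pct_shared_of_b": self.pct_shared_of_b,
            "underflow": self.underflow,
        }


def _log_hypergeom_tail(a: int, N: int, nA: int, nB: int) -> tuple:
    """P[X >= a] for X ~ Hypergeom(N, nA, nB), summed in log space."""
    if a <= max(0, nA + nB - N):
        return 1.0, False
    hi = min(nA, nB)
    if a > hi:
        return 0.0, True
    ks = np.arange(a, hi + 1)
    logpmf = stats.hypergeom.logpmf(ks, N, nA, nB)
    p = float(np.exp(logsumexp(logpmf)))
    if p == 0.0:
        return float(np.nextafter(0.0, 1.0)), True
    return min(p, 1.0), False


def _or_cmle(a: int, b: int, c: int, d: int) -> float:
    """Conditional-MLE odds ratio: solve E_psi[X | margins] = a.

    The conditional model is Fisher's noncentral hypergeometric with the
    observed margins; at the support boundaries the estimate is 0 or inf.
    """
    N = a + b + c + d
    nA, nB = a + b, a + c
    lo_support = max(0, nA + nB - N)
    hi_support = min(nA, nB)
    if hi_support == lo_support:
        return float("nan")
    if a == hi_support:
        return float("inf")
    if a == lo_support:
        return 0.0

    def cond_mean_minus_a(log_psi: float) -> float:
        return stats.nchypergeom_fisher.mean(N, nA, nB, np.exp(log_psi)) - a

    lo, hi = -1.0, 1.0
    for _ in range(100):
        if cond_mean_minus_a(lo) < 0:
            break
        lo -= 2.0
    for _ in range(100):
        if cond_mean_minus_a(hi) > 0:
            break
        hi += 2.0
    root = optimize.brentq(cond_mean_minus_a, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(np.exp(root))


def overlap_test(A: GeneSet, B: GeneSet, universe: GeneSet,
                 on_outside: str = "warn") -> OverlapResult:
    """One-sided hypergeometric overlap test of A and B within a universe.

    Members of A or B outside the universe are dropped with a warning
    (``on_outside="warn"``) or raise (``"error"``). Empty A or B is a valid
    degenerate input (a = 0, p = 1); an empty universe is an error.
    """
    if len(universe) == 0:
        raise ConfigError("universe is empty")
    uni = set(universe.genes)
    sa, sb = set(A.genes), set(B.genes)
    for name, s in ((A.name, sa), (B.name, sb)):
        outside = s - uni
        if outside:
            if on_outside == "error":
                raise ConfigError(
                    f"set {name!r} has {len(outside)} genes outside the universe"
                )
            warnings.warn(
                f"set {name!r}: dropping {len(outside)} genes outside the universe",
                stacklevel=2,
            )
    sa &= uni
    sb &= uni

    N = len(uni)
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = N - a - b - c
    p, underflow = _log_hypergeom_tail(a, N, len(sa), len(sb))

    with np.errstate(divide="ignore", invalid="ignore"):
        if b * c > 0:
            or_sample = (a * d) / (b * c)
        elif a * d > 0:
            or_sample = float("inf")
        else:
            or_sample = float("nan")

    return OverlapResult(
        a=a, b=b, c=c, d=d, N=N,
        p_one_sided=p,
        or_sample=float(or_sample),
        or_cmle=_or_cmle(a, b, c, d),
        pct_shared_of_a=100.0 * a / len(sa) if sa else float("nan"),
        pct_shared_of_b=100.0 * a / len(sb) if sb else float("nan"),
        underflow=underflow,
        name_a=A.name, name_b=B.name,
    )


def percent_shared(A: GeneSet, B: GeneSet, denominator: str = "A") -> float:
    """``100 * |A & B| / |denominator set|`` — invariant to the universe."""
    denom = A if denominator.upper() == "A" else B
    if len(denom) == 0:
        raise ConfigError("denominator set is empty")
    return 100.0 * len(A.intersection(B)) / len(denom)


@dataclass
class ComparisonMatrix:
    """Grid of pairwise overlap results (rows x columns of gene sets)."""

    row_names: list
    col_names: list
    results: list  # list of rows, each a list of OverlapResult
    universe_name: str
    p_adjusted: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.results) != len(self.row_names) or any(
            len(row) != len(self.col_names) for row in self.results
        ):
            raise ConfigError("grid dimensions must match the set lists")

    def p_values(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[r.p_one_sided for r in row] for row in self.results],
            index=self.row_names, columns=self.col_names,
        )

    def shared_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[r.a for r in row] for row in self.results],
            index=self.row_names, columns=self.col_names,
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for rname, row in zip(self.row_names, self.results):
            for cname, res in zip(self.col_names, row):
                d = res.to_dict()
                d["set_a"], d["set_b"] = rname, cname
                rows.append(d)
        return pd.DataFrame(rows)


def comparison_matrix(rows, cols, universe: GeneSet,
                      adjust: str | None = None,
                      on_outside: str = "warn") -> ComparisonMatrix:
    """All pairwise overlap tests between two lists of gene sets.

    No multiplicity correction is applied across cells by default;
    ``adjust="bh"`` adds a BH-adjusted p-value grid alongside.
    """
    grid = [
        [overlap_test(r, c, universe, on_outside=on_outside) for c in cols]
        for r in rows
    ]
    cm = ComparisonMatrix(
        row_names=[r.name for r in rows],
        col_names=[c.name for c in cols],
        results=grid,
        universe_name=universe.name,
    )
    if adjust == "bh":
        from .diffexpr import bh_adjust

        flat = np.array([r.p_one_sided for row in grid for r in row])
        adj = bh_adjust(flat).reshape(len(rows), len(cols))
        cm.p_adjusted = pd.DataFrame(adj, index=cm.row_names, columns=cm.col_names)
    elif adjust is not None:
        raise ConfigError("adjust must be None or 'bh'")
    return cm
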