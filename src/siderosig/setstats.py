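"""Contingency-table statistics for gene-list overlap and enrichment.

Gene-signature validation against an independent cohort reduces to a 2x2
table over a shared gene universe: in-both / only-A / only-B / in-neither.
The odds ratio (with a Woolf log-scale confidence interval and the
Haldane-Anscombe zero-cell correction) measures overlap strength; Fisher's
exact test and the 2x2 chi-square provide p-values.  Functional-category
enrichment is the same hypergeometric machinery applied set-by-set, with
Benjamini-Hochberg control across categories and an optional EASE-style
conservative variant (overlap decremented by one).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .differential import benjamini_hochberg

__all__ = [
    "ContingencyTable2x2",
    "GeneSetCollection",
    "EnrichmentResult",
    "overlap_table",
    "odds_ratio_ci",
    "fisher_exact",
    "chi_square_2x2",
    "enrich",
]

# above this total the exact integer hypergeometric path switches to
# log-space (gammaln) weights
_EXACT_TOTAL_LIMIT = 2000


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Integer 2x2 counts; for overlap use, ``a`` is the in-both cell."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.total < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"set {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    expected: float
    p: float
    q: float
    ease_p: float | None = None


def overlap_table(list_a, list_b, universe) -> ContingencyTable2x2:
    """2x2 overlap table of two gene lists over a universe.

    ``a=|A∩B|, b=|A\\B|, c=|B\\A|, d=|universe\\(A∪B)|``.
    """
    A, B, U = set(list_a), set(list_b), set(universe)
    offenders = sorted((A | B) - U)
    if offenders:
        raise ValueError(f"genes outside the universe: {offenders[:10]}")
    a = len(A & B)
    return ContingencyTable2x2(a=a, b=len(A) - a, c=len(B) - a,
                               d=len(U) - len(A | B))


def odds_ratio_ci(
    table: ContingencyTable2x2, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio with a Woolf (log-scale normal) confidence interval.

    When any cell is zero, 0.5 is added to every cell (Haldane-Anscombe)
    before both the ratio and its standard error are computed.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt((1 / cells).sum())
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return (
        float(or_),
        float(or_ * math.exp(-z * se)),
        float(or_ * math.exp(z * se)),
    )


def _hypergeom_margins(table: ContingencyTable2x2) -> tuple[int, int, int, int]:
    N = table.total
    K = table.a + table.b  # row 1 margin
    n = table.a + table.c  # column 1 margin
    return N, K, n, table.a


def fisher_exact(table: ContingencyTable2x2, sidedness: str = "two_sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    ``one_greater`` sums the upper tail P(X >= a); ``two_sided`` sums the
    probability of every table (with the same margins) no more probable
    than the observed one.  Totals up to ``_EXACT_TOTAL_LIMIT`` use exact
    integer weights; larger tables use log-space weights with a relative
    tie tolerance of 1e-7.
    """
    if sidedness not in ("one_greater", "two_sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    N, K, n, a = _hypergeom_margins(table)
    return _hypergeom_p(N, K, n, a, sidedness)


def _hypergeom_p(N: int, K: int, n: int, a: int, sidedness: str) -> float:
    lo = max(0, K + n - N)
    hi = min(K, n)
    a = min(max(a, lo), hi)
    if N <= _EXACT_TOTAL_LIMIT:
        weights = {k: math.comb(K, k) * math.comb(N - K, n - k)
                   for k in range(lo, hi + 1)}
        denom = sum(weights.values())  # == comb(N, n)
        if sidedness == "one_greater":
            num = sum(w for k, w in weights.items() if k >= a)
        else:
            w_obs = weights[a]
            num = sum(w for w in weights.values() if w <= w_obs)
        return num / denom
    ks = np.arange(lo, hi + 1)
    logw = (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    denom = w.sum()
    if sidedness == "one_greater":
        num = w[ks >= a].sum()
    else:
        w_obs = w[ks == a][0]
        num = w[w <= w_obs * (1 + 1e-7)].sum()
    return float(min(1.0, num / denom))


def chi_square_2x2(
    table: ContingencyTable2x2, yates: bool = False
) -> tuple[float, float]:
    """Classical 2x2 chi-square (optionally Yates-corrected) and its p-value.

    ``chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; with Yates the
    absolute cross-product difference is reduced by ``n/2`` (floored at 0)
    before squaring.  One degree of freedom.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square requires all four margins positive")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff**2 / math.prod(margins)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def enrich(
    query, collection: GeneSetCollection, mode: str = "fisher"
) -> list[EnrichmentResult]:
    """One-sided over-representation of *query* in each collection set.

    Per set the p-value is the hypergeometric upper tail of the overlap
    given the set size, query size and universe size; ``mode='ease'``
    decrements the overlap by one (floored at 0) before taking the tail,
    the conservative EASE-score convention.  q-values are
    Benjamini-Hochberg across sets; results are sorted by p.
    """
    if mode not in ("fisher", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    Q = set(query)
    extra = Q - collection.universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:10]}")
    if not Q:
        warnings.warn("empty query: all enrichment p-values are 1", stacklevel=2)
    N = len(collection.universe)
    results = []
    for name, members in collection.sets.items():
        a = len(Q & members)
        a_eff = a if mode == "fisher" else max(a - 1, 0)
        p = _hypergeom_p(N, len(Q), len(members), a_eff, "one_greater") if Q else 1.0
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=a,
                expected=len(Q) * len(members) / N if N else 0.0,
                p=p,
                q=1.0,
                ease_p=p if mode == "ease" else None,
            )
        )
    if results:
        qvals = benjamini_hochberg([r.p for r in results])
        for r, qv in zip(results, qvals):
            r.q = float(qv)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results
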