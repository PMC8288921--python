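"""Exact and asymptotic statistical primitives shared by every pipeline stage.

These are the small tests that the headline contrasts of a knockout-effect
study reduce to: Fisher's exact and chi-square tests on 2x2 contingency
tables (heritable vs non-heritable, conserved vs non-conserved counts),
the hypergeometric upper tail behind GO-term and direct-target enrichment,
the Mann-Whitney U test for h2 distributions, and Benjamini-Hochberg FDR
adjustment.  All of them delegate the numerics to scipy but enforce the
validation and convention choices documented below:

* two-sided Fisher uses the "probability <= observed" tie convention;
* the 2x2 chi-square applies the Yates continuity correction by default,
  with the correction term clamped at |O - E|;
* the hypergeometric tail is the upper tail P(X >= k);
* Mann-Whitney switches from exact enumeration to the tie-corrected
  normal approximation once either sample exceeds 8 observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "ContingencyTable2x2",
    "PValueVector",
    "fisher_exact",
    "chisq_2x2",
    "hypergeom_tail",
    "mann_whitney_u",
    "bh_adjust",
]

Alternative = Literal["two_sided", "greater", "less"]

_ALT_MAP = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 table of non-negative counts.

    Rows are groups (e.g. clustered / distributed effects), columns are
    outcomes (e.g. significant / not significant).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        for x in cells:
            if not float(x).is_integer() or x < 0:
                raise ValueError(f"cell counts must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("at least one cell must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class PValueVector:
    """Raw and adjusted P-values in original input order."""

    raw: list[float]
    adjusted: list[float] = field(default_factory=list)
    method: str = "none"


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    return ContingencyTable2x2(*(int(x) for x in arr.ravel()))


def fisher_exact(table, alternative: Alternative = "two_sided") -> float:
    """Fisher's exact test P-value on a 2x2 table.

    The two-sided P-value sums the probabilities of every table with the
    same margins whose hypergeometric probability does not exceed that of
    the observed table (within relative tolerance for floating-point ties);
    ``greater`` / ``less`` are the hypergeometric tails on cell ``a``.

    A table with an empty row or column margin carries no information and
    returns 1.0.
    """
    t = _as_table(table)
    if alternative not in _ALT_MAP:
        raise ValueError(f"unknown alternative {alternative!r}")
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(_st.fisher_exact(arr, alternative=_ALT_MAP[alternative])[1])


def chisq_2x2(table, correction: bool = True) -> float:
    """Pearson chi-square test on a 2x2 table, 1 degree of freedom.

    With ``correction=True`` the Yates continuity correction subtracts
    min(0.5, |O - E|) from each cell's |O - E|, so the corrected deviation
    never goes negative and a table at its expectation yields statistic 0,
    P = 1.
    """
    t = _as_table(table)
    arr = t.as_array().astype(float)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin: expected counts are zero")
    expected = np.outer(rows, cols) / arr.sum()
    dev = np.abs(arr - expected)
    if correction:
        dev = dev - np.minimum(0.5, dev)
    stat = float((dev**2 / expected).sum())
    return float(_st.chi2.sf(stat, df=1))


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    Arguments follow the enrichment convention: ``k`` successes observed in
    a sample of ``n`` draws, from a population of ``N`` containing ``K``
    successes.  Computed through scipy's survival function, which works in
    log space internally and survives magnitudes far below 1e-15.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if not (k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent hypergeometric arguments k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(_st.hypergeom.sf(k - 1, N, K, n))


_EXACT_MAX = 8  # per-group size at or below which the exact null is enumerated


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U test P-value.

    Uses the exact permutation null when both samples have at most 8
    observations and no ties are present; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size <= _EXACT_MAX and y.size <= _EXACT_MAX and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = _st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))


def bh_adjust(raw: Sequence[float] | PValueVector) -> PValueVector:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    adjusted_(i) = min over j >= i of p_(j) * m / j after sorting by raw P,
    capped at 1.
    """
    if isinstance(raw, PValueVector):
        raw = raw.raw
    p = np.asarray(raw, dtype=float)
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValueError("raw P-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return PValueVector(raw=[], adjusted=[], method="bh")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    adj = np.maximum(adj, p)  # guard a float rounding ulp below the raw value
    return PValueVector(raw=list(map(float, p)), adjusted=list(map(float, adj)), method="bh")
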