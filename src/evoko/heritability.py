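"""Single-locus heritability of expression traits in a segregant population.

A cross between a wild-type strain and a deletion line yields tetrads of
haploid segregants; selecting tetrads with 2:2 allele balance at the focal
locus gives a small population in which, for each expression trait y
(log2 RPKM across segregants), the mixed model

    y = mu * 1_N + u + e,      V = A * sigma2_u + I * sigma2_e

partitions variance into a locus-attributable component (A is the
same-allele indicator relatedness matrix built from the focal locus) and
residual noise.  Heritability h2 = sigma2_u / (sigma2_u + sigma2_e) is
estimated by REML, profiling out sigma2_e and maximizing the restricted
likelihood over the variance ratio with Brent's method on the bounded
h2 scale.  On a balanced two-group design this REML fit coincides with the
one-way random-effects ANOVA estimator, which the test suite exploits as
an independent closed-form oracle.

Significance of h2 follows the study procedure: a per-gene two-group
differential test between the allele classes (Welch's t on log2 RPKM),
BH-adjusted over exactly the tested gene family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as _st

from .stats import bh_adjust, mann_whitney_u

__all__ = [
    "SegregantPopulation",
    "HeritabilityResult",
    "build_relatedness",
    "reml_h2",
    "h2_significance",
    "compare_h2_groups",
]

_H2_EPS = 1e-10  # estimates below this collapse to the boundary


@dataclass
class SegregantPopulation:
    """Expression over segregants plus focal-locus genotype and tetrad labels.

    ``expression``: gene x segregant DataFrame of log2(RPKM);
    ``genotype``: 1 for the wild-type allele, 0 for the null allele;
    ``tetrad``: meiosis-of-origin label per segregant.
    """

    expression: pd.DataFrame
    genotype: np.ndarray
    tetrad: np.ndarray

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype)
        self.tetrad = np.asarray(self.tetrad)
        n = self.expression.shape[1]
        if self.genotype.shape != (n,) or self.tetrad.shape != (n,):
            raise ValueError("genotype and tetrad must have one entry per segregant")
        if not set(np.unique(self.genotype)) <= {0, 1}:
            raise ValueError("genotype must be binary (1 wild-type, 0 null)")
        for t in np.unique(self.tetrad):
            sel = self.tetrad == t
            if sel.sum() != 4 or self.genotype[sel].sum() != 2:
                raise ValueError(f"tetrad {t!r} is not 2:2 genotype-balanced with 4 spores")


@dataclass
class HeritabilityResult:
    gene: str
    sigma2_u: float
    sigma2_e: float
    h2: float
    p_raw: float = np.nan
    p_adj: float = np.nan
    significant: bool = False
    zero_variance: bool = False


def build_relatedness(genotype) -> np.ndarray:
    """Same-allele indicator relatedness: A_ij = 1 iff i and j share the allele."""
    g = np.asarray(genotype)
    if not set(np.unique(g)) <= {0, 1}:
        raise ValueError("genotype must be binary")
    if np.unique(g).size < 2:
        raise ValueError("monomorphic genotype: h2 is unidentifiable")
    return (g[:, None] == g[None, :]).astype(float)


_LAMBDA_MAX = 1e12  # variance-ratio search bound; h2 at the bound is ~1


def _reml_score(lam: float, d: np.ndarray, x2: np.ndarray, z2: np.ndarray, xz: np.ndarray, n: int) -> float:
    # Derivative in lambda = sigma2_u/sigma2_e of the negative restricted
    # log-likelihood (sigma2_e profiled out); the REML optimum is its root.
    w = 1.0 / (1.0 + lam * d)
    sxx = float((w * x2).sum())
    beta = float((w * xz).sum()) / sxx
    r2 = z2 - 2 * beta * xz + beta * beta * x2
    q = max(float((w * r2).sum()), 1e-300)
    term_logdet = float((d * w).sum())
    term_sxx = float((d * w * w * x2).sum()) / sxx
    term_q = float((d * w * w * r2).sum()) / q
    return term_logdet - term_sxx - (n - 1) * term_q


def reml_h2(y, A) -> HeritabilityResult:
    """REML variance components for y = mu + u + e with cov(u) = A*sigma2_u.

    Works through the eigendecomposition of A, reducing the restricted
    likelihood to a smooth 1-D function of the variance ratio whose
    stationary point is located by Brent root-finding on the analytic
    score (boundary solutions at ratio 0 are detected from the score's
    sign).  A constant trait returns h2 = 0 with the ``zero_variance``
    flag rather than raising.
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray(A, dtype=float)
    n = y.size
    if A.shape != (n, n):
        raise ValueError(f"A must be {n}x{n} to match y")
    if np.var(y) == 0:
        return HeritabilityResult(gene="", sigma2_u=0.0, sigma2_e=0.0, h2=0.0, zero_variance=True)

    d, U = np.linalg.eigh(A)
    d = np.maximum(d, 0.0)
    z = U.T @ y
    x = U.T @ np.ones(n)
    x2, z2, xz = x * x, z * z, x * z

    score = lambda lam: _reml_score(lam, d, x2, z2, xz, n)  # noqa: E731
    if score(0.0) >= 0.0:
        lam = 0.0  # likelihood decreasing in the ratio: boundary solution
    else:
        hi = 1.0
        while score(hi) < 0.0 and hi < _LAMBDA_MAX:
            hi *= 8.0
        if score(hi) < 0.0:
            lam = _LAMBDA_MAX
        else:
            lam = float(optimize.brentq(score, hi / 8.0 if hi > 1.0 else 0.0, hi, xtol=1e-300, rtol=8.9e-16))
    if lam / (1.0 + lam) < _H2_EPS:
        lam = 0.0
    w = 1.0 / (1.0 + lam * d)
    sxx = float((w * x2).sum())
    beta = float((w * xz).sum()) / sxx
    q = float((w * (z2 - 2 * beta * xz + beta * beta * x2)).sum())
    sigma2_e = max(q / (n - 1), 1e-12)
    sigma2_u = lam * sigma2_e
    return HeritabilityResult(
        gene="",
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        h2=sigma2_u / (sigma2_u + sigma2_e),
    )


def anova_h2(y, genotype) -> tuple[float, float, float]:
    """Balanced one-way random-effects ANOVA estimator (closed-form oracle).

    Returns (sigma2_u, sigma2_e, h2) with sigma2_u = max(0, (MSB - MSW)/m)
    for group size m.  Valid for balanced two-group designs only.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotype)
    groups = [y[g == v] for v in np.unique(g)]
    m = len(groups[0])
    if any(len(gr) != m for gr in groups):
        raise ValueError("ANOVA closed form requires a balanced design")
    grand = y.mean()
    msb = m * sum((gr.mean() - grand) ** 2 for gr in groups) / (len(groups) - 1)
    msw = sum(((gr - gr.mean()) ** 2).sum() for gr in groups) / (y.size - len(groups))
    s2u = max(0.0, (msb - msw) / m)
    s2e = msw
    h2 = 0.0 if s2u == 0 else s2u / (s2u + s2e)
    return s2u, s2e, h2


def h2_significance(
    expression: pd.DataFrame,
    genotype,
    test_genes: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group allele-difference test per gene, BH over exactly that family.

    Welch's t-test on log2 RPKM between the wild-type- and null-allele
    segregant groups; returns a DataFrame (gene, p_raw, p_adj, significant).
    """
    g = np.asarray(genotype)
    if (g == 1).sum() < 2 or (g == 0).sum() < 2:
        raise ValueError("each genotype group needs at least 2 segregants")
    genes = list(expression.index) if test_genes is None else list(test_genes)
    vals = expression.loc[genes].to_numpy(dtype=float)
    a, b = vals[:, g == 1], vals[:, g == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = _st.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    p = np.where(np.isfinite(p), p, 1.0)
    adj = np.asarray(bh_adjust(p).adjusted)
    return pd.DataFrame(
        {"gene": genes, "p_raw": p, "p_adj": adj, "significant": adj < alpha}
    )


def estimate_h2_table(pop: SegregantPopulation, test_genes=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene REML h2 plus allele-difference significance, as one table."""
    genes = list(pop.expression.index) if test_genes is None else list(test_genes)
    A = build_relatedness(pop.genotype)
    rows = []
    for gname in genes:
        r = reml_h2(pop.expression.loc[gname].to_numpy(dtype=float), A)
        rows.append((gname, r.sigma2_u, r.sigma2_e, r.h2, r.zero_variance))
    tab = pd.DataFrame(rows, columns=["gene", "sigma2_u", "sigma2_e", "h2", "zero_variance"])
    sig = h2_significance(pop.expression, pop.genotype, genes, alpha=alpha)
    return tab.merge(sig, on="gene")


def compare_h2_groups(h2_clustered, h2_distributed) -> float:
    """Two-sided Mann-Whitney U comparing h2 between effect classes."""
    return mann_whitney_u(h2_clustered, h2_distributed)
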