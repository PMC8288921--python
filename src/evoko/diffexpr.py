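"""Responsive-gene calling from RNA-seq count matrices.

A gene is "responsive" to a deletion when its expression differs
significantly between the deletion line and its isogenic wild type:
adjusted P < 0.05 and fold change > 1.5 by default.  The test is a
transparent negative-binomial Wald test on normalized counts
(median-of-ratios size factors, method-of-moments gene-wise dispersion
shrunk toward a fitted mean-dispersion trend).  Externally computed
effect tables (e.g. from DESeq2 or a published compendium) can be
ingested instead, with significance recomputed from the supplied
thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import bh_adjust

__all__ = [
    "CountMatrix",
    "EffectTable",
    "URACIL_PATHWAY_GENES",
    "rpkm",
    "call_responsive_genes",
    "ingest_effect_table",
]

# Uracil-biosynthesis genes respond to the URA3 selection cassette, not to the
# focal deletion, and are excluded from responsive-gene calling by default.
URACIL_PATHWAY_GENES = frozenset(
    {
        "YBL039C",
        "YEL021W",
        "YJL130C",
        "YJR103W",
        "YKL024C",
        "YKL216W",
        "YLR420W",
        "YML106W",
        "YMR271C",
    }
)


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with sample metadata.

    ``metadata`` has one row per sample with columns ``sample``, ``strain``,
    ``genotype`` (``wild_type`` or ``deletion``) and ``replicate``.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gene_lengths.shape != (len(self.genes),):
            raise ValueError("gene_lengths must have one entry per gene")

    def to_tsv(self, counts_path, metadata_path=None) -> None:
        df = pd.DataFrame(self.counts, index=self.genes, columns=self.samples)
        df.insert(0, "length", self.gene_lengths.astype(int))
        df.to_csv(counts_path, sep="\t", index_label="gene")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, metadata_path=None) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col="gene")
        lengths = df.pop("length").to_numpy(dtype=float)
        meta = (
            pd.read_csv(metadata_path, sep="\t")
            if metadata_path is not None
            else pd.DataFrame({"sample": df.columns})
        )
        return cls(
            genes=list(df.index),
            samples=list(df.columns),
            counts=df.to_numpy(),
            gene_lengths=lengths,
            metadata=meta,
        )


#: Effect tables are plain DataFrames with the columns below; ``direction`` is
#: +1 (up in mutant) or -1 (down), ``tested`` is False for genes removed by the
#: low-count filter.
EFFECT_COLUMNS = ["gene", "log2fc", "p_raw", "p_adj", "direction", "significant", "tested"]
EffectTable = pd.DataFrame


def rpkm(matrix: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million: count / (length/1e3) / (library/1e6)."""
    if (matrix.gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libsize = matrix.counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        raise ValueError("zero library size in at least one sample")
    vals = matrix.counts / (matrix.gene_lengths[:, None] / 1e3) / (libsize[None, :] / 1e6)
    return pd.DataFrame(vals, index=matrix.genes, columns=matrix.samples)


def _size_factors(counts: np.ndarray) -> np.ndarray:
    # DESeq median-of-ratios: ratio of each sample to the geometric-mean
    # pseudo-reference, over genes expressed in every sample.
    logc = np.log(counts, out=np.full(counts.shape, -np.inf), where=counts > 0)
    ref = logc.mean(axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        return np.ones(counts.shape[1])
    ratios = logc[usable] - ref[usable, None]
    return np.exp(np.median(ratios, axis=0))


def _dispersion(q: np.ndarray, groups: np.ndarray, prior_df: float = 10.0) -> np.ndarray:
    """Method-of-moments NB dispersion with shrinkage toward a 1/mean trend.

    ``q`` is the normalized count matrix, ``groups`` labels the two
    conditions.  Gene-wise dispersion comes from the pooled within-group
    variance (var = mu + a*mu^2); the trend a(mu) = a0 + a1/mu is fitted by
    least squares over genes with positive raw dispersion, and the gene-wise
    value is shrunk toward it with ``prior_df`` pseudo-degrees of freedom.
    """
    n = q.shape[1]
    means = np.zeros(q.shape[0])
    ss = np.zeros(q.shape[0])
    df = 0
    mu_pool = np.zeros(q.shape[0])
    for g in np.unique(groups):
        sel = groups == g
        m = q[:, sel].mean(axis=1)
        ss += ((q[:, sel] - m[:, None]) ** 2).sum(axis=1)
        df += sel.sum() - 1
        mu_pool += m * sel.sum()
    mu_pool /= n
    s2 = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu_pool) / mu_pool**2
    raw = np.where(np.isfinite(raw), raw, 0.0)

    ok = (raw > 0) & (mu_pool > 0)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_pool[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0, a1 = max(np.median(raw[ok]) if ok.any() else 0.01, 1e-4), 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu_pool, 1e-8)
    w = df / (df + prior_df)
    disp = w * np.maximum(raw, 0.0) + (1 - w) * trend
    return np.maximum(disp, 1e-8)


def call_responsive_genes(
    wt: CountMatrix,
    mut: CountMatrix,
    alpha: float = 0.05,
    min_fc: float = 1.5,
    exclude: frozenset[str] | set[str] = URACIL_PATHWAY_GENES,
    min_total_count: float = 10.0,
) -> EffectTable:
    """Negative-binomial Wald test of deletion line vs wild type.

    Returns an effect table over the shared gene universe minus ``exclude``;
    genes whose total normalized count falls below ``min_total_count`` are
    reported untested (NaN P-values).  Significance requires adjusted
    P < ``alpha`` and fold change > ``min_fc`` on the ratio scale
    (|log2fc| > log2(min_fc)).
    """
    if wt.genes != mut.genes:
        raise ValueError("wild-type and mutant matrices must share the gene universe")
    if len(wt.samples) < 2 or len(mut.samples) < 2:
        raise ValueError("need at least 2 replicates per condition")
    keep = [g not in exclude for g in wt.genes]
    genes = [g for g, k in zip(wt.genes, keep) if k]
    counts = np.concatenate([wt.counts[keep], mut.counts[keep]], axis=1).astype(float)
    groups = np.array([0] * len(wt.samples) + [1] * len(mut.samples))

    sf = _size_factors(counts)
    q = counts / sf[None, :]
    disp = _dispersion(q, groups)

    n0, n1 = len(wt.samples), len(mut.samples)
    mu0 = q[:, groups == 0].mean(axis=1)
    mu1 = q[:, groups == 1].mean(axis=1)

    zero_mean = (mu0 == 0) | (mu1 == 0)
    pseudo = np.where(zero_mean, 0.5, 0.0)
    log2fc = np.log2(mu1 + pseudo) - np.log2(mu0 + pseudo)

    # Delta-method variance of log mean under NB: Var(mean)/mean^2 = (1/mu + a)/n
    with np.errstate(divide="ignore"):
        var_ln = (1.0 / np.maximum(mu0, pseudo + 1e-12) + disp) / n0 + (
            1.0 / np.maximum(mu1, pseudo + 1e-12) + disp
        ) / n1
    se_ln = np.sqrt(var_ln)
    z = (log2fc * math.log(2)) / se_ln
    p_raw = 2.0 * _st.norm.sf(np.abs(z))

    tested = q.sum(axis=1) >= min_total_count
    p_raw = np.where(tested, p_raw, np.nan)
    p_adj = np.full_like(p_raw, np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(p_raw[tested]).adjusted

    lfc_cut = math.log2(min_fc)
    significant = tested & (p_adj < alpha) & (np.abs(log2fc) > lfc_cut)
    direction = np.where(log2fc > 0, 1, -1)

    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
            "significant": significant,
            "tested": tested,
        }
    )


def ingest_effect_table(
    path,
    alpha: float = 0.05,
    min_fc: float = 1.2,
    escalation_count: int = 1500,
    escalated_alpha: float = 0.01,
    use_adjusted: bool | None = None,
) -> EffectTable:
    """Load a precomputed per-gene effect table and recompute significance.

    Expects a TSV with columns ``gene``, ``fc`` or ``log2fc``, and ``p``
    (optionally ``p_adj``).  Mirrors the compendium convention: raw
    P < ``alpha`` and |FC| > ``min_fc``, escalating to ``escalated_alpha``
    when more than ``escalation_count`` genes pass the lenient cutoff.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene"} - set(df.columns)
    if "fc" not in df.columns and "log2fc" not in df.columns:
        missing.add("fc (or log2fc)")
    if "p" not in df.columns and "p_raw" not in df.columns:
        missing.add("p")
    if missing:
        raise ValueError(f"effect table {path} is missing columns: {sorted(missing)}")

    if "log2fc" in df.columns:
        log2fc = df["log2fc"].to_numpy(dtype=float)
    else:
        fc = df["fc"].to_numpy(dtype=float)
        # Ratio-scale FC; values below 1 are down-regulation.
        log2fc = np.log2(np.abs(fc))
        log2fc[fc < 0] = -np.log2(np.abs(fc[fc < 0]))
    p = df["p"].to_numpy(dtype=float) if "p" in df.columns else df["p_raw"].to_numpy(dtype=float)
    p_adj = df["p_adj"].to_numpy(dtype=float) if "p_adj" in df.columns else bh_adjust(p).adjusted

    lfc_cut = math.log2(min_fc)
    sig = (p < alpha) & (np.abs(log2fc) > lfc_cut)
    if int(sig.sum()) > escalation_count:
        sig = (p < escalated_alpha) & (np.abs(log2fc) > lfc_cut)

    return pd.DataFrame(
        {
            "gene": df["gene"],
            "log2fc": log2fc,
            "p_raw": p,
            "p_adj": np.asarray(p_adj, dtype=float),
            "direction": np.where(log2fc > 0, 1, -1),
            "significant": sig,
            "tested": True,
        }
    )
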