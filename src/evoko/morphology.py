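"""Morphological-trait effects of deletion lines.

Image-derived quantitative traits (areas, distances, angles of mother
cell, bud and nuclei; 405 traits when actin is unstained) are compared
between replicates of a deletion line and the matching wild type.
Because replicate counts are large, many traits reach statistical
significance with negligible biological difference, so a trait counts as
affected only when adjusted P < 0.05 AND the wild-type-to-mutant change
exceeds 5% of the wild-type mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import bh_adjust, fisher_exact

__all__ = ["TraitTable", "call_trait_effects", "conserved_shared_contrast"]


@dataclass
class TraitTable:
    """Trait-by-replicate values for one line."""

    values: pd.DataFrame  # traits x replicates
    line: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 replicates")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="trait")

    @classmethod
    def from_tsv(cls, path, line: str = "", genotype: str = "") -> "TraitTable":
        return cls(values=pd.read_csv(path, sep="\t", index_col="trait"), line=line, genotype=genotype)


def call_trait_effects(
    wt: TraitTable,
    mut: TraitTable,
    alpha: float = 0.05,
    min_rel_diff: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per trait, BH over all traits, plus the 5% magnitude rule.

    Returns a DataFrame (trait, mean_wt, mean_mut, rel_diff, p_raw, p_adj,
    direction, affected, skipped); traits with a zero wild-type mean have
    an undefined relative difference and are flagged skipped.
    """
    if list(wt.values.index) != list(mut.values.index):
        raise ValueError("wild-type and mutant tables must share the trait list")
    a = wt.values.to_numpy(dtype=float)
    b = mut.values.to_numpy(dtype=float)
    mean_wt, mean_mut = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = _st.ttest_ind(b, a, axis=1, equal_var=False).pvalue
    p = np.where(np.isfinite(p), p, 1.0)
    adj = np.asarray(bh_adjust(p).adjusted)
    skipped = mean_wt == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(mean_mut - mean_wt) / np.abs(mean_wt)
    rel = np.where(skipped, np.nan, rel)
    affected = ~skipped & (adj < alpha) & (rel > min_rel_diff)
    return pd.DataFrame(
        {
            "trait": wt.values.index,
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "rel_diff": rel,
            "p_raw": p,
            "p_adj": adj,
            "direction": np.where(mean_mut >= mean_wt, 1, -1),
            "affected": affected,
            "skipped": skipped,
        }
    )


def conserved_shared_contrast(
    conserved_affected: set[str],
    nonconserved_affected: set[str],
    shared_all_lines: set[str],
) -> dict:
    """Are conserved trait effects shared across all lines more often?

    One-tailed (greater) Fisher's exact test on the 2x2 table
    [conserved vs non-conserved] x [shared with all other lines vs not].
    Returns the P-value plus per-class sharing proportions with binomial SE.
    """
    if conserved_affected & nonconserved_affected:
        raise ValueError("conserved and non-conserved trait sets must be disjoint")
    a = len(conserved_affected & shared_all_lines)
    b = len(conserved_affected) - a
    c = len(nonconserved_affected & shared_all_lines)
    d = len(nonconserved_affected) - c
    p = fisher_exact([[a, b], [c, d]], alternative="greater")

    def _prop(k: int, n: int) -> tuple[float, float]:
        if n == 0:
            return float("nan"), float("nan")
        r = k / n
        return r, float(np.sqrt(r * (1 - r) / n))

    rc, sc = _prop(a, a + b)
    rn, sn = _prop(c, c + d)
    return {
        "p": p,
        "conserved_shared": a,
        "conserved_total": a + b,
        "nonconserved_shared": c,
        "nonconserved_total": c + d,
        "conserved_rate": rc,
        "conserved_se": sc,
        "nonconserved_rate": rn,
        "nonconserved_se": sn,
    }
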