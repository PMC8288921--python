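"""Cross-strain / cross-species conservation of deletion effects.

An effect defined in the reference strain is *conserved* when the same
gene is also significantly changed in the target strain or species'
deletion line — under the same statistical cutoffs — with the same
direction of change.  Rates are anchored on the reference's significant
set (denominators come from the reference only); the contrast between
effect classes is a 2x2 chi-square with continuity correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import EffectTable
from .stats import chisq_2x2

__all__ = ["call_conserved", "conservation_contrast"]


def call_conserved(
    reference: EffectTable,
    target: EffectTable,
    orthologs: pd.DataFrame | None = None,
    min_reference_rpkm: float | None = None,
    reference_rpkm: pd.Series | None = None,
) -> dict:
    """Conservation calls for reference-significant genes.

    ``orthologs`` (optional) maps reference gene ids to target ids
    (columns ``reference``, ``target``).  ``min_reference_rpkm`` with
    ``reference_rpkm`` drops lowly expressed reference genes from the
    denominator (robustness filter) without altering individual calls.

    Returns ``calls`` (DataFrame: gene, direction_reference,
    significant_in_target, direction_target, conserved), plus the
    conservation ``rate`` and its binomial ``se``.
    """
    ref_sig = reference[reference["significant"]]
    if min_reference_rpkm is not None:
        if reference_rpkm is None:
            raise ValueError("min_reference_rpkm requires reference_rpkm values")
        keep = reference_rpkm.reindex(ref_sig["gene"]).to_numpy() >= min_reference_rpkm
        ref_sig = ref_sig[keep]
    if len(ref_sig) == 0:
        return {"calls": pd.DataFrame(), "rate": float("nan"), "se": float("nan"), "n": 0}

    mapping = None
    if orthologs is not None:
        if not {"reference", "target"} <= set(orthologs.columns):
            raise ValueError("ortholog table needs columns 'reference' and 'target'")
        mapping = dict(zip(orthologs["reference"], orthologs["target"]))

    tgt = target.set_index("gene")
    rows = []
    for g, d_ref in zip(ref_sig["gene"], ref_sig["direction"]):
        tg = mapping.get(g, None) if mapping is not None else g
        if tg is not None and tg in tgt.index:
            sig_t = bool(tgt.loc[tg, "significant"])
            d_t = int(tgt.loc[tg, "direction"])
        else:
            sig_t, d_t = False, 0
        rows.append((g, int(d_ref), sig_t, d_t, sig_t and d_t == int(d_ref)))
    calls = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "direction_reference",
            "significant_in_target",
            "direction_target",
            "conserved",
        ],
    )
    n = len(calls)
    rate = calls["conserved"].mean()
    se = float(np.sqrt(rate * (1 - rate) / n))
    return {"calls": calls, "rate": float(rate), "se": se, "n": n}


def conservation_contrast(
    clustered: tuple[int, int],
    distributed: tuple[int, int],
    correction: bool = True,
) -> float:
    """Chi-square P comparing conservation counts between effect classes.

    ``clustered`` and ``distributed`` are (conserved, total) pairs.
    """
    (kc, nc), (kd, nd) = clustered, distributed
    if nc <= 0 or nd <= 0:
        raise ValueError("totals must be positive")
    if kc > nc or kd > nd:
        raise ValueError("conserved counts cannot exceed totals")
    return chisq_2x2([[kc, nc - kc], [kd, nd - kd]], correction=correction)
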