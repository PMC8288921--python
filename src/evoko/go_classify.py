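"""GO enrichment of responsive genes and clustered/distributed classification.

The central dichotomy of the package: a knockout-responsive gene whose
annotation places it inside at least one significantly enriched GO term
(among the responsive set) is a *clustered* effect — interpreted as an
evolutionarily selected consequence of losing the gene's native function —
while a responsive gene outside every enriched term is a *distributed*
effect, an ad hoc response scattered across unrelated processes.

Enrichment is the classical hypergeometric over-representation test,
stratified by ontology class (BP/MF/CC), with the field's fold-enrichment
statistic FE = (k/n)/(K/N) and the cutoffs adjusted P < 0.01, FE > 2,
term size < 200.  Annotations are used flat, exactly as supplied (no DAG
up-propagation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .stats import bh_adjust, hypergeom_tail

__all__ = [
    "GOAnnotationSet",
    "EnrichmentResult",
    "EffectClassification",
    "DEFAULT_EXCLUDED_EVIDENCE",
    "DIRECT_ASSAY_EVIDENCE",
    "filter_evidence",
    "enrich",
    "classify_effects",
]

# Computational-analysis and other less reliable evidence codes dropped in
# the default mode; the strict mode keeps only direct experimental assays.
DEFAULT_EXCLUDED_EVIDENCE = frozenset(
    {"IBA", "IC", "IEA", "IKR", "IRD", "ISA", "ISM", "ISO", "ISS", "NAS", "ND", "TAS"}
)
DIRECT_ASSAY_EVIDENCE = frozenset({"IDA", "HDA", "IPI"})


@dataclass
class GOAnnotationSet:
    """Flat term -> gene-set annotation with per-class backgrounds.

    ``terms`` maps term id to the annotated gene set, ``ontology`` maps term
    id to its class (BP, MF or CC), ``evidence`` optionally records the
    evidence codes supporting each (gene, term) pair.
    """

    terms: dict[str, set[str]]
    ontology: dict[str, str]
    description: dict[str, str] = field(default_factory=dict)
    evidence: dict[tuple[str, str], set[str]] | None = None

    def __post_init__(self) -> None:
        for t, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {t} has an empty gene set")
            if t not in self.ontology:
                raise ValueError(f"term {t} has no ontology class")

    def class_background(self, ontology_class: str) -> set[str]:
        """Union of genes annotated to any term of the class."""
        out: set[str] = set()
        for t, genes in self.terms.items():
            if self.ontology[t] == ontology_class:
                out |= genes
        return out

    def classes(self) -> list[str]:
        return sorted(set(self.ontology.values()))

    def term_size(self, term: str) -> int:
        return len(self.terms[term])

    # --- I/O -------------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = []
        for t in sorted(self.terms):
            for g in sorted(self.terms[t]):
                ev = ""
                if self.evidence is not None:
                    ev = ";".join(sorted(self.evidence.get((g, t), set())))
                rows.append((g, t, self.ontology[t], ev))
        pd.DataFrame(rows, columns=["gene", "term", "ontology_class", "evidence"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "GOAnnotationSet":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if not {"gene", "term"} <= set(df.columns):
            raise ValueError("annotation TSV needs at least columns gene, term")
        if "ontology_class" not in df.columns:
            df["ontology_class"] = "BP"
        has_ev = "evidence" in df.columns and df["evidence"].str.len().gt(0).any()
        terms: dict[str, set[str]] = {}
        onto: dict[str, str] = {}
        ev: dict[tuple[str, str], set[str]] = {}
        for row in df.itertuples(index=False):
            terms.setdefault(row.term, set()).add(row.gene)
            onto[row.term] = row.ontology_class
            if has_ev and row.evidence:
                ev.setdefault((row.gene, row.term), set()).update(row.evidence.split(";"))
        return cls(terms=terms, ontology=onto, evidence=ev if has_ev else None)

    @classmethod
    def from_gaf(cls, path) -> "GOAnnotationSet":
        """Parse a GAF 2.2 file: columns 2 (gene), 5 (term), 7 (evidence), 9 (aspect)."""
        aspect_map = {"P": "BP", "F": "MF", "C": "CC"}
        terms: dict[str, set[str]] = {}
        onto: dict[str, str] = {}
        ev: dict[tuple[str, str], set[str]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9:
                    raise ValueError(f"malformed GAF line ({len(cols)} columns)")
                gene, term, code, aspect = cols[1], cols[4], cols[6], cols[8]
                terms.setdefault(term, set()).add(gene)
                onto[term] = aspect_map.get(aspect, aspect)
                ev.setdefault((gene, term), set()).add(code)
        return cls(terms=terms, ontology=onto, evidence=ev)


@dataclass
class EnrichmentResult:
    term_id: str
    ontology_class: str
    k: int  # responsive genes in term
    n: int  # responsive genes in class background
    K: int  # genes in term
    N: int  # genes in all terms of the class
    fold_enrichment: float
    p_raw: float
    p_adj: float
    passes: bool


@dataclass
class EffectClassification:
    """Partition of a responsive set into clustered and distributed effects."""

    labels: dict[str, str]  # gene -> "clustered" | "distributed"
    supporting_terms: dict[str, list[str]]  # gene -> passing terms containing it

    @property
    def clustered(self) -> set[str]:
        return {g for g, l in self.labels.items() if l == "clustered"}

    @property
    def distributed(self) -> set[str]:
        return {g for g, l in self.labels.items() if l == "distributed"}

    def to_tsv(self, path) -> None:
        rows = [
            (g, self.labels[g], ";".join(self.supporting_terms.get(g, [])))
            for g in sorted(self.labels)
        ]
        pd.DataFrame(rows, columns=["gene", "label", "supporting_terms"]).to_csv(
            path, sep="\t", index=False
        )


def filter_evidence(annotation: GOAnnotationSet, mode: str = "default_exclusions") -> GOAnnotationSet:
    """Restrict annotations by evidence code.

    ``default_exclusions`` removes computational and other indirect codes
    (IBA, IC, IEA, ..., TAS); ``direct_assay_only`` keeps only IDA, HDA and
    IPI; ``none`` returns the input unchanged.
    """
    if mode == "none":
        return annotation
    if annotation.evidence is None:
        raise ValueError(f"evidence mode {mode!r} requires evidence codes in the annotation")
    if mode == "default_exclusions":
        keep = lambda codes: bool(codes - DEFAULT_EXCLUDED_EVIDENCE)  # noqa: E731
    elif mode == "direct_assay_only":
        keep = lambda codes: bool(codes & DIRECT_ASSAY_EVIDENCE)  # noqa: E731
    else:
        raise ValueError(f"unknown evidence mode {mode!r}")
    terms: dict[str, set[str]] = {}
    ev: dict[tuple[str, str], set[str]] = {}
    for (gene, term), codes in annotation.evidence.items():
        if keep(codes):
            terms.setdefault(term, set()).add(gene)
            ev[(gene, term)] = set(codes)
    onto = {t: annotation.ontology[t] for t in terms}
    desc = {t: d for t, d in annotation.description.items() if t in terms}
    return GOAnnotationSet(terms=terms, ontology=onto, description=desc, evidence=ev)


def enrich(
    responsive: set[str],
    annotation: GOAnnotationSet,
    padj_cut: float = 0.01,
    fe_cut: float = 2.0,
    max_term_size: int = 200,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``responsive`` per GO term.

    Terms of size >= ``max_term_size`` are excluded before testing; the BH
    family is the set of tested terms (k >= 1) within each ontology class,
    with the class background N = genes in all terms of the class.  A term
    passes when adjusted P < ``padj_cut`` and FE > ``fe_cut``.
    """
    results: list[EnrichmentResult] = []
    if not responsive:
        return results
    for cls_ in annotation.classes():
        background = annotation.class_background(cls_)
        N = len(background)
        n = len(responsive & background)
        if n == 0:
            continue
        class_terms = [
            t
            for t in sorted(annotation.terms)
            if annotation.ontology[t] == cls_ and annotation.term_size(t) < max_term_size
        ]
        tested = []
        for t in class_terms:
            genes = annotation.terms[t]
            k = len(responsive & genes)
            if k == 0:
                continue  # undefined enrichment, saves multiplicity
            K = len(genes)
            p = hypergeom_tail(k, n, K, N)
            fe = (k / n) / (K / N)
            tested.append((t, cls_, k, n, K, N, fe, p))
        if not tested:
            continue
        adj = bh_adjust([row[-1] for row in tested]).adjusted
        for row, p_adj in zip(tested, adj):
            t, c, k, n_, K, N_, fe, p = row
            results.append(
                EnrichmentResult(
                    term_id=t,
                    ontology_class=c,
                    k=k,
                    n=n_,
                    K=K,
                    N=N_,
                    fold_enrichment=fe,
                    p_raw=p,
                    p_adj=p_adj,
                    passes=bool(p_adj < padj_cut and fe > fe_cut),
                )
            )
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def classify_effects(
    responsive: set[str],
    enrichment: list[EnrichmentResult],
    annotation: GOAnnotationSet,
) -> EffectClassification:
    """Label each responsive gene clustered (in >= 1 passing term) or distributed."""
    passing = [r.term_id for r in enrichment if r.passes]
    labels: dict[str, str] = {}
    support: dict[str, list[str]] = {}
    for g in responsive:
        terms = [t for t in passing if g in annotation.terms[t]]
        if terms:
            labels[g] = "clustered"
            support[g] = sorted(terms)
        else:
            labels[g] = "distributed"
            support[g] = []
    return EffectClassification(labels=labels, supporting_terms=support)
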