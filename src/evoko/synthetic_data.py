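"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study conditions of a yeast gene-deletion
expression experiment: negative-binomial RNA-seq counts for wild-type and
deletion lines across strains/species, a flat GO universe in which
"native" responders concentrate in a few related terms while "spurious"
responders scatter uniformly, a 24-segregant tetrad-structured cross with
a controllable locus-attributable variance fraction per gene, and normally
distributed cell-morphology traits with planted mean shifts.

Defaults mirror the study's scale: a 5146-gene background, 65 native +
130 spurious responders (the 195-responsive-gene split), six 2:2-balanced
tetrads (24 segregants), 405 morphology traits, ~6.5 million mapped reads
per sample, and 3-6 replicate clones per line (default 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .go_classify import GOAnnotationSet
from .heritability import SegregantPopulation
from .morphology import TraitTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_go_universe",
    "generate_truth",
    "simulate_counts",
    "simulate_segregants",
    "simulate_morphology",
]


@dataclass
class SimulationConfig:
    """One bundle of generator knobs; a fixed seed reproduces outputs exactly."""

    n_genes: int = 5146
    n_terms: int = 300
    term_size_range: tuple[int, int] = (10, 120)
    large_term_fraction: float = 0.05  # terms pushed past the 200-gene filter
    n_native: int = 65
    n_spurious: int = 130
    n_focus_terms: int = 5
    lfc_magnitude: float = 2.0
    replicates_per_line: int = 4
    nb_dispersion: float = 0.05
    library_size: float = 6.5e6
    n_tetrads: int = 6
    segregant_noise_sd: float = 1.0
    morphology_n_traits: int = 405
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_terms",
            "n_native",
            "n_spurious",
            "n_focus_terms",
            "replicates_per_line",
            "n_tetrads",
            "morphology_n_traits",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.segregant_noise_sd < 0:
            raise ValueError("segregant_noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Planted truth for one focal deletion line.

    ``native_genes`` are responders drawn from the union of a few related
    focus terms (evolutionarily selected effects); ``spurious_genes``
    scatter uniformly over the remaining background.  ``planted_lfc`` is
    the signed log2 fold change per responder, ``planted_h2`` the
    locus-attributable variance fraction per gene in the segregant cross,
    and ``conserved_flags[(species, gene)]`` says whether a planted effect
    is retained in that species' deletion line.
    """

    native_genes: set[str]
    spurious_genes: set[str]
    planted_lfc: dict[str, float]
    planted_h2: dict[str, float] = field(default_factory=dict)
    conserved_flags: dict[tuple[str, str], bool] = field(default_factory=dict)
    focus_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.native_genes & self.spurious_genes:
            raise ValueError("native and spurious gene sets must be disjoint")
        bad = [g for g, h in self.planted_h2.items() if not 0.0 <= h <= 1.0]
        if bad:
            raise ValueError(f"planted_h2 outside [0, 1] for {bad[:3]}")

    @property
    def responsive(self) -> set[str]:
        return self.native_genes | self.spurious_genes


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_go_universe(
    n_genes: int = 5146,
    n_terms: int = 300,
    term_size_range: tuple[int, int] = (10, 120),
    large_term_fraction: float = 0.05,
    seed: int = 0,
) -> GOAnnotationSet:
    """A flat single-class GO universe over ``n_genes`` genes.

    Term sizes are uniform over ``term_size_range``; a
    ``large_term_fraction`` of terms get sizes in [200, 400] to exercise
    the term-size filter.  Every gene ends up annotated to at least one
    term.  Annotation is flat (no DAG propagation).
    """
    lo, hi = term_size_range
    if not (0 < lo <= hi < n_genes):
        raise ValueError(f"infeasible term sizes {term_size_range} for {n_genes} genes")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_ids(n_genes))
    terms: dict[str, set[str]] = {}
    onto: dict[str, str] = {}
    n_large = int(round(large_term_fraction * n_terms))
    for i in range(n_terms):
        tid = f"GO:{i:07d}"
        if i < n_large and n_genes > 400:
            size = int(rng.integers(200, 401))
        else:
            size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        terms[tid] = set(members.tolist())
        onto[tid] = "BP"
    annotated = set().union(*terms.values())
    orphans = [g for g in genes if g not in annotated]
    if orphans:
        small_terms = sorted(t for t in terms if len(terms[t]) < 200)
        homes = rng.choice(np.array(small_terms), size=len(orphans), replace=True)
        for g, t in zip(orphans, homes):
            terms[t].add(g)
    return GOAnnotationSet(terms=terms, ontology=onto)


def generate_truth(
    universe: GOAnnotationSet,
    n_native: int = 65,
    n_spurious: int = 130,
    n_focus_terms: int = 5,
    lfc_magnitude: float = 2.0,
    h2_native: tuple[float, float] = (0.2, 0.8),
    h2_spurious: tuple[float, float] = (0.0, 0.1),
    retention: dict[str, float] | None = None,
    species: tuple[str, ...] = ("target_species",),
    seed: int = 0,
) -> GroundTruth:
    """Plant native responders inside ``n_focus_terms`` related small terms
    and spurious responders uniformly over the remaining background.

    Heritability is drawn uniformly from ``h2_native`` / ``h2_spurious``
    per gene; conservation in each of ``species`` is Bernoulli with
    class-specific retention probabilities (default 0.3 native,
    0.05 spurious, echoing the asymmetry the pipeline is meant to detect).
    """
    rng = np.random.default_rng(seed)
    retention = retention or {"native": 0.3, "spurious": 0.05}
    small = [t for t in sorted(universe.terms) if universe.term_size(t) < 200]
    rng.shuffle(small)
    focus: list[str] = []
    pool: set[str] = set()
    for t in small:
        focus.append(t)
        pool |= universe.terms[t]
        if len(focus) >= n_focus_terms and len(pool) >= n_native:
            break
    if len(pool) < n_native:
        raise ValueError("focus terms cannot jointly hold the requested native genes")
    focus = focus[:max(n_focus_terms, len(focus))]

    native = set(rng.choice(sorted(pool), size=n_native, replace=False).tolist())
    background = sorted(universe.class_background("BP") - pool)
    if len(background) < n_spurious:
        raise ValueError("background too small for the requested spurious genes")
    spurious = set(rng.choice(background, size=n_spurious, replace=False).tolist())

    lfc: dict[str, float] = {}
    h2: dict[str, float] = {}
    flags: dict[tuple[str, str], bool] = {}
    for g in sorted(native | spurious):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc[g] = sign * lfc_magnitude
        cls = "native" if g in native else "spurious"
        lo_h, hi_h = h2_native if cls == "native" else h2_spurious
        h2[g] = float(rng.uniform(lo_h, hi_h))
        for sp in species:
            flags[(sp, g)] = bool(rng.random() < retention[cls])
    return GroundTruth(
        native_genes=native,
        spurious_genes=spurious,
        planted_lfc=lfc,
        planted_h2=h2,
        conserved_flags=flags,
        focus_terms=focus,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # numpy's NB is (n, p) with var = mu + mu^2/n, so n = 1/dispersion.
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(n, p)
    return np.where(mean <= 0, 0, out)


def simulate_counts(
    truth: GroundTruth,
    genes: list[str],
    deleted_gene: str | None = None,
    species: str | None = None,
    replicates: int = 4,
    nb_dispersion: float = 0.05,
    library_size: float = 6.5e6,
    strain: str = "reference",
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix]:
    """Wild-type and deletion-line count matrices for one strain.

    Gene baseline means are log-normal and scaled so the expected library
    equals ``library_size``; the deletion line shifts planted responders by
    2**planted_lfc (only retained effects when ``species`` is a non-reference
    species per the truth's conservation flags) and zeroes the deleted
    gene's own counts.
    """
    if replicates < 3:
        raise ValueError("need at least 3 replicate clones per line")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng(seed)
    n = len(genes)
    lengths = rng.integers(500, 3001, size=n).astype(float)
    base = rng.lognormal(mean=np.log(200.0), sigma=1.2, size=n)
    base *= library_size / base.sum()

    mut_mean = base.copy()
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, lfc in truth.planted_lfc.items():
        if g not in gene_index:
            continue
        if species is not None and not truth.conserved_flags.get((species, g), False):
            continue
        mut_mean[gene_index[g]] = base[gene_index[g]] * 2.0**lfc
    if deleted_gene is not None and deleted_gene in gene_index:
        mut_mean[gene_index[deleted_gene]] = 0.0

    def _matrix(mean: np.ndarray, genotype: str) -> CountMatrix:
        cols = [f"{strain}_{genotype}_r{i+1}" for i in range(replicates)]
        counts = np.column_stack([_nb_draw(rng, mean, nb_dispersion) for _ in cols])
        meta = pd.DataFrame(
            {
                "sample": cols,
                "strain": strain,
                "genotype": genotype,
                "replicate": np.arange(1, replicates + 1),
            }
        )
        return CountMatrix(
            genes=list(genes), samples=cols, counts=counts, gene_lengths=lengths, metadata=meta
        )

    return _matrix(base, "wild_type"), _matrix(mut_mean, "deletion")


def simulate_segregants(
    truth: GroundTruth,
    n_tetrads: int = 6,
    noise_sd: float = 1.0,
    genes: list[str] | None = None,
    seed: int = 0,
) -> SegregantPopulation:
    """A tetrad-structured segregant population on the log2(RPKM) scale.

    Each tetrad contributes 2 wild-type-allele and 2 null-allele spores
    (the 2:2 balance of selected tetrads).  Per gene, the allele effect is
    scaled so the expected locus-attributable variance fraction equals the
    planted h2 given residual noise of ``noise_sd``.
    """
    if n_tetrads < 1:
        raise ValueError("need at least one tetrad")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = sorted(truth.responsive)
    n_seg = 4 * n_tetrads
    genotype = np.empty(n_seg, dtype=int)
    tetrad = np.empty(n_seg, dtype=int)
    for t in range(n_tetrads):
        sl = slice(4 * t, 4 * t + 4)
        tetrad[sl] = t
        perm = rng.permutation([1, 1, 0, 0])
        genotype[sl] = perm

    expr = np.empty((len(genes), n_seg))
    centered = genotype - 0.5  # +/- 0.5 coding: between-group variance = delta^2/4
    for i, g in enumerate(genes):
        h2 = float(np.clip(truth.planted_h2.get(g, 0.0), 0.0, 1.0))
        if noise_sd == 0:
            delta = 1.0 if h2 > 0 else 0.0
        else:
            h2c = min(h2, 1.0 - 1e-12)
            delta = 2.0 * noise_sd * np.sqrt(h2c / (1.0 - h2c))
        grand = rng.normal(5.0, 1.0)
        expr[i] = grand + delta * centered + rng.normal(0.0, noise_sd, size=n_seg)
    df = pd.DataFrame(expr, index=genes, columns=[f"seg_{j:02d}" for j in range(n_seg)])
    return SegregantPopulation(expression=df, genotype=genotype, tetrad=tetrad)


def simulate_morphology(
    affected: dict[str, dict[str, float]],
    n_traits: int = 405,
    shift_pct: float = 0.10,
    noise_cv: float = 0.05,
    replicates: int = 18,
    seed: int = 0,
) -> dict[str, TraitTable]:
    """Per-line trait-by-replicate tables with planted relative mean shifts.

    ``affected`` maps line id to {trait id: shift sign}; affected traits in
    a line move by ``shift_pct`` of the wild-type mean in the given
    direction.  Also returns a ``wild_type`` table.  Replicate values are
    normal with coefficient of variation ``noise_cv``; the study measured
    13-23 high-quality replicates per line (default 18).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    traits = [f"T{i:03d}" for i in range(n_traits)]
    base = rng.lognormal(mean=np.log(50.0), sigma=0.8, size=n_traits)

    def _table(line: str, shifts: dict[str, float], genotype: str) -> TraitTable:
        means = base.copy()
        for t, sgn in shifts.items():
            i = traits.index(t)
            means[i] = base[i] * (1.0 + np.sign(sgn) * shift_pct)
        vals = rng.normal(means[:, None], noise_cv * np.abs(means[:, None]), size=(n_traits, replicates))
        df = pd.DataFrame(vals, index=traits, columns=[f"rep_{j+1}" for j in range(replicates)])
        return TraitTable(values=df, line=line, genotype=genotype)

    out = {"wild_type": _table("wild_type", {}, "wild_type")}
    for line, shifts in affected.items():
        out[line] = _table(line, shifts, "deletion")
    return out
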