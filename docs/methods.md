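# Methods

`evoko` implements a pipeline for separating the transcriptional (and
morphological) consequences of a gene deletion into two classes with
different evolutionary standing:

* **clustered effects** — responsive genes that fall inside at least one
  GO term significantly enriched among the responsive set; these are
  interpreted as evolutionarily selected consequences of losing the
  gene's native function;
* **distributed effects** — responsive genes outside every enriched
  term, scattered over unrelated processes; interpreted as ad hoc,
  largely non-heritable responses of the perturbed system.

The pipeline then asks whether the two classes differ in the signatures
selection should leave: single-locus heritability in a segregant
population, conservation across strains and species, and overlap across
deletion lines of the same protein complex.

## Responsive-gene calling

Counts are normalized with DESeq-style median-of-ratios size factors.
The per-gene test is a negative-binomial Wald test: gene-wise dispersion
is estimated by the method of moments from pooled within-condition
variances (var = μ + αμ²), shrunk toward a fitted a₀ + a₁/μ
mean-dispersion trend with 10 pseudo-degrees of freedom; the Wald
statistic uses the delta-method variance of the log mean,
Var(log μ̂) = (1/μ + α)/n per condition. Genes with total normalized
count below 10 are reported untested; BH adjustment runs over the tested
family. A gene is responsive when adjusted P < 0.05 and fold change
exceeds 1.5 on the ratio scale (|log₂FC| > log₂ 1.5 ≈ 0.585). The nine
uracil-biosynthesis genes are excluded by default because the deletion
cassette, not the focal gene, drives their response; the list is
configurable. Genes with a zero condition mean (the deleted gene itself)
get a 0.5 pseudocount for the reported log₂FC and are flagged rather
than dropped. Raw (unshrunken) fold changes are thresholded.
Externally computed effect tables can be ingested instead; compendium
tables use raw P < 0.05 and |FC| > 1.2, escalating to P < 0.01 when more
than 1500 genes pass the lenient cutoff.

The Wald test is intentionally transparent rather than a DESeq2
re-implementation (no GLM dispersion fitting, no apeglm shrinkage, no
Cook's filtering); nothing downstream depends on matching DESeq2 gene
lists.

## GO enrichment and effect classification

Enrichment is the hypergeometric upper tail, computed per ontology class
(BP/MF/CC) with background N = all genes annotated in the class and
fold enrichment FE = (k/n)/(K/N). Terms of 200 or more genes are
excluded before testing (specificity), terms with no responsive gene are
not tested (undefined enrichment, saves multiplicity), and BH runs
within each class. A term passes at adjusted P < 0.01 and FE > 2.
A responsive gene is *clustered* iff it belongs to at least one passing
term — the membership rule is our operationalization; published counts
do not pin the rule, and a gene in passing terms of several classes
counts once. Annotations are used flat, exactly as supplied (no DAG
up-propagation); evidence-code filtering offers the default exclusion
list (IBA, IC, IEA, IKR, IRD, ISA, ISM, ISO, ISS, NAS, ND, TAS) and a
strict direct-assay mode (IDA, HDA, IPI only).

## Single-locus heritability

For each expression trait y (log₂RPKM over N = 24 segregants from six
2:2-balanced tetrads) the model is

    y = μ1_N + u + e,   V = Aσ²_u + Iσ²_e,   h² = σ²_u/(σ²_u + σ²_e)

with A the same-allele indicator relatedness matrix at the focal locus
(A_ij = 1 iff i and j carry the same allele). The indicator convention
(rather than a centered-and-scaled marker kinship) is deliberate: on a
balanced design it makes the REML fit identical to the one-way
random-effects ANOVA estimator σ̂²_u = max(0, (MSB − MSW)/m), which the
test suite uses as an independent closed-form oracle (agreement to
relative error 1e-13 in practice).

REML works in the eigenbasis of A, profiles out σ²_e, and locates the
stationary point of the restricted likelihood by Brent root-finding on
the analytic score in λ = σ²_u/σ²_e (search bound λ ≤ 1e12); a
non-negative score at λ = 0 is the boundary solution h² = 0, and
constant traits return h² = 0 with a zero-variance flag. Estimates are
invariant to shifting y and to positive rescaling.

Significance of h² is not a likelihood-ratio test on σ²_u: it is the
two-group allele-difference test (Welch's t on log₂RPKM between the 12
wild-type-allele and 12 null-allele segregants), BH-adjusted over
exactly the tested gene family, because that is the study's procedure.
Tetrad labels are carried in the data model but not modeled as a random
effect.

Small-sample behaviour, measured by simulation at n = 24: with one
degree of freedom between groups the h² ratio estimate is noisy and
biased upward at intermediate values (mean ĥ² ≈ 0.74 at planted 0.6;
≈ 0.04 at planted 0), while the allele-difference test has essentially
full power at planted h² = 0.8. Interpret individual ĥ² values with
caution; class-level contrasts (Mann-Whitney U between clustered and
distributed ĥ² vectors) are the intended use.

## Conservation calling

An effect defined in the reference line is conserved in a target
strain/species when the same gene (optionally through a user-supplied
ortholog map; no sequence-based inference) is significant there under
the same cutoffs *and* changes in the same direction — sign of log₂FC
only, magnitudes are not compared. Rates are anchored on the
reference-significant set; binomial SE accompanies each rate. An
optional low-expression filter drops lowly expressed reference genes
from the denominator without flipping any individual call. The class
contrast is a 2×2 chi-square with Yates continuity correction (the
correction term clamped at |O − E|).

## Overlap resampling test

For a gene group (complex/pathway) the observed statistic is the number
of genes present with the same direction in every member line's
clustered set. The null equalizes set sizes per the three cases: (i) if
clustered < distributed in all lines (the common case), pseudo-clustered
sets are subsampled without replacement from each line's distributed
pool at the clustered size; (ii) if clustered > distributed in all
lines, the larger (clustered) side is subsampled to the distributed
size — the published description repeats "distributed" here, which
cannot equalize counts, so we subsample the side that can; (iii) mixed
cases sample consistently from the distributed side, with replacement
only where a pool is too small. 1000 resamplings give the empirical 99%
interval, taken as the enclosing order statistics at the 0.5th/99.5th
percentiles because counts are discrete (interpolated quantiles can
exclude boundary mass). Significance = observed outside the interval;
fold = observed/null mean. Direction matching is enforced in both the
observed and resampled overlaps.

Known limitation: the null is conditional on each line's realized
distributed pool and is underdispersed relative to the marginal
distribution of the observed count when member lines are few or effect
sets cover a large fraction of the background. In simulations with
exchangeable clustered/distributed labels the false-flag rate at the
99% interval is ~0% for a 4-line group over a ~2000-gene background
(30/60 effects per line, the regime the test is used in) but rises to
several percent for 2-line groups or very dense backgrounds. Results
for small groups should be read accordingly.

Compendium preprocessing: genes significant in ≥ 12% of deletion lines,
capped at the top 10% most frequently responsive (ties broken by gene
id), are excluded as ubiquitous responders; only lines with ≥ 20
clustered effects enter group analyses.

## Morphology

Trait-by-replicate tables (405 traits by default; 13–23 replicates per
line in the source protocol, 18 by default in the generator) are
compared by Welch's t-test per trait — replicate counts differ between
lines, so the unequal-variance form is the safe default — with BH over
all traits. Because large replicate numbers make negligible differences
significant, a trait is *affected* only when adjusted P < 0.05 and the
relative difference exceeds 5% of the wild-type mean (trait units are
heterogeneous, so the threshold is relative, denominated by the
wild-type mean; zero-mean traits are skipped with a flag). The
conserved-vs-shared contrast is a one-tailed (greater) Fisher's exact
test on [conserved vs non-conserved] × [shared with all lines vs not].

## Synthetic data generator

The generator produces every input with planted truth, at the study's
scale by default: a 5146-gene background annotated to 300 flat
single-class GO terms (sizes 10–120, with 5% of terms pushed to 200–400
genes to exercise the size filter), 65 native responders drawn from the
union of ≤ 5 related small terms and 130 spurious responders uniform
over the remaining background (the 195 = 65 + 130 split), planted
|log₂FC| = 2 with random sign, negative-binomial counts (gene means
log-normal, single dispersion 0.05, ~6.5 million reads per sample, 4
replicate clones per line within the 3–6 used in practice), the deleted
gene zeroed in its own line, six 2:2-balanced tetrads (24 segregants)
with per-gene allele effects scaled to the planted h² on the log₂RPKM
scale (segregant expression is simulated directly on that scale, since
the heritability model operates there), Bernoulli retention of effects
in a second species (0.3 native vs 0.05 spurious by default, mirroring
the qualitative conservation asymmetry), and normal morphology
replicates with planted relative shifts.

What it does **not** emulate: a realistic GO DAG (annotations are flat
and independent), correlated expression programs, batch effects,
library-preparation biases, linkage beyond the single focal locus, and
any quantitative model of how spurious responses arise (uniform
background sampling is an assumption, flagged as such). Passing tests
therefore show the pipeline's statistics behave as designed under a
clean generative model, not that the biological classification is
correct on real data.

## Numerical choices and problem sizes

* Fisher two-sided uses the "probability ≤ observed" tie convention;
  degenerate margins return P = 1.
* Mann-Whitney switches from exact enumeration to the tie-corrected
  normal approximation above 8 observations per group.
* BH output is clamped to be ≥ the raw P (guards a one-ulp float
  rounding) and preserves input order.
* All randomness funnels through `numpy.random.default_rng` seeds; the
  pipeline derives per-stage streams from one root `SeedSequence`, so
  outputs are byte-identical under a fixed config.
* Test and acceptance problem sizes — 100 traits for the REML/ANOVA
  oracle, 500 traits for h² recovery, 100 four-line groups × 1000
  resamplings for calibration, 10 seeds at the 5146-gene scale for
  classification recovery — were chosen to keep the full suite under a
  minute while leaving Monte-Carlo error well inside the asserted bands.
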