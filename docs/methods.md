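# Methods

## The model

`phenocover` scores candidate drug targets by asking how much of a drug's
side-effect profile is *explained* by the phenotypes of a single-gene
loss-of-function mouse model. Both entities are described as sets of terms
from a phenotype ontology (Mammalian Phenotype terms, optionally merged with
Human Phenotype terms through cross-namespace `is_a` links materialized by an
upstream cross-species integration — that merged ontology is an input, not
something this package computes).

Three steps define the score between a drug profile D and a gene profile M:

1. **Annotation closure.** Every profile is augmented with all ontological
   ancestors of its terms (reflexive `is_a` closure). This is the true-path
   convention all group-wise semantic similarity assumes: an entity annotated
   with a specific phenotype is implicitly annotated with every
   generalization of it.

2. **Information content.** For each term t,

       IC(t) = −log2 p(t),

   where p(t) is the fraction of annotated entities — drugs and genes
   jointly — whose *closed* profile contains t. Terms shared by every entity
   (the root, after closure) carry IC = 0; rare specific phenotypes carry
   high IC. Closure guarantees p is antitone along subsumption, so IC is
   monotone: a parent is never more informative than its child. The base of
   the logarithm rescales every IC by the same constant and cancels in all
   similarity ratios; base 2 is used so values read in bits. No smoothing is
   applied: a term never annotated in the corpus has no defined IC, and
   querying one raises rather than silently contributing zero.

3. **Coverage similarity.**

       sim(D, M) = Σ_{t ∈ D∩M} IC(t) / Σ_{t ∈ D} IC(t)

   the fraction of the drug profile's information content covered by the
   model's phenotypes. It is deliberately **non-symmetric**: phenotypes of M
   absent from D are not penalized. A drug perturbs many proteins while a
   knockout removes exactly one, so a true target is expected to explain
   only part of the drug's effects, and the unexplained part carries no
   evidence against the pairing. Two symmetric baselines are provided for
   comparison: SimGIC (IC of the intersection over IC of the union — the
   measure coverage derives from) and the unweighted Jaccard index.

Similarity is computed over one namespace (default `MP:`) after closure over
the merged ontology: a drug annotated with a human phenotype term still
contributes the mouse-namespace ancestors that the merged ontology assigns
to it. The restriction is applied after closure and before IC estimation;
both the restriction and the joint (drugs ∪ genes) IC corpus are switchable
(`namespace_prefix=None`, `ic_corpus="genes"`) for sensitivity analysis.

Degenerate inputs: a drug whose restricted closed profile is empty, or whose
terms all have zero IC (e.g. a profile reduced to the root), carries no
usable information and is excluded from the matrix with a logged count; the
scalar `coverage_similarity` raises `UndefinedScoreError` on such input.
The matrix stage orders rows and columns by sorted identifier, so outputs
are deterministic for fixed inputs.

## Profiles and evaluation data

Gene profiles are the union of phenotype annotations over all single-gene
loss-of-function models of a gene; models flagged as multi-gene contribute
nothing. Drug profiles come from side-effect tables keyed by UMLS concept
IDs, mapped into the ontology by a layered mapping table: exact lexical
matching of concept labels against term names and synonyms (normalization:
case-fold, trim, collapse internal whitespace — nothing more aggressive,
since the match is meant to be exact), ontology cross-references, and
manually curated maps, merged with provenance priority curated > xref >
lexical. Concepts may map to several terms; all mappings are kept.

Evaluation sets are drug–protein interaction tables filtered to mode of
action `inhibition` at an inclusive confidence cutoff (≥); the package
defaults evaluate at 0.0, 0.5 and 0.7. Human targets are translated to
mouse genes through an orthology table, keeping one positive pair per
ortholog (paralog fan-out is retained; no canonical-ortholog tie rule is
imposed). Pairs whose drug or gene is not scorable are excluded from
evaluation (intersection semantics) — an ROC over unscorable pairs is
undefined.

## ROC analysis

Evaluation pools every scored (drug, gene) cell of the similarity matrix:
cells in the evaluation set are positives, all other scored cells negatives
(unlabeled-as-negative; no negative sampling). The curve is a descending
threshold sweep with tied scores processed as one block, making the
trapezoid-rule AUC equal to the Mann–Whitney U statistic with ties counted
1/2 (asserted against an independent pair-counting oracle in the tests). A
per-drug macro-averaged mode is intentionally absent from the default path;
pooling is the primary analysis.

Confidence intervals use a normal approximation with the distribution-free
maximum-variance bound σ² = AUC(1−AUC)/min(m, n), m and n the positive and
negative counts, and half-width z·σ with z = 1.96 at the default 95% level.
A Hanley–McNeil variance is available behind the same `variance_formula`
switch. The bound is conservative (widest interval consistent with the
counts); intervals are clipped to [0, 1] and degenerate to a point at AUC 0
or 1.

Stratified analysis restricts the candidate space per group: protein-family
reports restrict the gene columns to family members (every drug kept), drug
category reports restrict the drug rows (every gene kept) — families group
*targets*, categories group *drugs*. A group is reported only if it
contains strictly more than `min_positives` (default 5) positive pairs in
its restricted matrix; an analysis where no group qualifies returns an
explicit empty report rather than raising.

## The synthetic benchmark

The generator builds a self-contained corpus with the statistical structure
the method assumes, so every stage is testable without external downloads.

* **Ontology**: a single-rooted random DAG of `n_terms` (default 500) terms
  in the `MP:` namespace; each non-root term draws 1 + Poisson(mean_parents
  − 1) parents (default mean 1.8) from earlier terms, acyclic by
  construction.
* **Gene profiles** (default 200 genes): direct annotations sampled with a
  leaf bias — probability ∝ 1/(1 + number of descendants) — so profiles
  look like specific phenotype calls rather than abstract ones (annotations
  concentrated near the root would collapse the IC structure). Sizes are
  Poisson with mean 8, chosen as the order of magnitude of typical per-gene
  curated phenotype annotation counts; a lognormal multiplier
  (`gene_size_dispersion`) produces the heavy-tailed size spectrum of real
  corpora when enabled.
* **Drug profiles** (default 100 drugs): each drug draws 1–3 target genes,
  copies each target's *direct* terms independently with probability
  `coverage_fraction` (default 0.5), unions them, and adds
  Poisson(`noise_terms_mean`, default 3) unrelated terms. Closure is left
  to the pipeline, so both profile kinds exercise it. The planted (drug,
  target) pairs form the evaluation table with action `inhibition`.
* **Variants**: `hub_gene` adds one gene annotated with
  ⌈`hub_coverage`·n_terms⌉ terms and never planted as a target;
  `hp_fraction` swaps a fraction of drug terms for fresh `HP:`-namespace
  children of the original term (exercising cross-namespace closure and
  restriction); `random_confidence` draws uniform confidences for the
  planted pairs so cutoff filtering is testable.

Identical configuration and seed give byte-identical output files.

### What the generator does and does not emulate

It reproduces the *relational* structure — subsumption DAG, true-path
closure, drugs as noisy multi-target mixtures, inhibition-only positives —
but not the quantitative topology of the real Mammalian Phenotype ontology,
real side-effect frequency spectra, or interaction-confidence
distributions. Passing benchmarks therefore demonstrate correctness and the
qualitative behavior of the measures, not the AUC levels attainable on any
real corpus.

### The multi-target regime

`GeneratorConfig.multi_target()` names the regime in which the asymmetric
measure outperforms the symmetric baselines, and the choice deserves its own
account. Under the *default* bundle (homogeneous Poisson profile sizes,
uniformly chosen targets) SimGIC slightly outperforms coverage: its penalty
on the candidate gene's profile size is a correct regularization whenever
chance intersections scale with profile size. The symmetric measures
collapse — as observed on real corpora — only when three features co-occur,
all documented properties of real annotation data:

1. knockout profiles are much larger than drug profiles and heavy-tailed in
   size (well-studied genes carry hundreds of phenotype annotations);
2. a drug's effects cover only a small fraction of any one target's
   phenotypes, because the drug distributes its effects over several
   targets (here: 2–5 targets, 15% of each target's direct terms);
3. known positives concentrate among richly annotated genes — established
   drug targets are heavily studied, so exactly the genes a symmetric
   measure penalizes for their many unmatched phenotypes are the true ones.

The configuration freezes these as mean profile size 40 with lognormal
dispersion 1.2, `targets_per_drug_range=(2, 5)`, `coverage_fraction=0.15`,
and target sampling weight ∝ (profile size)² (`target_annotation_bias=2`).
Under it, coverage strictly exceeds SimGIC and Jaccard on every tested seed,
reproducing the direction of effect the measure was designed for; the same
mechanism produces the measure's known failure mode, checked separately:
a hub gene annotated with half of all terms floats into the top-5 ranking
of nearly every drug without ever being a true target.

## Problem sizes and numerics

Benchmarks run at 500 terms × 200 genes × 100 drugs (20 000 scored pairs
per bundle), with 5 seeds for recovery and comparison analyses and 10 for
the null calibration — sizes chosen so the full suite and the reproduction
script each complete in seconds while keeping the sampling error of the
reported means near ±0.01 AUC. Matrices are computed densely via boolean
term-incidence matrices and one matrix product per measure; scores are
clipped to [0, 1] against floating-point drift and asserted against exact
set-arithmetic recomputation to 1e-12 in the tests. Ranking breaks ties by
mean rank with a deterministic secondary sort on gene ID.

## Known limitations

* The IC corpus and the similarity must use the same ontology and closure;
  profiles closed elsewhere raise on unknown terms rather than guessing.
* The maximum-variance CI is conservative; it does not model score
  correlation between pairs sharing a drug or gene.
* Pooled ROC mixes within-drug and between-drug discrimination; the
  coverage measure's cross-drug calibration (normalizing by the drug's own
  IC) is part of what the multi-target benchmark measures, and per-drug
  macro-averaging would tell a different story.
* The lexical mapper is exact-match by design; it will not recover
  morphological variants ("nauseous" vs "nausea").
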