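# phenocover

Prioritize candidate drug targets from mouse knockout phenotypes.

Loss-of-function mouse models and drug treatments can perturb the same
protein, and when they do, the knockout's phenotypes and the drug's
side-effect profile tend to overlap. `phenocover` makes that idea
computable: it represents each drug and each single-gene knockout as a set
of phenotype ontology terms, and scores how much of the drug's effect
*information* the knockout explains. High-scoring genes are candidate
inhibition targets of the drug — useful for target identification and drug
repurposing, where animal-model phenotypes are an independent,
experiment-derived evidence source.

## The measure

Profiles are closed under ontological subsumption (every term implies its
ancestors). Each term t gets an information content from corpus annotation
frequency,

    IC(t) = −log₂ p(t),     p(t) = fraction of entities annotated with t,

and a drug profile D is scored against a gene profile M with a
**non-symmetric coverage similarity**:

    sim(D, M) = Σ_{t ∈ D∩M} IC(t) / Σ_{t ∈ D} IC(t)  ∈ [0, 1]

— the fraction of the drug's effect information covered by the knockout's
phenotypes. Knockout phenotypes absent from the drug profile are *not*
penalized: a drug usually perturbs several proteins, so one target is only
expected to explain part of its effects. Symmetric group-wise baselines
(SimGIC, Jaccard) are included for comparison, and the evaluation module
ranks genes per drug, builds pooled ROC curves against known
inhibition-target sets, attaches maximum-variance normal-approximation
confidence intervals to each AUC, and stratifies by protein family or drug
category. A synthetic-benchmark generator (random ontology DAG, gene
profiles, drugs as noisy subsamples of planted targets' phenotypes) makes
the whole pipeline testable end to end without any external data.

See `docs/methods.md` for the full model description, parameter defaults
and design rationale.

## Worked example

Generate a synthetic corpus (500 ontology terms, 200 genes, 100 drugs with
1–3 planted inhibition targets each), score it, and evaluate:

```sh
phenocover synth --seed 1 --out demo
phenocover matrix --ontology demo/ontology.obo \
    --gene-annotations demo/gene_annotations.tsv \
    --drug-effects demo/drug_effects.tsv \
    --mapping demo/umls_mapping.tsv --out demo/matrix.tsv
phenocover evaluate --matrix demo/matrix.tsv --positives demo/evaluation.tsv
phenocover rank --matrix demo/matrix.tsv --drug Drug0000 --top 5
```

which prints:

```
100 x 200 coverage matrix written to demo/matrix.tsv
AUC = 0.8717  95% CI [0.8258, 0.9176]  (m=204 positives, n=19796 negatives)
 gene_id    score  rank
Gene0142 0.858248   1.0
Gene0078 0.709847   2.0
Gene0012 0.652481   3.0
Gene0106 0.630587   4.0
Gene0068 0.529569   5.0
```

The AUC of 0.87 says a planted target outranks a random non-target pair 87%
of the time across the pooled 100×200 matrix. For `Drug0000` the top-ranked
gene (`Gene0142`, coverage 0.86 — 86% of the drug profile's information
content is explained by that knockout's phenotypes) is indeed its planted
target, as `demo/manifest.json` records. Real analyses substitute the
synthetic files with a merged phenotype ontology (OBO), model annotation
and side-effect TSVs, UMLS mapping tables, interaction and orthology TSVs —
formats are documented in the module docstrings — and typically run through
a single YAML-driven command, `phenocover run -c config.yaml`.

The library mirrors the CLI: `parse_obo`, `close_profile`,
`build_gene_profiles` / `build_drug_profiles`, `estimate_ic`,
`build_matrix`, `roc`, `stratified_roc`, `explain` are all importable from
`phenocover`.

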