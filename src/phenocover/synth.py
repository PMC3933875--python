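"""Synthetic benchmark generator: ontology, profiles, planted targets.

Generates a self-contained bundle with the statistical structure the method
assumes, so that every pipeline stage can be exercised and the planted
drug-target signal recovered without any external downloads:

* a random single-rooted DAG ontology (``MP:`` namespace) in OBO format;
* per-gene phenotype profiles drawn with a leaf bias, mimicking specific
  phenotype annotations rather than abstract ones;
* per-drug effect profiles built as noisy subsamples of one to a few
  planted target genes' direct annotations — the drug "inherits" a fraction
  of each target's phenotypes and gains unrelated noise terms, mirroring a
  compound that perturbs several proteins;
* the planted (drug, target) pairs as an inhibition evaluation table, plus
  grouping, orthology and identity UMLS-mapping tables in the exact formats
  the corpus readers consume.

An optional "hub" gene annotated with a large fraction of all terms
reproduces the known failure mode of pure-coverage similarity: a profile
touching most ontology branches covers most of any drug's information and
floats to the top of nearly every ranking without being a real target.

Identical seed and configuration give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import (DrugProfileSet, EvaluationPair, EvaluationSet,
                     GeneProfileSet)
from .ontology import Ontology, Profile

HUB_GENE_ID = "GeneHUB"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic benchmark.

    Defaults define the standard planted-target recovery condition:
    a 500-term ontology, 200 genes with ~8 direct annotations each,
    100 drugs carrying half of each of their 1-3 targets' direct terms
    plus ~3 unrelated noise terms.
    """

    seed: int = 0
    n_terms: int = 500
    mean_parents: float = 1.8
    n_genes: int = 200
    mean_profile_size: float = 8.0
    n_drugs: int = 100
    targets_per_drug_range: tuple[int, int] = (1, 3)
    coverage_fraction: float = 0.5
    noise_terms_mean: float = 3.0
    hub_gene: bool = False
    hub_coverage: float = 0.5
    hp_fraction: float = 0.0      # fraction of drug terms swapped for HP: children
    random_confidence: bool = False
    gene_size_dispersion: float = 0.0   # lognormal sigma of gene profile sizes
    target_annotation_bias: float = 0.0  # target draw weight ∝ profile_size^bias

    def __post_init__(self) -> None:
        if not 0.0 <= self.hp_fraction <= 1.0:
            raise ValueError("hp_fraction must be in [0, 1]")
        if self.gene_size_dispersion < 0 or self.target_annotation_bias < 0:
            raise ValueError("dispersion and bias must be non-negative")

    @classmethod
    def multi_target(cls, seed: int = 0) -> "GeneratorConfig":
        """The multi-target regime in which the asymmetric measure earns its keep.

        Mirrors the structure of real annotation corpora where symmetric
        group-wise measures break down: knockout phenotype profiles are much
        larger than drug effect profiles and heavy-tailed in size
        (well-studied genes carry hundreds of annotations), each drug's
        effects cover only a small fraction of any one target's phenotypes
        because the drug perturbs several proteins, and known drug targets
        are concentrated among richly annotated genes. Symmetric measures
        penalize a true target's many unmatched phenotypes; the coverage
        measure, normalizing by the drug profile alone, does not.
        """
        return cls(seed=seed, mean_profile_size=40.0, gene_size_dispersion=1.2,
                   targets_per_drug_range=(2, 5), coverage_fraction=0.15,
                   noise_terms_mean=3.0, target_annotation_bias=2.0)
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if min(self.n_genes, self.n_drugs) < 1 or self.mean_profile_size <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in [0, 1]")
        if not 0.0 < self.hub_coverage <= 1.0:
            raise ValueError("hub_coverage must be in (0, 1]")
        lo, hi = self.targets_per_drug_range
        if not 1 <= lo <= hi:
            raise ValueError("targets_per_drug_range must satisfy 1 <= min <= max")


@dataclass
class SyntheticBundle:
    """In-memory view of one generated benchmark."""

    config: GeneratorConfig
    ontology: Ontology
    obo_text: str
    gene_annotations: list[tuple[str, str, str, int]]  # model, gene, term, lof
    drug_effects: list[tuple[str, str]]                # drug, umls
    umls_mapping: list[tuple[str, str]]                # umls, term
    evaluation: list[tuple[str, str, str, float]]      # drug, gene, action, conf
    gene_groups: list[tuple[str, str]]
    drug_groups: list[tuple[str, str]]
    orthology: list[tuple[str, str]]                   # human, mouse
    truth: dict[str, list[str]]                        # drug -> planted targets

    def write(self, out_dir) -> dict[str, Path]:
        """Write the bundle as the TSV/OBO files the corpus module reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ontology": out / "ontology.obo",
            "gene_annotations": out / "gene_annotations.tsv",
            "drug_effects": out / "drug_effects.tsv",
            "umls_mapping": out / "umls_mapping.tsv",
            "evaluation": out / "evaluation.tsv",
            "gene_groups": out / "gene_groups.tsv",
            "drug_groups": out / "drug_groups.tsv",
            "orthology": out / "orthology.tsv",
            "manifest": out / "manifest.json",
        }
        paths["ontology"].write_text(self.obo_text)
        _write_tsv(paths["gene_annotations"],
                   ("model_id", "gene_id", "mp_term", "single_gene_lof"),
                   self.gene_annotations)
        _write_tsv(paths["drug_effects"], ("drug_id", "umls_id"),
                   self.drug_effects)
        _write_tsv(paths["umls_mapping"], ("umls_id", "term_id", "provenance"),
                   [(u, t, "curated") for u, t in self.umls_mapping])
        _write_tsv(paths["evaluation"],
                   ("chemical_id", "protein_id", "action", "confidence"),
                   self.evaluation)
        _write_tsv(paths["gene_groups"], ("entity_id", "group"), self.gene_groups)
        _write_tsv(paths["drug_groups"], ("entity_id", "group"), self.drug_groups)
        _write_tsv(paths["orthology"], ("human_gene", "mouse_gene"),
                   self.orthology)
        manifest = {"config": dataclasses.asdict(self.config),
                    "truth": self.truth,
                    "n_terms": len(self.ontology),
                    "n_genes": len({g for _, g, _, _ in self.gene_annotations}),
                    "n_drugs": len({d for d, _ in self.drug_effects})}
        paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return paths


def _write_tsv(path: Path, header: tuple[str, ...], rows) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(x) for x in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def _term_id(i: int, prefix: str = "MP") -> str:
    return f"{prefix}:{i:07d}"


def generate_ontology(cfg: GeneratorConfig, *, rng: np.random.Generator | None = None,
                      ) -> tuple[Ontology, str]:
    """Random single-rooted DAG ontology in the ``MP:`` namespace.

    Term 0 is the root; every later term draws 1 + Poisson(mean_parents - 1)
    parents uniformly from earlier terms, so the graph is acyclic by
    construction. Returns the parsed ontology together with its OBO text.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    parents: dict[str, frozenset[str]] = {_term_id(0): frozenset()}
    labels = {_term_id(0): "phenotype root"}
    stanzas = [f"[Term]\nid: {_term_id(0)}\nname: phenotype root\n"]
    for i in range(1, cfg.n_terms):
        k = min(i, 1 + int(rng.poisson(max(cfg.mean_parents - 1.0, 0.0))))
        ps = sorted(_term_id(int(j)) for j in rng.choice(i, size=k, replace=False))
        tid = _term_id(i)
        name = f"phenotype {i:04d}"
        parents[tid] = frozenset(ps)
        labels[tid] = name
        body = "".join(f"is_a: {p} ! {labels[p]}\n" for p in ps)
        stanzas.append(f"[Term]\nid: {tid}\nname: {name}\n{body}")
    text = ("format-version: 1.2\nontology: synthetic-phenotype\n\n"
            + "\n".join(stanzas))
    return Ontology(parents=parents, labels=labels), text


def _leaf_bias_weights(ontology: Ontology, terms: list[str]) -> np.ndarray:
    """Sampling weight 1/(1 + n_descendants): specific terms are likelier,
    keeping the IC structure from collapsing toward the root."""
    n_desc = {t: 0 for t in terms}
    for t in terms:
        for a in ontology.ancestors(t):
            if a != t:
                n_desc[a] += 1
    w = np.array([1.0 / (1.0 + n_desc[t]) for t in terms])
    return w / w.sum()


def generate_bundle(cfg: GeneratorConfig) -> SyntheticBundle:
    """Generate the full benchmark bundle for one configuration and seed."""
    rng = np.random.default_rng(cfg.seed)
    ontology, obo_text = generate_ontology(cfg, rng=rng)
    terms = sorted(ontology.terms)
    weights = _leaf_bias_weights(ontology, terms)

    # Gene profiles: leaf-biased draws of direct (pre-closure) annotations.
    gene_ids = [f"Gene{i:04d}" for i in range(cfg.n_genes)]
    gene_terms: dict[str, list[str]] = {}
    annotations: list[tuple[str, str, str, int]] = []
    for g in gene_ids:
        # Poisson sizes by default; a lognormal multiplier (median
        # mean_profile_size) gives the heavy-tailed size spectrum of real
        # annotation corpora when gene_size_dispersion > 0.
        if cfg.gene_size_dispersion > 0:
            size = int(round(cfg.mean_profile_size
                             * rng.lognormal(0.0, cfg.gene_size_dispersion)))
        else:
            size = int(rng.poisson(cfg.mean_profile_size))
        size = min(max(1, size), len(terms))
        chosen = sorted(rng.choice(len(terms), size=size, replace=False, p=weights))
        gene_terms[g] = [terms[int(c)] for c in chosen]
        model = f"Model_{g}"
        annotations += [(model, g, t, 1) for t in gene_terms[g]]
    if cfg.hub_gene:
        n_hub = min(len(terms), math.ceil(cfg.hub_coverage * cfg.n_terms))
        chosen = sorted(rng.choice(len(terms), size=n_hub, replace=False))
        gene_terms[HUB_GENE_ID] = [terms[int(c)] for c in chosen]
        annotations += [(f"Model_{HUB_GENE_ID}", HUB_GENE_ID, t, 1)
                        for t in gene_terms[HUB_GENE_ID]]

    # Drug profiles: per-target Bernoulli(coverage_fraction) subsample of the
    # target's direct terms, union over targets, plus Poisson noise terms.
    # The hub gene is never a planted target.
    lo, hi = cfg.targets_per_drug_range
    drug_ids = [f"Drug{i:04d}" for i in range(cfg.n_drugs)]
    drug_terms: dict[str, list[str]] = {}
    truth: dict[str, list[str]] = {}
    if cfg.target_annotation_bias > 0:
        sizes = np.array([len(gene_terms[g]) for g in gene_ids], dtype=float)
        target_w = sizes ** cfg.target_annotation_bias
        target_w /= target_w.sum()
    else:
        target_w = None  # plain uniform draw, not weighted-choice with equal p
    for d in drug_ids:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(gene_ids))
        for _ in range(100):
            targets = sorted(rng.choice(len(gene_ids), size=k, replace=False,
                                        p=target_w))
            targets = [gene_ids[int(t)] for t in targets]
            profile: set[str] = set()
            for g in targets:
                gt = gene_terms[g]
                take = rng.random(len(gt)) < cfg.coverage_fraction
                profile |= {t for t, keep in zip(gt, take) if keep}
            n_noise = int(rng.poisson(cfg.noise_terms_mean))
            if n_noise:
                noise = rng.choice(len(terms), size=min(n_noise, len(terms)),
                                   replace=False)
                profile |= {terms[int(i)] for i in noise}
            if profile:
                break
        else:
            raise RuntimeError(
                f"could not draw a non-empty profile for {d} in 100 attempts; "
                "raise coverage_fraction or noise_terms_mean")
        drug_terms[d] = sorted(profile)
        truth[d] = targets

    # Two-namespace variant: swap a fraction of each drug's terms for fresh
    # HP: children of the original MP term (cross-namespace is_a link), so
    # that closure recovers the MP ancestor and namespace restriction is
    # exercised on realistic mixed profiles.
    if cfg.hp_fraction > 0.0:
        hp_of: dict[str, str] = {}
        extra_stanzas: list[str] = []
        new_parents = dict(ontology.parents)
        new_labels = dict(ontology.labels)
        for d in drug_ids:
            swapped = []
            for t in drug_terms[d]:
                if rng.random() < cfg.hp_fraction:
                    if t not in hp_of:
                        hp_id = _term_id(int(t.split(":")[1]), prefix="HP")
                        hp_of[t] = hp_id
                        new_parents[hp_id] = frozenset({t})
                        new_labels[hp_id] = f"human analogue of {ontology.labels[t]}"
                        extra_stanzas.append(
                            f"[Term]\nid: {hp_id}\nname: {new_labels[hp_id]}\n"
                            f"is_a: {t} ! {ontology.labels[t]}\n")
                    swapped.append(hp_of[t])
                else:
                    swapped.append(t)
            drug_terms[d] = sorted(set(swapped))
        ontology = Ontology(parents=new_parents, labels=new_labels)
        obo_text = obo_text + "\n" + "\n".join(extra_stanzas)

    # UMLS layer: one synthetic concept per used term, identity-mapped.
    used = sorted({t for ts in drug_terms.values() for t in ts})
    umls_of = {t: f"C{t[:2]}{int(t.split(':')[1]):07d}" for t in used}
    drug_effects = [(d, umls_of[t]) for d in drug_ids for t in drug_terms[d]]
    umls_mapping = [(umls_of[t], t) for t in used]

    evaluation = [
        (d, g, "inhibition",
         round(float(rng.uniform()), 4) if cfg.random_confidence else 1.0)
        for d in drug_ids for g in truth[d]]

    all_genes = sorted(gene_terms)
    n_fam = max(2, cfg.n_genes // 25)
    gene_groups = [(g, f"FAM{int(rng.integers(n_fam)):02d}") for g in all_genes]
    n_cat = max(2, cfg.n_drugs // 25)
    drug_groups = [(d, f"ATC{int(rng.integers(n_cat)):02d}") for d in drug_ids]
    orthology = [(f"H{g.upper()}", g) for g in all_genes]

    return SyntheticBundle(
        config=cfg, ontology=ontology, obo_text=obo_text,
        gene_annotations=annotations, drug_effects=drug_effects,
        umls_mapping=umls_mapping, evaluation=evaluation,
        gene_groups=gene_groups, drug_groups=drug_groups,
        orthology=orthology, truth=truth)


def bundle_profiles(bundle: SyntheticBundle
                    ) -> tuple[dict[str, Profile], dict[str, Profile]]:
    """Direct (pre-closure) drug and gene profiles of a bundle, keyed by ID.

    Convenience for in-memory pipelines that skip the TSV round-trip.
    """
    genes: dict[str, set[str]] = {}
    for _, g, t, lof in bundle.gene_annotations:
        if lof == 1:
            genes.setdefault(g, set()).add(t)
    umls_to_term = dict(bundle.umls_mapping)
    drugs: dict[str, set[str]] = {}
    for d, u in bundle.drug_effects:
        drugs.setdefault(d, set()).add(umls_to_term[u])
    return (
        {d: Profile(d, frozenset(ts)) for d, ts in sorted(drugs.items())},
        {g: Profile(g, frozenset(ts)) for g, ts in sorted(genes.items())},
    )


def bundle_profile_sets(bundle: SyntheticBundle
                        ) -> tuple[DrugProfileSet, GeneProfileSet]:
    """Bundle profiles wrapped in the corpus container types."""
    drugs, genes = bundle_profiles(bundle)
    return DrugProfileSet(profiles=drugs), GeneProfileSet(profiles=genes)


def bundle_evaluation_set(bundle: SyntheticBundle) -> EvaluationSet:
    """The planted (drug, target) pairs as an inhibition evaluation set."""
    pairs = [EvaluationPair(d, g, action, float(conf), "planted")
             for d, g, action, conf in bundle.evaluation]
    return EvaluationSet(pairs=pairs, source="planted")
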