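"""End-to-end orchestration: profiles -> IC -> matrix -> ranking -> ROC.

A run is driven by a single YAML config naming the input files and the
analysis settings, and writes every artifact (similarity matrix, per-drug
ranked candidate lists, ROC results per evaluation dataset and confidence
cutoff, stratified reports, and a machine-readable manifest with input
checksums) into one output directory. Reruns on identical inputs reproduce
identical numbers; the similarity matrix — the stage that dominates
runtime — is cached on the checksum of everything that determines it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .corpus import (EvaluationSet, MappingTable, OrthologyMap,
                     build_drug_profiles, build_evaluation_set,
                     build_gene_profiles)
from .evaluation import roc, stratified_roc
from .ontology import close_profile, parse_obo, restrict_namespace
from .similarity import (ICTable, SimilarityMatrix, build_matrix, estimate_ic,
                         explain_coverage)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one analysis run; mirrors the YAML keys."""

    ontology: str
    gene_annotations: str
    drug_effects: str
    mappings: list[str]
    interactions: dict[str, str]          # dataset label -> TSV path
    output_dir: str
    orthology: str | None = None
    orthology_datasets: list[str] = field(default_factory=list)
    gene_grouping: str | None = None
    drug_grouping: str | None = None
    measure: str = "coverage"
    namespace_prefix: str | None = "MP:"
    action_filter: str = "inhibition"
    confidence_cutoffs: list[float] = field(default_factory=lambda: [0.0, 0.5, 0.7])
    min_positives: int = 5
    ci_level: float = 0.95
    variance_formula: str = "max_variance"
    seed: int = 0                          # provenance only; the run is sampling-free

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.ontology, self.gene_annotations, self.drug_effects,
                 *self.mappings, *self.interactions.values()]
        for opt in (self.orthology, self.gene_grouping, self.drug_grouping):
            if opt:
                paths.append(opt)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        bad = [c for c in self.confidence_cutoffs if not 0.0 <= c <= 1.0]
        if bad:
            raise ValueError(f"confidence cutoffs outside [0, 1]: {bad}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Any stage failure propagates with the stage name prefixed, so a broken
    input is attributable without a debugger.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    ontology = stage("ontology")(parse_obo, config.ontology)
    genes = stage("gene_profiles")(build_gene_profiles, config.gene_annotations)
    mapping_tables = [stage("mappings")(MappingTable.read, p)
                      for p in config.mappings]
    from .corpus import merge_mappings
    mapping = merge_mappings(*mapping_tables)
    drugs = stage("drug_profiles")(build_drug_profiles, config.drug_effects,
                                   mapping, ontology)

    matrix_inputs = [config.ontology, config.gene_annotations,
                     config.drug_effects, *config.mappings]
    cache_key = hashlib.sha256(
        ("\n".join(_sha256(p) for p in matrix_inputs)
         + f"|{config.measure}|{config.namespace_prefix}").encode()).hexdigest()
    matrix_path = out / "similarity_matrix.tsv"
    cache_tag = out / "similarity_matrix.key"
    if matrix_path.exists() and cache_tag.exists() and cache_tag.read_text() == cache_key:
        logger.info("similarity matrix cache hit; reusing %s", matrix_path)
        matrix = SimilarityMatrix.read_tsv(matrix_path, measure=config.measure)
    else:
        matrix = stage("matrix")(build_matrix, drugs, genes, ontology,
                                 measure=config.measure,
                                 namespace_prefix=config.namespace_prefix)
        matrix.write_tsv(matrix_path)
        cache_tag.write_text(cache_key)

    rank_path = out / "ranked_targets.tsv"
    from .evaluation import rank_targets
    with open(rank_path, "w") as fh:
        fh.write("drug_id\tgene_id\tscore\trank\n")
        for drug in matrix.drugs:
            ranked = rank_targets(matrix, drug)
            for r in ranked.itertuples():
                fh.write(f"{drug}\t{r.gene_id}\t{r.score:.6g}\t{r.rank:g}\n")

    orthology = (OrthologyMap.read(config.orthology)
                 if config.orthology else None)
    summary_rows = []
    for label, path in sorted(config.interactions.items()):
        use_orth = orthology if label in config.orthology_datasets else None
        for cutoff in config.confidence_cutoffs:
            eval_set = stage(f"evaluation[{label}]")(
                build_evaluation_set, path, action_filter=config.action_filter,
                min_confidence=cutoff, orthology=use_orth, source=label)
            tag = f"{label}_conf{cutoff:g}"
            try:
                result = roc(matrix, eval_set, level=config.ci_level,
                             variance_formula=config.variance_formula, label=tag)
            except ValueError as exc:
                logger.warning("ROC skipped for %s: %s", tag, exc)
                continue
            result.to_points_frame().to_csv(out / f"roc_{tag}.tsv", sep="\t",
                                            index=False)
            summary_rows.append(result.summary_row())
            for kind, grouping in (("protein_family", config.gene_grouping),
                                   ("drug_category", config.drug_grouping)):
                if not grouping:
                    continue
                report = stratified_roc(
                    matrix, eval_set, grouping, kind=kind,
                    min_positives=config.min_positives, level=config.ci_level,
                    variance_formula=config.variance_formula)
                report.to_frame().to_csv(out / f"stratified_{kind}_{tag}.tsv",
                                         sep="\t", index=False)
                summary_rows += [r.summary_row() | {"label": f"{tag}/{g}"}
                                 for g, r in report.groups.items()]

    import pandas as pd
    pd.DataFrame(summary_rows).to_csv(out / "roc_summary.tsv", sep="\t",
                                      index=False)
    with open(out / "roc_summary.json", "w") as fh:
        json.dump(summary_rows, fh, indent=1)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_checksums": {p: _sha256(p) for p in matrix_inputs},
        "n_drugs_scored": len(matrix.drugs),
        "n_genes_scored": len(matrix.genes),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def explain(config_or_paths, drug: str, gene: str) -> dict:
    """Coverage breakdown for one (drug, gene) pair.

    Recomputes profiles and IC exactly as the matrix stage does, then
    returns the per-term decomposition: covered and uncovered drug-profile
    terms with their IC, and the covered-IC fraction (which equals the
    matrix cell for the same pair).
    """
    config = config_or_paths
    ontology = parse_obo(config.ontology)
    genes = build_gene_profiles(config.gene_annotations)
    from .corpus import merge_mappings
    mapping = merge_mappings(*[MappingTable.read(p) for p in config.mappings])
    drugs = build_drug_profiles(config.drug_effects, mapping, ontology)
    if drug not in drugs.profiles:
        raise KeyError(f"drug {drug!r} has no scorable profile")
    if gene not in genes.profiles:
        raise KeyError(f"gene {gene!r} has no scorable profile")

    def prepare(profile):
        closed = close_profile(profile, ontology)
        return (restrict_namespace(closed, config.namespace_prefix)
                if config.namespace_prefix else closed)

    drug_profiles = {d: prepare(p) for d, p in drugs.profiles.items()}
    gene_profiles = {g: prepare(p) for g, p in genes.profiles.items()}
    corpus = [p for p in list(drug_profiles.values()) + list(gene_profiles.values())
              if p.terms]
    ic: ICTable = estimate_ic(corpus)
    return explain_coverage(drug_profiles[drug], gene_profiles[gene], ic)
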