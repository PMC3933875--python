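"""Build drug and gene phenotype profiles and filtered evaluation sets.

Gene profiles come from mouse model annotations restricted to single-gene
loss-of-function models: for each gene the profile is the union of the
phenotype terms observed across all of its retained models. Drug profiles
come from side-effect tables keyed by UMLS concept IDs, mapped into the
phenotype ontology through a layered mapping table (lexical matching against
term names and synonyms, ontology cross-references, and manual curation).
Evaluation sets are known drug-protein interactions filtered to mode of
action "inhibition" at a confidence cutoff, optionally translated from human
to mouse genes through an orthology map.

All tabular inputs are TSV with a header row; gzip-compressed files are
accepted transparently (pandas infers compression from the filename).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .ontology import Ontology, Profile

logger = logging.getLogger(__name__)

PROVENANCE_PRIORITY = {"curated": 0, "xref": 1, "lexical": 2}


class FormatError(ValueError):
    """Raised when an input table is missing required columns or malformed."""


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


@dataclass
class GeneProfileSet:
    """Per-gene phenotype profiles (union over single-gene LOF models)."""

    profiles: dict[str, Profile]
    model_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, gene: str) -> Profile:
        return self.profiles[gene]


@dataclass
class DrugProfileSet:
    """Per-drug phenotype profiles after UMLS -> ontology mapping.

    Drugs whose effects all fail to map are excluded from ``profiles`` and
    listed in ``excluded``; per-drug unmapped-effect counts are retained for
    diagnostics either way.
    """

    profiles: dict[str, Profile]
    unmapped_counts: dict[str, int] = field(default_factory=dict)
    excluded: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, drug: str) -> Profile:
        return self.profiles[drug]


@dataclass(frozen=True)
class MappingRow:
    umls_id: str
    term_id: str
    provenance: str  # lexical | xref | curated


@dataclass
class MappingTable:
    """UMLS concept -> ontology term mapping; one concept may map to many terms."""

    rows: list[MappingRow]

    def to_dict(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for r in self.rows:
            out.setdefault(r.umls_id, set()).add(r.term_id)
        return {k: frozenset(v) for k, v in out.items()}

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def read(cls, path) -> "MappingTable":
        df = _read_tsv(path, ("umls_id", "term_id"))
        prov = df["provenance"] if "provenance" in df.columns else "curated"
        df = df.assign(provenance=prov)
        return cls([MappingRow(r.umls_id, r.term_id, r.provenance)
                    for r in df.itertuples()])


@dataclass(frozen=True)
class EvaluationPair:
    drug: str
    gene: str
    action: str
    confidence: float
    source: str


@dataclass
class EvaluationSet:
    """Positive (drug, gene) pairs retained after action/confidence filtering."""

    pairs: list[EvaluationPair]
    source: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((p.drug, p.gene) for p in self.pairs)


@dataclass
class OrthologyMap:
    """Human gene -> mouse gene(s); one-to-many is permitted."""

    mapping: dict[str, frozenset[str]]

    @classmethod
    def read(cls, path) -> "OrthologyMap":
        df = _read_tsv(path, ("human_gene", "mouse_gene"))
        out: dict[str, set[str]] = {}
        for r in df.itertuples():
            if not r.human_gene or not r.mouse_gene or r.human_gene == r.mouse_gene:
                continue
            out.setdefault(r.human_gene, set()).add(r.mouse_gene)
        return cls({k: frozenset(v) for k, v in out.items()})

    def __getitem__(self, human_gene: str) -> frozenset[str]:
        return self.mapping[human_gene]


def build_gene_profiles(annotations) -> GeneProfileSet:
    """Union per-gene phenotype profiles from a model annotation table.

    ``annotations`` is a TSV path or DataFrame with columns
    ``model_id, gene_id, mp_term, single_gene_lof`` — models with
    ``single_gene_lof`` other than 1 contribute nothing (multi-gene models
    are excluded). Duplicate (model, term) rows de-duplicate silently.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = _read_tsv(
            annotations, ("model_id", "gene_id", "mp_term", "single_gene_lof"))
    kept = annotations[annotations["single_gene_lof"].astype(str) == "1"]
    profiles: dict[str, Profile] = {}
    counts: dict[str, int] = {}
    for gene, sub in kept.groupby("gene_id", sort=True):
        profiles[gene] = Profile(entity_id=gene,
                                 terms=frozenset(sub["mp_term"]))
        counts[gene] = sub["model_id"].nunique()
    n_dropped = annotations["model_id"].nunique() - kept["model_id"].nunique()
    if n_dropped:
        logger.info("excluded %d model(s) failing the single-gene LOF filter",
                    n_dropped)
    return GeneProfileSet(profiles=profiles, model_counts=counts)


_WS_RE = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Normalization for exact lexical matching: case-fold, trim, collapse
    internal whitespace. Deliberately no stemming or punctuation stripping —
    anything more aggressive would inflate matches beyond exact identity."""
    return _WS_RE.sub(" ", label.strip()).casefold()


def lexical_map(umls_terms, ontology: Ontology) -> MappingTable:
    """Map UMLS concepts to ontology terms by exact lexical matching.

    A concept maps to every ontology term whose primary name or any synonym
    equals its label after :func:`normalize_label`. ``umls_terms`` is a TSV
    path or DataFrame with columns ``umls_id, label``.
    """
    if not isinstance(umls_terms, pd.DataFrame):
        umls_terms = _read_tsv(umls_terms, ("umls_id", "label"))
    index: dict[str, set[str]] = {}
    for term, name in ontology.labels.items():
        index.setdefault(normalize_label(name), set()).add(term)
    for term, syns in ontology.synonyms.items():
        for s in syns:
            index.setdefault(normalize_label(s), set()).add(term)
    rows = [
        MappingRow(r.umls_id, term, "lexical")
        for r in umls_terms.itertuples()
        for term in sorted(index.get(normalize_label(r.label), ()))
    ]
    return MappingTable(rows)


def merge_mappings(*tables: MappingTable) -> MappingTable:
    """Union mapping tables, de-duplicating (umls_id, term_id) pairs.

    Conflicting rows for one UMLS ID are all kept (multi-mapping is legal);
    for an identical pair appearing in several layers the provenance of the
    highest-priority layer wins (curated > xref > lexical).
    """
    best: dict[tuple[str, str], str] = {}
    for table in tables:
        for r in table.rows:
            key = (r.umls_id, r.term_id)
            prev = best.get(key)
            if prev is None or (PROVENANCE_PRIORITY.get(r.provenance, 99)
                                < PROVENANCE_PRIORITY.get(prev, 99)):
                best[key] = r.provenance
    return MappingTable(
        [MappingRow(u, t, p) for (u, t), p in sorted(best.items())])


def build_drug_profiles(drug_effects, mapping: MappingTable,
                        ontology: Ontology) -> DrugProfileSet:
    """Build drug phenotype profiles from a (drug_id, umls_id) effect table.

    Each drug's profile is the union of ontology terms its UMLS effects map
    to; mapped terms absent from the ontology are dropped. Drugs with zero
    mapped terms are excluded (logged) but their unmapped counts retained.
    """
    if not isinstance(drug_effects, pd.DataFrame):
        drug_effects = _read_tsv(drug_effects, ("drug_id", "umls_id"))
    if drug_effects[["drug_id", "umls_id"]].isna().any().any():
        bad = int(drug_effects[["drug_id", "umls_id"]].isna().any(axis=1).idxmax())
        raise FormatError(f"drug effect table: empty field at data row {bad + 1}")
    umls_to_terms = mapping.to_dict()
    profiles: dict[str, Profile] = {}
    unmapped: dict[str, int] = {}
    excluded: set[str] = set()
    for drug, sub in drug_effects.groupby("drug_id", sort=True):
        terms: set[str] = set()
        n_unmapped = 0
        for u in sub["umls_id"]:
            mapped = {t for t in umls_to_terms.get(u, ()) if t in ontology}
            if mapped:
                terms |= mapped
            else:
                n_unmapped += 1
        unmapped[drug] = n_unmapped
        if terms:
            profiles[drug] = Profile(entity_id=drug, terms=frozenset(terms))
        else:
            excluded.add(drug)
    if excluded:
        logger.info("excluded %d drug(s) with no mapped effect terms", len(excluded))
    return DrugProfileSet(profiles=profiles, unmapped_counts=unmapped,
                          excluded=frozenset(excluded))


def build_evaluation_set(interactions, *, action_filter: str = "inhibition",
                         min_confidence: float = 0.0,
                         orthology: OrthologyMap | None = None,
                         source: str = "") -> EvaluationSet:
    """Filter a drug-protein interaction table into an evaluation set.

    Keeps rows whose action equals ``action_filter`` and whose confidence is
    at least ``min_confidence`` (inclusive). If an orthology map is given,
    protein IDs are treated as human genes and translated to their mouse
    ortholog(s) — one positive pair per ortholog — and untranslatable rows
    are dropped (logged). The result is de-duplicated on (drug, gene).

    ``interactions``: TSV path or DataFrame with columns
    ``chemical_id, protein_id, action, confidence``.
    """
    if not isinstance(interactions, pd.DataFrame):
        interactions = _read_tsv(
            interactions, ("chemical_id", "protein_id", "action", "confidence"))
    interactions = interactions.assign(
        confidence=interactions["confidence"].astype(float))
    conf = interactions["confidence"]
    if ((conf < 0) | (conf > 1)).any():
        bad = conf[(conf < 0) | (conf > 1)].iloc[0]
        raise ValueError(f"confidence value outside [0, 1]: {bad}")
    kept = interactions.loc[
        (interactions["action"] == action_filter) & (conf >= min_confidence)]
    pairs: dict[tuple[str, str], EvaluationPair] = {}
    n_untranslated = 0
    for r in kept.itertuples():
        if orthology is None:
            genes = [r.protein_id]
        else:
            genes = sorted(orthology.mapping.get(r.protein_id, ()))
            if not genes:
                n_untranslated += 1
                continue
        for g in genes:
            key = (r.chemical_id, g)
            if key not in pairs:
                pairs[key] = EvaluationPair(r.chemical_id, g, r.action,
                                            float(r.confidence), source)
    if n_untranslated:
        logger.info("dropped %d interaction(s) with no mouse ortholog",
                    n_untranslated)
    return EvaluationSet(pairs=[pairs[k] for k in sorted(pairs)], source=source)
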