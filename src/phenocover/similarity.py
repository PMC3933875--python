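"""Information content and the asymmetric coverage similarity.

The central quantity is a non-symmetric, group-wise semantic similarity
between a drug effect profile D and the phenotype profile M of a single-gene
knockout, both closed under subsumption:

    sim(D, M) = sum_{t in D ∩ M} IC(t)  /  sum_{t in D} IC(t)

where IC(t) = -log2 p(t) and p(t) is the fraction of annotated entities
(drugs and genes jointly) whose closed profile contains t. The score is the
fraction of the drug profile's information that the knockout phenotypes
cover: it does not penalize knockout phenotypes absent from the drug
profile, which is deliberate — a drug perturbs many proteins, a knockout
exactly one, so mismatches carry no evidence against the pairing.

Symmetric baselines (SimGIC — the IC-weighted Jaccard this measure derives
from — and the plain Jaccard index) are provided for comparison. The base
of the IC logarithm rescales all IC values by a constant and therefore
cancels in every similarity ratio; base 2 is used so IC reads in bits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import DrugProfileSet, GeneProfileSet
from .ontology import Ontology, Profile, close_profile, restrict_namespace

logger = logging.getLogger(__name__)

MEASURES = ("coverage", "simgic", "jaccard")


class UndefinedScoreError(ValueError):
    """A similarity is requested for profiles over which it is undefined
    (empty drug profile or zero total information content)."""


@dataclass(frozen=True)
class ICTable:
    """Term -> information content (bits), derived from corpus annotation
    frequencies over ``n_entities`` closed profiles. Terms never annotated
    in the corpus have no entry; querying one is an error (it signals that a
    profile was closed against a different ontology or corpus)."""

    ic: dict[str, float]
    n_entities: int

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise KeyError(
                f"term {term!r} has no corpus annotations, so its information "
                "content is undefined; was the profile closed over the same "
                "ontology and corpus?") from None

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __len__(self) -> int:
        return len(self.ic)

    def total(self, terms) -> float:
        """Summed IC over a term set (every term must be in the table)."""
        return sum(self[t] for t in terms)


def estimate_ic(profiles) -> ICTable:
    """Estimate per-term information content from a corpus of closed profiles.

    p(t) is the fraction of distinct entities whose closed profile contains
    t; IC(t) = -log2 p(t). A term carried by every entity (e.g. the root
    after closure) gets IC exactly 0.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot estimate information content from an empty corpus")
    for p in profiles:
        if not p.closed:
            raise ValueError(f"profile {p.entity_id!r} is not closed; "
                             "close profiles before IC estimation")
    n = len(profiles)
    counts: dict[str, int] = {}
    for p in profiles:
        for t in p.terms:
            counts[t] = counts.get(t, 0) + 1
    ic = {t: -math.log2(c / n) for t, c in counts.items()}
    return ICTable(ic=ic, n_entities=n)


def coverage_similarity(drug: Profile, model: Profile, ic: ICTable) -> float:
    """Fraction of the drug profile's information covered by the model.

    Non-symmetric: sum IC over D ∩ M divided by sum IC over D. Requires a
    non-empty drug profile with positive total IC; a drug violating that
    should have been excluded upstream.
    """
    denom = ic.total(drug.terms)
    if not drug.terms or denom <= 0.0:
        raise UndefinedScoreError(
            f"coverage similarity undefined for drug {drug.entity_id!r}: "
            "empty profile or zero total information content")
    num = ic.total(drug.terms & model.terms)
    return num / denom


def simgic(a: Profile, b: Profile, ic: ICTable) -> float:
    """Symmetric IC-weighted Jaccard: IC of the intersection over IC of the union."""
    union = a.terms | b.terms
    denom = ic.total(union)
    if not union or denom <= 0.0:
        raise UndefinedScoreError(
            f"SimGIC undefined for {a.entity_id!r} vs {b.entity_id!r}: "
            "empty union or zero total information content")
    return ic.total(a.terms & b.terms) / denom


def jaccard(a: Profile, b: Profile) -> float:
    """Plain Jaccard index |A ∩ B| / |A ∪ B|."""
    union = a.terms | b.terms
    if not union:
        raise UndefinedScoreError(
            f"Jaccard undefined for {a.entity_id!r} vs {b.entity_id!r}: both empty")
    return len(a.terms & b.terms) / len(union)


@dataclass
class SimilarityMatrix:
    """Dense drugs x genes score matrix with aligned, sorted ID lists."""

    drugs: list[str]
    genes: list[str]
    scores: np.ndarray  # shape (len(drugs), len(genes)), values in [0, 1]
    measure: str = "coverage"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.drugs), len(self.genes)):
            raise ValueError("score matrix shape does not match ID lists")
        self._drug_index = {d: i for i, d in enumerate(self.drugs)}
        self._gene_index = {g: j for j, g in enumerate(self.genes)}

    def score(self, drug: str, gene: str) -> float:
        return float(self.scores[self._drug_index[drug], self._gene_index[gene]])

    def drug_row(self, drug: str) -> np.ndarray:
        if drug not in self._drug_index:
            raise KeyError(f"unknown drug: {drug!r}")
        return self.scores[self._drug_index[drug]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=pd.Index(self.drugs, name="drug_id"),
                            columns=self.genes)

    def write_tsv(self, path) -> None:
        frame = self.to_frame().map(lambda v: float(f"{v:.6g}"))
        frame.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, measure: str = "coverage") -> "SimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(drugs=[str(d) for d in frame.index],
                   genes=[str(g) for g in frame.columns],
                   scores=frame.to_numpy(dtype=float), measure=measure)


def _profile_matrix(profiles: dict[str, Profile], term_index: dict[str, int]
                    ) -> np.ndarray:
    mat = np.zeros((len(profiles), len(term_index)), dtype=bool)
    for i, p in enumerate(profiles.values()):
        for t in p.terms:
            mat[i, term_index[t]] = True
    return mat


def build_matrix(drugs: DrugProfileSet, genes: GeneProfileSet,
                 ontology: Ontology, *, measure: str = "coverage",
                 namespace_prefix: str | None = "MP:",
                 ic_corpus: str = "joint") -> SimilarityMatrix:
    """Assemble the drugs x genes similarity matrix.

    All profiles are closed over the (merged) ontology, restricted to
    ``namespace_prefix`` (pass ``None`` to skip the restriction), and the IC
    table is estimated once over the combined corpus — drugs and genes
    jointly by default, or genes only with ``ic_corpus="genes"`` for
    sensitivity analysis. Drugs whose restricted profile is empty are
    excluded as rows, phenotype-less genes as columns (both logged).
    Output ordering is sorted on IDs, so the matrix is deterministic.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if ic_corpus not in ("joint", "genes"):
        raise ValueError("ic_corpus must be 'joint' or 'genes'")

    def prepare(profile: Profile) -> Profile:
        closed = profile if profile.closed else close_profile(profile, ontology)
        return restrict_namespace(closed, namespace_prefix) if namespace_prefix else closed

    drug_profiles = {d: prepare(p) for d, p in sorted(drugs.profiles.items())}
    gene_profiles = {g: prepare(p) for g, p in sorted(genes.profiles.items())}
    dropped_drugs = [d for d, p in drug_profiles.items() if not p.terms]
    dropped_genes = [g for g, p in gene_profiles.items() if not p.terms]
    for d in dropped_drugs:
        del drug_profiles[d]
    for g in dropped_genes:
        del gene_profiles[g]
    if dropped_drugs:
        logger.info("excluded %d drug(s) with empty restricted profiles",
                    len(dropped_drugs))
    if dropped_genes:
        logger.info("excluded %d gene(s) with empty restricted profiles",
                    len(dropped_genes))
    if not drug_profiles or not gene_profiles:
        raise ValueError("no scorable drugs or genes after closure/restriction")

    corpus = (list(drug_profiles.values()) + list(gene_profiles.values())
              if ic_corpus == "joint" else list(gene_profiles.values()))
    ic_table = estimate_ic(corpus)

    terms = sorted({t for p in corpus for t in p.terms})
    term_index = {t: k for k, t in enumerate(terms)}
    # Terms outside the IC corpus (possible under ic_corpus="genes") are a
    # usage error for IC-weighted measures; surface it per the scalar API.
    if ic_corpus == "genes":
        extra = {t for p in drug_profiles.values() for t in p.terms} - set(terms)
        if extra and measure in ("coverage", "simgic"):
            raise KeyError(
                f"{len(extra)} drug profile term(s) absent from the gene-only "
                f"IC corpus, e.g. {sorted(extra)[:3]}")
        for t in extra:
            term_index[t] = len(term_index)

    d_mat = _profile_matrix(drug_profiles, term_index)
    g_mat = _profile_matrix(gene_profiles, term_index)
    ic_vec = np.zeros(len(term_index))
    for t, k in term_index.items():
        if t in ic_table:
            ic_vec[k] = ic_table[t]

    d_ic = d_mat @ ic_vec          # per-drug total IC
    # Vectorized score assembly; boolean intersection via float matmul.
    df = d_mat.astype(float)
    gf = g_mat.astype(float)
    if measure == "coverage":
        # A profile reduced to universally shared terms (e.g. the root alone)
        # carries zero information; its coverage is undefined, so the drug is
        # excluded just like an empty-profile one. IC stays estimated over
        # the full corpus — the drug is still an annotated entity.
        bad = d_ic <= 0.0
        if bad.any():
            names = [d for d, m in zip(drug_profiles, bad) if m]
            logger.info("excluded %d drug(s) with zero total profile IC: %s",
                        len(names), names[:5])
            keep = ~bad
            df, d_ic = df[keep], d_ic[keep]
            drug_profiles = {d: p for (d, p), k in
                             zip(drug_profiles.items(), keep) if k}
            if not drug_profiles:
                raise UndefinedScoreError(
                    "every drug profile has zero total information content")
        inter = (df * ic_vec) @ gf.T
        scores = inter / d_ic[:, None]
    elif measure == "simgic":
        inter = (df * ic_vec) @ gf.T
        union = d_ic[:, None] + (gf @ ic_vec)[None, :] - inter
        with np.errstate(invalid="ignore"):
            scores = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    else:  # jaccard
        inter = df @ gf.T
        union = df.sum(1)[:, None] + gf.sum(1)[None, :] - inter
        scores = inter / union
    return SimilarityMatrix(drugs=list(drug_profiles), genes=list(gene_profiles),
                            scores=np.clip(scores, 0.0, 1.0), measure=measure)


def explain_coverage(drug: Profile, model: Profile, ic: ICTable) -> dict:
    """Per-term decomposition of a coverage score.

    Returns the covered-IC fraction (identical to
    :func:`coverage_similarity`) together with the covered and uncovered
    drug-profile terms and their IC values — the quantity reported when one
    says "X% of a drug's effect information is explained by this knockout".
    """
    fraction = coverage_similarity(drug, model, ic)
    covered = sorted(drug.terms & model.terms)
    uncovered = sorted(drug.terms - model.terms)
    return {
        "drug": drug.entity_id,
        "gene": model.entity_id,
        "fraction": fraction,
        "covered": [(t, ic[t]) for t in covered],
        "uncovered": [(t, ic[t]) for t in uncovered],
        "covered_ic": ic.total(covered),
        "total_ic": ic.total(drug.terms),
    }
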