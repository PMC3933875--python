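"""Phenotype ontology handling: OBO parsing, subsumption DAG, annotation closure.

The similarity pipeline operates on a merged cross-species phenotype ontology
(Mammalian Phenotype terms plus Human Phenotype terms, with cross-namespace
``is_a`` links already materialized by an upstream integration step). This
module parses such an ontology from OBO flat files, exposes reflexive ancestor
sets over the ``is_a`` graph, and propagates annotations to superclasses —
the "true-path" closure that group-wise semantic similarity assumes.

Only ``is_a`` edges are traversed; ``part_of`` and other relations are
ignored, since subsumption is the relation the similarity is defined over.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

_SYNONYM_RE = re.compile(r'^"(.*)"')


class OntologyError(ValueError):
    """Raised for malformed or cyclic ontology input."""


@dataclass(frozen=True)
class Ontology:
    """A phenotype ontology as a subsumption DAG.

    Parameters
    ----------
    parents
        Map from term ID to the set of its direct ``is_a`` parents.
        Every referenced parent must itself be a key.
    labels
        Term ID -> primary name.
    synonyms
        Term ID -> set of synonym strings (text only, scope/xrefs stripped).
    obsolete
        IDs of obsolete terms; these are recorded for diagnostics but are
        not part of the DAG and carry no edges.
    """

    parents: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, frozenset[str]] = field(default_factory=dict)
    obsolete: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for term, ps in self.parents.items():
            missing = ps - self.parents.keys()
            if missing:
                raise OntologyError(
                    f"term {term!r} references unknown parent(s): {sorted(missing)}"
                )
        graph = nx.DiGraph(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"is_a graph contains a cycle: {cycle}")
        # Precompute reflexive ancestor sets once; terms are processed in
        # topological order so each set is built from its parents' sets.
        anc: dict[str, frozenset[str]] = {}
        for term in self._topological_order():
            s = {term}
            for p in self.parents[term]:
                s |= anc[p]
            anc[term] = frozenset(s)
        object.__setattr__(self, "_ancestors", anc)

    def _topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}
        for start in self.parents:
            if start in state:
                continue
            stack = [start]
            while stack:
                t = stack[-1]
                if state.get(t, 0) == 0:
                    state[t] = 1
                    stack.extend(p for p in self.parents[t] if state.get(p, 0) == 0)
                else:
                    if state[t] == 1:
                        state[t] = 2
                        order.append(t)
                    stack.pop()
        return order

    @property
    def terms(self) -> frozenset[str]:
        """All non-obsolete term IDs."""
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive ancestor set: all terms reachable via ``is_a``, plus the term.

        Raises
        ------
        KeyError
            If ``term`` is not a non-obsolete term of this ontology.
        """
        try:
            return self._ancestors[term]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown ontology term: {term!r}") from None

    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self.parents.items() if not ps)

    def n_edges(self) -> int:
        return sum(len(ps) for ps in self.parents.values())


@dataclass(frozen=True)
class Profile:
    """A set of ontology terms annotating one entity (a drug or a gene).

    ``closed=True`` marks that the set has been augmented with all ancestors
    of its members (annotation propagation); closure is idempotent.
    """

    entity_id: str
    terms: frozenset[str]
    closed: bool = False

    def __len__(self) -> int:
        return len(self.terms)


def _synonym_text(raw: str) -> str | None:
    m = _SYNONYM_RE.match(raw.strip())
    return m.group(1) if m else None


def parse_obo(path) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Non-obsolete ``[Term]`` stanzas become DAG nodes; ``is_a`` and
    ``relationship: is_a`` edges are captured; obsolete terms are recorded in
    ``Ontology.obsolete`` and excluded from the DAG. A cyclic ``is_a`` graph
    raises :class:`OntologyError` naming one cycle.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except (ValueError, KeyError) as exc:
        raise OntologyError(f"malformed OBO file {path!r}: {exc}") from exc

    obsolete = frozenset(
        t for t, d in graph.nodes(data=True)
        if str(d.get("is_obsolete", "")).lower() == "true"
    )
    live = [t for t in graph.nodes if t not in obsolete]
    parents: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    synonyms: dict[str, frozenset[str]] = {}
    for t in live:
        data = graph.nodes[t]
        # obonet edges point child -> parent, keyed by relation type.
        ps = frozenset(
            parent
            for _, parent, rel in graph.out_edges(t, keys=True)
            if rel == "is_a" and parent not in obsolete
        )
        parents[t] = ps
        if "name" in data:
            labels[t] = data["name"]
        syns = frozenset(
            s for s in (_synonym_text(x) for x in data.get("synonym", [])) if s
        )
        if syns:
            synonyms[t] = syns
    return Ontology(parents=parents, labels=labels, synonyms=synonyms,
                    obsolete=obsolete)


def close_profile(profile: Profile, ontology: Ontology, *,
                  on_unknown: str = "drop") -> Profile:
    """Propagate annotations to superclasses (reflexive ancestor closure).

    Terms absent from the ontology are dropped with a warning by default
    (real annotation snapshots contain retired IDs); ``on_unknown="error"``
    raises instead. The input profile is not modified; closing an already
    closed profile is a no-op up to re-validation.
    """
    if on_unknown not in ("drop", "error"):
        raise ValueError(f"on_unknown must be 'drop' or 'error', got {on_unknown!r}")
    closed: set[str] = set()
    unknown: list[str] = []
    for t in profile.terms:
        if t in ontology:
            closed |= ontology.ancestors(t)
        else:
            unknown.append(t)
    if unknown:
        if on_unknown == "error":
            raise KeyError(
                f"profile {profile.entity_id!r} has terms not in the ontology: "
                f"{sorted(unknown)}"
            )
        logger.warning(
            "profile %s: dropped %d term(s) not in the ontology: %s",
            profile.entity_id, len(unknown), sorted(unknown)[:5],
        )
    return Profile(entity_id=profile.entity_id, terms=frozenset(closed),
                   closed=True)


def restrict_namespace(profile: Profile, prefix: str) -> Profile:
    """Keep only terms whose ID starts with ``prefix`` (e.g. ``"MP:"``).

    Applied after closure so that cross-namespace ancestors mapped into the
    target namespace survive while foreign-namespace terms are removed. The
    result may be empty; downstream policy (e.g. excluding the entity from
    the similarity matrix) is the caller's decision.
    """
    if not profile.closed:
        raise ValueError("restrict_namespace expects a closed profile")
    return replace(profile,
                   terms=frozenset(t for t in profile.terms if t.startswith(prefix)))
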