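"""Shared fixtures: small hand-built ontologies and random-profile factories."""

import numpy as np
import pytest

from phenocover.ontology import Ontology, Profile

# Ten terms, twelve is_a edges, one synonym each; the manifest the parse
# test checks against is (10 terms, 12 edges, 1 obsolete).
FIXTURE_OBO = """format-version: 1.2
ontology: fixture

[Term]
id: MP:0000001
name: root phenotype
synonym: "any phenotype" EXACT []

[Term]
id: MP:0000002
name: growth phenotype
synonym: "growth anomaly" EXACT []
is_a: MP:0000001 ! root phenotype

[Term]
id: MP:0000003
name: skeletal phenotype
synonym: "bone phenotype" EXACT []
is_a: MP:0000001 ! root phenotype

[Term]
id: MP:0000004
name: limb phenotype
synonym: "limb anomaly" EXACT []
is_a: MP:0000003 ! skeletal phenotype

[Term]
id: MP:0000005
name: bone overgrowth
synonym: "skeletal overgrowth" EXACT []
is_a: MP:0000002 ! growth phenotype
is_a: MP:0000003 ! skeletal phenotype

[Term]
id: MP:0000006
name: fibula phenotype
synonym: "fibular anomaly" EXACT []
is_a: MP:0000004 ! limb phenotype

[Term]
id: MP:0000007
name: fibula overgrowth
synonym: "fibular overgrowth" EXACT []
is_a: MP:0000005 ! bone overgrowth
is_a: MP:0000006 ! fibula phenotype

[Term]
id: MP:0000008
name: behavior phenotype
synonym: "behavioural phenotype" EXACT []
is_a: MP:0000001 ! root phenotype

[Term]
id: MP:0000009
name: nausea
synonym: "sickness feeling" EXACT []
is_a: MP:0000008 ! behavior phenotype

[Term]
id: MP:0000010
name: tremor
synonym: "shaking" EXACT []
is_a: MP:0000008 ! behavior phenotype
is_a: MP:0000002 ! growth phenotype

[Term]
id: MP:0000099
name: retired phenotype
is_obsolete: true
"""

FIXTURE_MANIFEST = {"n_terms": 10, "n_edges": 12, "n_obsolete": 1}


@pytest.fixture
def fixture_obo(tmp_path):
    path = tmp_path / "fixture.obo"
    path.write_text(FIXTURE_OBO)
    return path


@pytest.fixture
def chain_ontology():
    """leaf -> mid -> root."""
    return Ontology(parents={
        "MP:0000001": frozenset(),
        "MP:0000002": frozenset({"MP:0000001"}),
        "MP:0000003": frozenset({"MP:0000002"}),
    })


@pytest.fixture
def diamond_ontology():
    """a -> {b, c} -> d."""
    return Ontology(parents={
        "d": frozenset(),
        "b": frozenset({"d"}),
        "c": frozenset({"d"}),
        "a": frozenset({"b", "c"}),
    })


@pytest.fixture
def merged_ontology():
    """Two-namespace DAG: an HP term subsumed by an MP term, as a merged
    cross-species ontology materializes (specific human phenotype under a
    more general mouse phenotype)."""
    return Ontology(parents={
        "MP:0000001": frozenset(),
        "MP:0002187": frozenset({"MP:0000001"}),     # abnormal fibula morphology
        "HP:0007126": frozenset({"MP:0002187"}),     # proximal fibular overgrowth
        "HP:0000002": frozenset({"MP:0000001"}),
    })


def random_dag(rng: np.random.Generator, n_terms: int,
               mean_parents: float = 1.5) -> Ontology:
    parents = {"T0000": frozenset()}
    for i in range(1, n_terms):
        k = min(i, 1 + int(rng.poisson(max(mean_parents - 1, 0))))
        ps = rng.choice(i, size=k, replace=False)
        parents[f"T{i:04d}"] = frozenset(f"T{int(j):04d}" for j in ps)
    return Ontology(parents=parents)


def random_profile(rng: np.random.Generator, ontology: Ontology,
                   max_size: int = 10, entity: str = "E") -> Profile:
    terms = sorted(ontology.terms)
    size = int(rng.integers(1, max_size + 1))
    chosen = rng.choice(len(terms), size=min(size, len(terms)), replace=False)
    return Profile(entity_id=entity, terms=frozenset(terms[int(i)] for i in chosen))


def brute_force_ancestors(ontology: Ontology, term: str) -> set[str]:
    """Independent oracle: repeated parent expansion to a fixed point."""
    out = {term}
    while True:
        grown = set(out)
        for t in out:
            grown |= ontology.parents[t]
        if grown == out:
            return out
        out = grown
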