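"""Information content and the coverage / SimGIC / Jaccard measures."""

import math

import numpy as np
import pytest

from phenocover.corpus import DrugProfileSet, GeneProfileSet
from phenocover.ontology import Ontology, Profile, close_profile
from phenocover.similarity import (ICTable, SimilarityMatrix,
                                   UndefinedScoreError, build_matrix,
                                   coverage_similarity, estimate_ic, jaccard,
                                   simgic)

from conftest import random_dag, random_profile


def closed(entity, terms):
    return Profile(entity, frozenset(terms), closed=True)


class TestEstimateIC:
    def test_half_corpus_term_is_one_bit(self):
        profiles = [closed(f"e{i}", {"t"} if i < 2 else {"s"}) for i in range(4)]
        ic = estimate_ic(profiles)
        assert ic["t"] == pytest.approx(1.0)
        assert ic.n_entities == 4

    def test_universal_term_has_zero_ic(self):
        profiles = [closed(f"e{i}", {"root", f"t{i}"}) for i in range(5)]
        assert estimate_ic(profiles)["root"] == 0.0

    def test_never_annotated_term_raises(self):
        ic = estimate_ic([closed("e", {"t"})])
        with pytest.raises(KeyError, match="ghost"):
            ic["ghost"]

    def test_unclosed_profiles_rejected(self):
        with pytest.raises(ValueError, match="not closed"):
            estimate_ic([Profile("e", frozenset({"t"}))])

    def test_matches_counting_oracle_on_random_profiles(self):
        rng = np.random.default_rng(11)
        ont = random_dag(rng, 60)
        profiles = [close_profile(random_profile(rng, ont, entity=f"e{i}"), ont)
                    for i in range(100)]
        ic = estimate_ic(profiles)
        for term in sorted({t for p in profiles for t in p.terms}):
            count = sum(term in p.terms for p in profiles)
            assert ic[term] == pytest.approx(-math.log2(count / 100), abs=1e-12)

    def test_ic_antitone_along_is_a_edges(self):
        rng = np.random.default_rng(13)
        ont = random_dag(rng, 80)
        profiles = [close_profile(random_profile(rng, ont, entity=f"e{i}"), ont)
                    for i in range(50)]
        ic = estimate_ic(profiles)
        for child, parents in ont.parents.items():
            if child not in ic:
                continue
            for parent in parents:
                assert ic[parent] <= ic[child] + 1e-12


IC3 = ICTable(ic={"t1": 1.0, "t2": 2.0, "t3": 3.0}, n_entities=8)


class TestScalarMeasures:
    def test_coverage_hand_example(self):
        d = closed("d", {"t1", "t2", "t3"})
        m = closed("m", {"t1", "t3"})
        assert coverage_similarity(d, m, IC3) == pytest.approx(4 / 6)

    def test_full_coverage_and_disjoint(self):
        d = closed("d", {"t1", "t2"})
        assert coverage_similarity(d, closed("m", {"t1", "t2", "t3"}), IC3) == 1.0
        assert coverage_similarity(d, closed("m", {"t3"}), IC3) == 0.0

    def test_coverage_undefined_for_empty_or_zero_ic_drug(self):
        with pytest.raises(UndefinedScoreError):
            coverage_similarity(closed("d", set()), closed("m", {"t1"}), IC3)
        zero = ICTable(ic={"t1": 0.0}, n_entities=2)
        with pytest.raises(UndefinedScoreError):
            coverage_similarity(closed("d", {"t1"}), closed("m", {"t1"}), zero)

    def test_simgic_hand_example_and_symmetry(self):
        a, b = closed("a", {"t1", "t2"}), closed("b", {"t2", "t3"})
        assert simgic(a, b, IC3) == pytest.approx(2 / 6)
        assert simgic(b, a, IC3) == simgic(a, b, IC3)

    def test_jaccard_hand_examples(self):
        a, b = closed("a", {"t1", "t2"}), closed("b", {"t2", "t3"})
        assert jaccard(a, b) == pytest.approx(1 / 3)
        assert jaccard(a, a) == 1.0
        assert jaccard(a, closed("c", {"t3"})) == 0.0

    def test_identity_scores_one_for_all_measures(self):
        a = closed("a", {"t1", "t3"})
        assert coverage_similarity(a, a, IC3) == 1.0
        assert simgic(a, a, IC3) == 1.0
        assert jaccard(a, a) == 1.0

    def test_both_empty_undefined(self):
        e = closed("e", set())
        for fn in (lambda: simgic(e, e, IC3), lambda: jaccard(e, e)):
            with pytest.raises(UndefinedScoreError):
                fn()

    def test_log_base_cancels_in_ratios(self):
        d = closed("d", {"t1", "t2", "t3"})
        m = closed("m", {"t2"})
        nats = ICTable(ic={t: v * math.log(2) for t, v in IC3.ic.items()},
                       n_entities=8)
        assert coverage_similarity(d, m, nats) == pytest.approx(
            coverage_similarity(d, m, IC3))
        assert simgic(d, m, nats) == pytest.approx(simgic(d, m, IC3))

    def test_coverage_monotone_in_model_terms(self):
        rng = np.random.default_rng(5)
        ont = random_dag(rng, 50)
        profiles = [close_profile(random_profile(rng, ont, entity=f"e{i}"), ont)
                    for i in range(30)]
        ic = estimate_ic(profiles)
        d = profiles[0]
        for m in profiles[1:6]:
            base = coverage_similarity(d, m, ic)
            extra = sorted(set().union(*(p.terms for p in profiles)) - m.terms)
            grown = closed(m.entity_id, m.terms | set(extra[:3]))
            assert coverage_similarity(d, grown, ic) >= base - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_set_arithmetic_oracle(self, seed):
        """All three measures equal a from-scratch set-arithmetic recomputation
        on 100 random closed-profile pairs (500 pairs over the seeds)."""
        rng = np.random.default_rng(1000 + seed)
        ont = random_dag(rng, 70)
        corpus = [close_profile(random_profile(rng, ont, entity=f"e{i}"), ont)
                  for i in range(60)]
        ic = estimate_ic(corpus)
        for _ in range(100):
            a, b = rng.choice(60, size=2, replace=False)
            d, m = corpus[int(a)], corpus[int(b)]
            inter, union = d.terms & m.terms, d.terms | m.terms
            ic_d = sum(ic[t] for t in d.terms)
            ic_i = sum(ic[t] for t in inter)
            ic_u = sum(ic[t] for t in union)
            if ic_d > 0:
                assert abs(coverage_similarity(d, m, ic) - ic_i / ic_d) < 1e-12
            if ic_u > 0:
                assert abs(simgic(d, m, ic) - ic_i / ic_u) < 1e-12
            assert abs(jaccard(d, m) - len(inter) / len(union)) < 1e-12


class TestBuildMatrix:
    @staticmethod
    def tiny_sets():
        ont = Ontology(parents={
            "MP:1": frozenset(),
            "MP:2": frozenset({"MP:1"}),
            "MP:3": frozenset({"MP:1"}),
            "MP:4": frozenset({"MP:2"}),
            "MP:5": frozenset({"MP:3"}),
        })
        drugs = DrugProfileSet(profiles={
            "dA": Profile("dA", frozenset({"MP:4"})),
            "dB": Profile("dB", frozenset({"MP:4", "MP:5"})),
            "dC": Profile("dC", frozenset({"MP:5", "MP:2"})),
        })
        genes = GeneProfileSet(profiles={
            "g1": Profile("g1", frozenset({"MP:4"})),
            "g2": Profile("g2", frozenset({"MP:5"})),
            "g3": Profile("g3", frozenset({"MP:2", "MP:3"})),
            "g4": Profile("g4", frozenset({"MP:3"})),
        })
        return ont, drugs, genes

    def test_identical_profiles_score_one(self):
        # the background gene keeps the corpus non-degenerate (without it all
        # terms are universal, IC vanishes and the drug is unscorable)
        ont, _, _ = self.tiny_sets()
        drugs = DrugProfileSet(profiles={"d": Profile("d", frozenset({"MP:4"}))})
        genes = GeneProfileSet(profiles={
            "g": Profile("g", frozenset({"MP:4"})),
            "gBackground": Profile("gBackground", frozenset({"MP:5"}))})
        mat = build_matrix(drugs, genes, ont)
        assert mat.score("d", "g") == pytest.approx(1.0)

    @pytest.mark.parametrize("measure", ["coverage", "simgic", "jaccard"])
    def test_cells_equal_scalar_measure(self, measure):
        ont, drugs, genes = self.tiny_sets()
        mat = build_matrix(drugs, genes, ont, measure=measure)
        prepared = {e: close_profile(p, ont)
                    for e, p in {**drugs.profiles, **genes.profiles}.items()}
        ic = estimate_ic(list(prepared.values()))
        for d in mat.drugs:
            for g in mat.genes:
                if measure == "coverage":
                    expected = coverage_similarity(prepared[d], prepared[g], ic)
                elif measure == "simgic":
                    expected = simgic(prepared[d], prepared[g], ic)
                else:
                    expected = jaccard(prepared[d], prepared[g])
                assert mat.score(d, g) == pytest.approx(expected, abs=1e-12)

    def test_coverage_is_asymmetric_on_fixture(self):
        ont, drugs, genes = self.tiny_sets()
        mat = build_matrix(drugs, genes, ont)
        swapped = build_matrix(
            DrugProfileSet(profiles=genes.profiles),
            GeneProfileSet(profiles=drugs.profiles), ont)
        asym = [abs(mat.score(d, g) - swapped.score(g, d)) > 1e-9
                for d in mat.drugs for g in mat.genes]
        assert any(asym)

    def test_namespace_restriction_drops_foreign_terms(self, merged_ontology):
        drugs = DrugProfileSet(profiles={
            "d": Profile("d", frozenset({"HP:0007126"}))})
        genes = GeneProfileSet(profiles={
            "g": Profile("g", frozenset({"MP:0002187"})),
            "gRootOnly": Profile("gRootOnly", frozenset({"MP:0000001"}))})
        mat = build_matrix(drugs, genes, merged_ontology, namespace_prefix="MP:")
        # after closure+restriction the drug profile is exactly g's
        assert mat.score("d", "g") == pytest.approx(1.0)

    def test_empty_restricted_drug_excluded(self, merged_ontology):
        drugs = DrugProfileSet(profiles={
            "d": Profile("d", frozenset({"HP:0007126"})),
            "dOnlyForeign": Profile("dOnlyForeign", frozenset({"HP:0000002"}))})
        genes = GeneProfileSet(profiles={
            "g": Profile("g", frozenset({"MP:0002187"}))})
        # HP:0000002 closes to {HP:0000002, MP root}; restriction leaves only
        # the root, which has zero IC -> drug excluded
        mat = build_matrix(drugs, genes, merged_ontology, namespace_prefix="MP:")
        assert mat.drugs == ["d"]

    def test_matrix_tsv_roundtrip(self, tmp_path):
        ont, drugs, genes = self.tiny_sets()
        mat = build_matrix(drugs, genes, ont)
        path = tmp_path / "m.tsv"
        mat.write_tsv(path)
        back = SimilarityMatrix.read_tsv(path)
        assert back.drugs == mat.drugs and back.genes == mat.genes
        np.testing.assert_allclose(back.scores, mat.scores, rtol=1e-5)

    def test_scores_within_unit_interval(self):
        ont, drugs, genes = self.tiny_sets()
        for measure in ("coverage", "simgic", "jaccard"):
            mat = build_matrix(drugs, genes, ont, measure=measure)
            assert ((mat.scores >= 0) & (mat.scores <= 1)).all()
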