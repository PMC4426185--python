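"""Candidate generation, chaining and gold alignment."""

import pytest

import lalex as lx
from lalex.candidates import (
    AlignmentAmbiguityError,
    align_gold,
    build_candidate_set,
    chain_relation_pairs,
    gazetteer_chunks,
    generate_entity_candidates,
    generate_relation_candidates,
)
from lalex.lexicons import HabitatOntology, OntologyNode, TaxonomyLexicon
from lalex.model import is_feasible
from lalex.standoff import (
    AlignmentError,
    AnnotationSet,
    EntityAnnotation,
    RelationAnnotation,
    TextSpan,
)
from lalex.synthetic import GeneratorConfig, generate_corpus
from tests.conftest import make_doc


@pytest.fixture()
def doc_and_lexicons(one_sentence_doc, tiny_lexicons):
    return one_sentence_doc, *tiny_lexicons


class TestEntityCandidates:
    def test_lexicon_membership_drives_candidacy(self, doc_and_lexicons):
        doc, ont, tax = doc_and_lexicons
        chunks = [TextSpan(0, 22), TextSpan(37, 46)]  # full name, "human gut"
        cands = generate_entity_candidates(doc, chunks, ont, tax)
        assert [(c.in_C_tr, c.in_C_lm) for c in cands] == [(True, False), (False, True)]
        assert cands[0].mention(doc) == "Bifidobacterium longum"
        assert cands[1].mention(doc) == "human gut"

    def test_chunk_overlapping_no_lexicon_is_discarded(self, doc_and_lexicons):
        doc, ont, tax = doc_and_lexicons
        the = doc.text.index("the")
        cands = generate_entity_candidates(doc, [TextSpan(the, the + 3)], ont, tax)
        assert cands == []

    def test_chunk_overlapping_both_lexicons_joins_both_sets(self, one_sentence_doc):
        ont = HabitatOntology([OntologyNode("O1", "longum")])  # constructed overlap
        tax = TaxonomyLexicon(["Bifidobacterium longum"])
        cands = generate_entity_candidates(
            one_sentence_doc, [TextSpan(0, 22)], ont, tax
        )
        assert [(c.in_C_tr, c.in_C_lm) for c in cands] == [(True, True)]

    def test_head_is_token_with_external_dependency_head(self, doc_and_lexicons):
        doc, ont, tax = doc_and_lexicons
        cands = generate_entity_candidates(doc, [TextSpan(0, 22)], ont, tax)
        # "longum" heads the phrase: its dependency head (the verb) is outside
        assert doc.tokens[cands[0].head_index].surface == "longum"

    def test_misaligned_chunk_raises(self, doc_and_lexicons):
        doc, ont, tax = doc_and_lexicons
        with pytest.raises(AlignmentError):
            generate_entity_candidates(doc, [TextSpan(0, 10)], ont, tax)


class TestRelationCandidates:
    def _phrase(self, k, tr, lm):
        return lx.PhraseCandidate(k, "d", (k,), TextSpan(k * 5, k * 5 + 3), k, tr, lm)

    def test_cross_product_size(self):
        phrases = [self._phrase(k, True, False) for k in range(2)]
        phrases += [self._phrase(k + 2, False, True) for k in range(3)]
        rels = generate_relation_candidates(phrases)
        assert len(rels) == 6
        starts = [(r.bacterium.span.start, r.habitat.span.start) for r in rels]
        assert starts == sorted(starts)

    def test_no_bacteria_means_no_relations(self):
        phrases = [self._phrase(0, False, True)]
        assert generate_relation_candidates(phrases) == []

    def test_dual_membership_excludes_self_pair(self):
        phrases = [self._phrase(0, True, True), self._phrase(1, False, True)]
        rels = generate_relation_candidates(phrases)
        assert len(rels) == 1
        assert rels[0].bacterium.id == 0 and rels[0].habitat.id == 1

    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 0), (3, 2), (5, 4)])
    def test_chaining_pairs_each_relation_with_its_successor(self, n, expected):
        phrases = [self._phrase(0, True, False)] + [
            self._phrase(k + 1, False, True) for k in range(n)
        ]
        rels = generate_relation_candidates(phrases)[:n]
        pairs = chain_relation_pairs(rels)
        assert len(pairs) == expected
        for i, p in enumerate(pairs):
            assert p.first is rels[i] and p.second is rels[i + 1]


class TestGoldAlignment:
    def _cands(self, doc, ont, tax):
        chunks = [TextSpan(0, 22), TextSpan(37, 46)]
        return build_candidate_set(doc, chunks, ont, tax)

    def test_empty_gold_gives_all_auxiliary_labels(self, doc_and_lexicons):
        doc, ont, tax = doc_and_lexicons
        cands = self._cands(doc, ont, tax)
        y = align_gold(cands, AnnotationSet())
        assert y.nrol.all() and y.nloc.all() and not y.rr.any()
        assert not y.tr.any() and not y.lm.any()

    def test_exact_span_match_sets_entity_labels(self, doc_and_lexicons):
        doc, ont, tax = doc_and_lexicons
        cands = self._cands(doc, ont, tax)
        gold = AnnotationSet(
            entities=[
                EntityAnnotation("T1", "Bacterium", (TextSpan(0, 22),), "Bifidobacterium longum"),
                EntityAnnotation("T2", "Habitat", (TextSpan(37, 46),), "human gut"),
            ],
            relations=[RelationAnnotation("R1", "Localization", "T1", "T2")],
        )
        y = align_gold(cands, gold)
        assert y.tr.tolist() == [1, 0] and y.lm.tolist() == [0, 1]
        assert y.loc.sum() == 1 and y.nloc.sum() == len(cands.relations) - 1
        assert cands.alignment.entity_recall_ceiling == 1.0
        assert is_feasible(cands, y)

    def test_overlap_mode_accepts_boundary_mismatch(self, doc_and_lexicons):
        doc, ont, tax = doc_and_lexicons
        cands = self._cands(doc, ont, tax)
        gold = AnnotationSet(
            entities=[
                EntityAnnotation("T1", "Habitat", (TextSpan(42, 46),), "gut"),
            ]
        )
        exact = align_gold(cands, gold, mode="exact")
        assert not exact.lm.any()
        assert cands.alignment.matched_gold_entities == 0
        overlap = align_gold(cands, gold, mode="overlap")
        assert overlap.lm.tolist() == [0, 1]

    def test_one_gold_relation_among_many_candidates(self):
        # two bacteria x two habitats -> four relation candidates, one gold
        doc = make_doc(
            "d",
            [[("Listeria", "listeria", "NNP", None, "root", "Organism"),
              ("and", "and", "CC", 0, "cc"),
              ("Bacillus", "bacillus", "NNP", 0, "conj", "Organism"),
              ("in", "in", "IN", 0, "case"),
              ("soil", "soil", "NN", 0, "nmod", "Habitat"),
              ("or", "or", "CC", 0, "cc"),
              ("milk", "milk", "NN", 0, "conj", "Habitat")]],
        )
        ont = HabitatOntology([OntologyNode("O1", "soil"), OntologyNode("O2", "milk")])
        tax = TaxonomyLexicon(["Listeria", "Bacillus"])
        chunks = gold_spans = [
            TextSpan(doc.text.index(w), doc.text.index(w) + len(w))
            for w in ("Listeria", "Bacillus", "soil", "milk")
        ]
        cands = build_candidate_set(doc, chunks, ont, tax)
        assert len(cands.relations) == 4
        gold = AnnotationSet(
            entities=[
                EntityAnnotation("T1", "Bacterium", (gold_spans[0],), "Listeria"),
                EntityAnnotation("T2", "Bacterium", (gold_spans[1],), "Bacillus"),
                EntityAnnotation("T3", "Habitat", (gold_spans[2],), "soil"),
                EntityAnnotation("T4", "Habitat", (gold_spans[3],), "milk"),
            ],
            relations=[RelationAnnotation("R1", "Localization", "T2", "T4")],
        )
        y = align_gold(cands, gold)
        assert y.loc.sum() == 1
        (i,) = [i for i in range(4) if y.loc[i]]
        assert cands.relations[i].bacterium.mention(doc) == "Bacillus"
        assert cands.relations[i].habitat.mention(doc) == "milk"

    def test_candidate_matching_two_types_is_ambiguous(self, one_sentence_doc):
        ont = HabitatOntology([OntologyNode("O1", "longum")])
        tax = TaxonomyLexicon(["Bifidobacterium longum"])
        cands = build_candidate_set(one_sentence_doc, [TextSpan(0, 22)], ont, tax)
        gold = AnnotationSet(
            entities=[
                EntityAnnotation("T1", "Bacterium", (TextSpan(0, 22),), "Bifidobacterium longum"),
                EntityAnnotation("T2", "Habitat", (TextSpan(0, 22),), "Bifidobacterium longum"),
            ]
        )
        with pytest.raises(AlignmentAmbiguityError):
            align_gold(cands, gold)


class TestOnSyntheticCorpus:
    def test_gold_alignment_is_always_feasible(self):
        corpus, ont, tax = generate_corpus(GeneratorConfig(n_docs=6, seed=2, noise=0.2))
        for doc, ann in corpus:
            cands = build_candidate_set(
                doc, gazetteer_chunks(doc, ont, tax), ont, tax
            )
            y = align_gold(cands, ann)
            assert is_feasible(cands, y)

    def test_gazetteer_candidate_recall_is_total_on_clean_corpus(self):
        corpus, ont, tax = generate_corpus(GeneratorConfig(n_docs=8, seed=4))
        for doc, ann in corpus:
            cands = build_candidate_set(
                doc, gazetteer_chunks(doc, ont, tax), ont, tax
            )
            align_gold(cands, ann)
            assert cands.alignment.entity_recall_ceiling == 1.0
            assert cands.alignment.relation_recall_ceiling == 1.0
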