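"""Feature extraction for the four feature families."""

import math

import pytest

from lalex.candidates import build_candidate_set
from lalex.features import (
    FeatureConfig,
    attach_features,
    pair_features,
    phrase_features,
    relation_pair_features,
    relation_similarity,
    word_features,
)
from lalex.lexicons import (
    HabitatOntology,
    OntologyNode,
    TaxonomyLexicon,
    edit_similarity,
)
from lalex.standoff import TextSpan, Token
from tests.conftest import make_doc


class TestWordFeatures:
    def test_full_enumeration_for_a_constructed_token(self):
        tok = Token(
            span=TextSpan(0, 8), surface="Listeria", lemma="listeria",
            pos="NNP", dep_head=3, dep_rel="nsubj", concept_tag="Organism",
            is_stopword=False,
        )
        assert word_features(tok) == {
            "word:surface=Listeria": 1.0,
            "word:lemma=listeria": 1.0,
            "word:pos=NNP": 1.0,
            "word:deprel=nsubj": 1.0,
            "word:cocoa=Organism": 1.0,
            "word:capital": 1.0,
        }

    def test_lowercase_stopword_token(self):
        tok = Token(span=TextSpan(0, 3), surface="the", lemma="the",
                    pos="DT", is_stopword=True)
        vec = word_features(tok)
        assert "word:capital" not in vec
        assert vec["word:stopword"] == 1.0


class TestPhraseFeatures:
    def test_head_and_nonhead_families(self, one_sentence_doc, tiny_lexicons):
        ont, tax = tiny_lexicons
        cands = build_candidate_set(
            one_sentence_doc, [TextSpan(0, 22), TextSpan(37, 46)], ont, tax
        )
        vec = phrase_features(cands.phrases[0], one_sentence_doc, ont, tax)
        assert vec["phrase:head:word:lemma=longum"] == 1.0
        assert vec["phrase:nhead:word:surface=Bifidobacterium"] == 1.0
        assert vec["phrase:surface=bifidobacterium_longum"] == 1.0
        assert "bias" in vec
        # full taxonomy name -> containment flags on
        assert vec["phrase:tax:overlap"] == 1.0
        assert vec["phrase:tax:contain"] == 1.0

    def test_single_token_phrase_has_no_nonhead_family(self, tiny_lexicons):
        ont, tax = tiny_lexicons
        doc = make_doc("d", [[("human", "human", "NN", None, "root", "Habitat")]])
        cands = build_candidate_set(doc, [TextSpan(0, 5)], ont, tax)
        vec = phrase_features(cands.phrases[0], doc, ont, tax)
        assert not any(k.startswith("phrase:nhead:") for k in vec)
        assert vec["phrase:ont:overlap"] == 1.0


class TestPairFeatures:
    def _two_paragraph_doc(self):
        return make_doc(
            "d",
            [
                [("Listeria", "listeria", "NNP", None, "root", "Organism"),
                 (".", ".", ".", 0, "punct")],
                [("The", "the", "DT", 1, "det"),
                 ("soil", "soil", "NN", None, "root", "Habitat"),
                 (".", ".", ".", 1, "punct")],
            ],
            paragraph_sentence_counts=[1, 1],
        )

    def _cands(self, doc):
        ont = HabitatOntology([OntologyNode("O1", "soil")])
        tax = TaxonomyLexicon(["Listeria"])
        spans = [
            TextSpan(doc.text.index("Listeria"), doc.text.index("Listeria") + 8),
            TextSpan(doc.text.index("soil"), doc.text.index("soil") + 4),
        ]
        return build_candidate_set(doc, spans, ont, tax)

    def test_cross_paragraph_pair_has_no_sentence_features(self):
        doc = self._two_paragraph_doc()
        cands = self._cands(doc)
        vec = pair_features(cands.relations[0], doc)
        assert "pair:same_par" not in vec
        assert "pair:same_sen" not in vec
        assert not any(k.startswith(("pair:verb", "pair:prep", "pair:parse")) for k in vec)
        assert vec["pair:in_title"] == 1.0  # bacterium is the title
        assert vec["pair:heads_lem=listeria_soil"] == 1.0

    def test_verb_and_preposition_between_arguments(self, one_sentence_doc, tiny_lexicons):
        ont, tax = tiny_lexicons
        cands = build_candidate_set(
            one_sentence_doc, [TextSpan(0, 22), TextSpan(37, 46)], ont, tax
        )
        vec = pair_features(cands.relations[0], one_sentence_doc)
        assert vec["pair:verb=colonize"] == 1.0
        assert vec["pair:same_sen"] == 1.0
        assert vec["pair:same_par"] == 1.0
        assert vec["pair:heads_pos=NNP_NN"] == 1.0
        assert "pair:dep_path=^nsubj/vobj" in vec

    def test_closest_verb_to_habitat_wins_ties_leftmost(self):
        doc = make_doc(
            "d",
            [[("Listeria", "listeria", "NNP", 1, "nsubj", "Organism"),
              ("grows", "grow", "VBZ", None, "root"),
              ("and", "and", "CC", 3, "cc"),
              ("colonizes", "colonize", "VBZ", 1, "conj"),
              ("soil", "soil", "NN", 3, "obj", "Habitat")]],
        )
        ont = HabitatOntology([OntologyNode("O1", "soil")])
        tax = TaxonomyLexicon(["Listeria"])
        spans = [TextSpan(0, 8), TextSpan(doc.text.index("soil"), doc.text.index("soil") + 4)]
        cands = build_candidate_set(doc, spans, ont, tax)
        vec = pair_features(cands.relations[0], doc)
        assert "pair:verb=colonize" in vec  # closest to the habitat
        assert "pair:verb=grow" not in vec


class TestRelationPairFeatures:
    def _setup(self):
        doc = make_doc(
            "d",
            [[("Listeria", "listeria", "NNP", 1, "nsubj", "Organism"),
              ("colonizes", "colonize", "VBZ", None, "root"),
              ("soil", "soil", "NN", 1, "obj", "Habitat"),
              ("and", "and", "CC", 4, "cc"),
              ("milk", "milk", "NN", 2, "conj", "Habitat")]],
        )
        ont = HabitatOntology([OntologyNode("O1", "soil"), OntologyNode("O2", "milk")])
        tax = TaxonomyLexicon(["Listeria"])
        spans = [
            TextSpan(0, 8),
            TextSpan(doc.text.index("soil"), doc.text.index("soil") + 4),
            TextSpan(doc.text.index("milk"), doc.text.index("milk") + 4),
        ]
        cands = build_candidate_set(doc, spans, ont, tax)
        return doc, ont, cands

    def test_same_bacterium_indicator(self):
        doc, ont, cands = self._setup()
        (pair,) = cands.relation_pairs
        fcfg = FeatureConfig(relpair_same_b=True, relpair_sim_bh=True)
        vec = relation_pair_features(pair, doc, ont, fcfg=fcfg)
        assert vec["relpair:sameB"] == 1.0

    def test_similarity_is_geometric_mean_of_argument_similarities(self):
        doc, ont, cands = self._setup()
        (pair,) = cands.relation_pairs
        sim = relation_similarity(pair.first, pair.second, doc, ont)
        # same bacterium (sim 1); habitats map to ontology nodes soil vs milk
        expected = math.sqrt(1.0 * edit_similarity("soil", "milk"))
        assert sim == pytest.approx(expected)
        # symmetry
        assert sim == pytest.approx(
            relation_similarity(pair.second, pair.first, doc, ont)
        )

    def test_identical_relations_have_similarity_one(self):
        doc, ont, cands = self._setup()
        r = cands.relations[0]
        assert relation_similarity(r, r, doc, ont) == pytest.approx(1.0)

    def test_zero_bacterium_similarity_zeroes_the_mean(self):
        doc = make_doc(
            "d2",
            [[("Zzz", "zzz", "NNP", 1, "nsubj", "Organism"),
              ("colonizes", "colonize", "VBZ", None, "root"),
              ("soil", "soil", "NN", 1, "obj", "Habitat"),
              ("like", "like", "IN", 5, "case"),
              ("Ycw", "ycw", "NNP", 2, "nmod", "Organism")]],
        )
        ont = HabitatOntology([OntologyNode("O1", "soil")])
        tax = TaxonomyLexicon(["Zzz", "Ycw"])
        spans = [
            TextSpan(0, 3),
            TextSpan(doc.text.index("soil"), doc.text.index("soil") + 4),
            TextSpan(doc.text.index("Ycw"), doc.text.index("Ycw") + 3),
        ]
        cands = build_candidate_set(doc, spans, ont, tax)
        r1, r2 = cands.relations  # (Zzz, soil) and (Ycw, soil)
        assert edit_similarity("zzz", "ycw") == 0.0
        assert relation_similarity(r1, r2, doc, ont) == 0.0

    def test_extraction_is_pure(self, one_sentence_doc, tiny_lexicons):
        ont, tax = tiny_lexicons
        cands = build_candidate_set(
            one_sentence_doc, [TextSpan(0, 22), TextSpan(37, 46)], ont, tax
        )
        fcfg = FeatureConfig(relpair_same_b=True, relpair_sim_bh=True)
        attach_features(cands, ont, tax, fcfg=fcfg)
        first = ([dict(v) for v in cands.phi_phrase], [dict(v) for v in cands.phi_pair])
        attach_features(cands, ont, tax, fcfg=fcfg)
        assert ([dict(v) for v in cands.phi_phrase], [dict(v) for v in cands.phi_pair]) == first

    def test_indicator_values_are_unit_and_sim_bounded(self):
        doc, ont, cands = self._setup()
        tax = TaxonomyLexicon(["Listeria"])
        fcfg = FeatureConfig(relpair_same_b=True, relpair_sim_bh=True)
        attach_features(cands, ont, tax, fcfg=fcfg)
        for vec in cands.phi_phrase + cands.phi_pair + cands.phi_rr:
            for name, value in vec.items():
                if name in ("relpair:simBH", "pair:parse_dis"):
                    assert 0.0 <= value <= 1.0
                else:
                    assert value == 1.0
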