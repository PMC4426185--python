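"""Sparse feature vectors for the four feature families.

Word features describe single tokens (surface, lemma, POS, dependency
relation, concept tag, capitalization, stopword membership).  Phrase features
combine the head token's word features, the remaining tokens' word features,
the concatenated surface, a phrasal POS tag and lexicon overlap flags against
the bacterium taxonomy and the habitat ontology.  Phrase-pair features
describe a candidate relation (discourse position, the verb or preposition
between the arguments, syntactic paths, head lemma/POS conjunctions).
Relation-pair features compare two chained relations (shared bacterium
candidate, argument-similarity score).

All indicator features have value 1.0; the relation similarity (``simBH``) is
the only real-valued family.  Extraction is a pure function of (document,
candidate, lexicons, config).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional

from .candidates import CandidateSet, PhraseCandidate, RelationCandidate, RelationPairCandidate
from .lexicons import (
    HabitatOntology,
    NormalizationConfig,
    TaxonomyLexicon,
    best_ontology_match,
    edit_similarity,
    lexicon_overlap_flags,
    normalize_bacterium_name,
    normalize_habitat_phrase,
)
from .standoff import Document, Token

FeatureVector = dict[str, float]


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families are enabled.

    ``relpair_same_b`` / ``relpair_sim_bh`` control the two relation-pair
    features (needed only by the rr template).  When no constituency parse is
    available, ``parse_fallback`` replaces the parse-tree distance by a
    token distance normalized by sentence length and the parse path by the POS
    sequence between the arguments.  ``hashing_dim`` optionally hashes feature
    names into a fixed number of buckets (off by default for determinism of
    feature names).
    """

    word: bool = True
    phrase: bool = True
    pair: bool = True
    relpair_same_b: bool = False
    relpair_sim_bh: bool = False
    parse_fallback: bool = True
    hashing_dim: Optional[int] = None


def _hashed(vec: FeatureVector, dim: Optional[int]) -> FeatureVector:
    if not dim:
        return vec
    out: FeatureVector = {}
    for name, val in vec.items():
        key = f"h{zlib.crc32(name.encode()) % dim}"
        out[key] = out.get(key, 0.0) + val
    return out


def word_features(tok: Token) -> FeatureVector:
    """Indicator features of a single token."""
    vec: FeatureVector = {
        f"word:surface={tok.surface}": 1.0,
        f"word:lemma={tok.lemma}": 1.0,
    }
    if tok.pos:
        vec[f"word:pos={tok.pos}"] = 1.0
    if tok.dep_rel:
        vec[f"word:deprel={tok.dep_rel}"] = 1.0
    if tok.concept_tag:
        vec[f"word:cocoa={tok.concept_tag}"] = 1.0
    if tok.is_capitalized:
        vec["word:capital"] = 1.0
    if tok.is_stopword:
        vec["word:stopword"] = 1.0
    return vec


def phrase_features(
    p: PhraseCandidate,
    doc: Document,
    ont: HabitatOntology,
    tax: TaxonomyLexicon,
    ncfg: NormalizationConfig = NormalizationConfig(),
    fcfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    vec: FeatureVector = {"bias": 1.0}
    tokens = [doc.tokens[i] for i in p.token_indices]
    head = doc.tokens[p.head_index]
    if fcfg.word:
        for name in word_features(head):
            vec[f"phrase:head:{name}"] = 1.0
        for i in p.token_indices:
            if i == p.head_index:
                continue
            for name in word_features(doc.tokens[i]):
                vec[f"phrase:nhead:{name}"] = 1.0
    surface = "_".join(t.surface for t in tokens)
    vec[f"phrase:surface={surface.lower()}"] = 1.0
    vec[f"phrase:pos_seq={'-'.join(t.pos for t in tokens)}"] = 1.0
    raw = " ".join(t.surface for t in tokens)
    tax_tokens = normalize_bacterium_name(raw, ncfg).split()
    for flag, name in zip(
        lexicon_overlap_flags(tax_tokens, tax),
        ("overlap", "contain", "inv_contain"),
    ):
        if flag:
            vec[f"phrase:tax:{name}"] = 1.0
    ont_tokens = normalize_habitat_phrase(raw, ncfg).split()
    for flag, name in zip(
        lexicon_overlap_flags(ont_tokens, ont),
        ("overlap", "contain", "inv_contain"),
    ):
        if flag:
            vec[f"phrase:ont:{name}"] = 1.0
    return _hashed(vec, fcfg.hashing_dim)


def _between_token_range(doc: Document, a: PhraseCandidate, b: PhraseCandidate) -> range:
    left, right = (a, b) if a.span.start <= b.span.start else (b, a)
    return range(left.token_indices[-1] + 1, right.token_indices[0])


def _closest_to(doc: Document, indices: list[int], target: PhraseCandidate) -> int:
    """Token index minimizing distance to the target phrase; ties -> leftmost."""
    t0, t1 = target.token_indices[0], target.token_indices[-1]

    def dist(i: int) -> int:
        if i < t0:
            return t0 - i
        if i > t1:
            return i - t1
        return 0

    return min(indices, key=lambda i: (dist(i), i))


def _dep_path(doc: Document, a: int, b: int) -> Optional[str]:
    """Dependency-relation path between two token indices (same sentence)."""

    def ancestors(i: int) -> list[int]:
        chain = [i]
        seen = {i}
        while doc.tokens[chain[-1]].dep_head is not None:
            h = doc.tokens[chain[-1]].dep_head
            if h in seen:  # defensive: cyclic layer
                return chain
            chain.append(h)
            seen.add(h)
        return chain

    ca, cb = ancestors(a), ancestors(b)
    common = set(ca) & set(cb)
    if not common:
        return None
    lca = next(i for i in ca if i in set(cb))
    up = [doc.tokens[i].dep_rel or "dep" for i in ca[: ca.index(lca)]]
    down = [doc.tokens[i].dep_rel or "dep" for i in cb[: cb.index(lca)]]
    return "/".join([f"^{r}" for r in up] + [f"v{r}" for r in reversed(down)])


def pair_features(
    r: RelationCandidate,
    doc: Document,
    fcfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Features of a (bacterium candidate, habitat candidate) pair."""
    vec: FeatureVector = {"bias": 1.0}
    b, h = r.bacterium, r.habitat
    pb, ph = doc.paragraph_index_of(b.span), doc.paragraph_index_of(h.span)
    sb, sh = doc.sentence_index_of(b.span), doc.sentence_index_of(h.span)
    same_par = pb is not None and pb == ph
    same_sen = sb is not None and sb == sh
    if same_par:
        vec["pair:same_par"] = 1.0
    if same_sen:
        vec["pair:same_sen"] = 1.0
    if doc.title_span is not None and doc.title_span.contains(b.span):
        vec["pair:in_title"] = 1.0
    head_b, head_h = doc.tokens[b.head_index], doc.tokens[h.head_index]
    vec[f"pair:heads_lem={head_b.lemma}_{head_h.lemma}"] = 1.0
    vec[f"pair:heads_pos={head_b.pos}_{head_h.pos}"] = 1.0
    if same_sen:
        between = list(_between_token_range(doc, b, h))
        verbs = [i for i in between if doc.tokens[i].pos.startswith("V")]
        if verbs:
            vec[f"pair:verb={doc.tokens[_closest_to(doc, verbs, h)].lemma}"] = 1.0
        preps = [i for i in between if doc.tokens[i].pos == "IN"]
        if preps:
            vec[f"pair:prep={doc.tokens[_closest_to(doc, preps, h)].lemma}"] = 1.0
        if fcfg.parse_fallback:
            sent = doc.sentence_spans[sb]
            n_sent_tokens = max(1, len(doc.token_indices_in(sent)))
            vec["pair:parse_dis"] = len(between) / n_sent_tokens
            pos_path = "-".join(doc.tokens[i].pos for i in between)
            vec[f"pair:parse_path={pos_path}"] = 1.0
        path = _dep_path(doc, b.head_index, h.head_index)
        if path is not None:
            vec[f"pair:dep_path={path}"] = 1.0
    return _hashed(vec, fcfg.hashing_dim)


def relation_similarity(
    r1: RelationCandidate,
    r2: RelationCandidate,
    doc: Document,
    ont: HabitatOntology,
    ncfg: NormalizationConfig = NormalizationConfig(),
) -> float:
    """Geometric mean of bacterium- and habitat-argument similarities.

    Bacterium similarity is the normalized edit similarity of the normalized
    bacterium mentions.  Each habitat argument is represented by the name of
    its best-matching ontology node (falling back to the normalized surface
    phrase when the ontology offers no match); habitat similarity is the edit
    similarity of the two representatives.
    """
    b1 = normalize_bacterium_name(r1.bacterium.mention(doc), ncfg)
    b2 = normalize_bacterium_name(r2.bacterium.mention(doc), ncfg)
    bact_sim = edit_similarity(b1, b2)
    if bact_sim == 0.0:
        return 0.0

    def habitat_rep(rel: RelationCandidate) -> str:
        phrase = normalize_habitat_phrase(rel.habitat.mention(doc), ncfg)
        node_id, sim = best_ontology_match(phrase, ont, ncfg)
        if node_id is None or sim == 0.0:
            return phrase
        name = ont.nodes[node_id].name
        return name.lower() if ncfg.case_fold else name

    hab_sim = edit_similarity(habitat_rep(r1), habitat_rep(r2))
    return math.sqrt(bact_sim * hab_sim)


def relation_pair_features(
    rp: RelationPairCandidate,
    doc: Document,
    ont: HabitatOntology,
    ncfg: NormalizationConfig = NormalizationConfig(),
    fcfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    vec: FeatureVector = {"bias": 1.0}
    if fcfg.relpair_same_b and rp.first.bacterium is rp.second.bacterium:
        vec["relpair:sameB"] = 1.0
    if fcfg.relpair_sim_bh:
        sim = relation_similarity(rp.first, rp.second, doc, ont, ncfg)
        if sim > 0.0:
            vec["relpair:simBH"] = sim
    return _hashed(vec, fcfg.hashing_dim)


def attach_features(
    cands: CandidateSet,
    ont: HabitatOntology,
    tax: TaxonomyLexicon,
    ncfg: NormalizationConfig = NormalizationConfig(),
    fcfg: FeatureConfig = FeatureConfig(),
) -> CandidateSet:
    """Compute and cache the per-candidate feature vectors on a candidate set."""
    doc = cands.doc
    cands.phi_phrase = [
        phrase_features(p, doc, ont, tax, ncfg, fcfg) for p in cands.phrases
    ]
    cands.phi_pair = [pair_features(r, doc, fcfg) for r in cands.relations]
    if fcfg.relpair_same_b or fcfg.relpair_sim_bh:
        cands.phi_rr = [
            relation_pair_features(rp, doc, ont, ncfg, fcfg)
            for rp in cands.relation_pairs
        ]
    else:
        cands.phi_rr = None
    return cands
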