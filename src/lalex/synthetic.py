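"""Synthetic corpus generator.

Emulates the structure of a bacteria-biotope corpus at desk scale: each
document has a title (usually naming the document's main bacterium), a title
paragraph whose habitat mentions are all related to that bacterium across
sentence boundaries, and a body paragraph mixing intra-sentence relation
sentences ("<Bacterium> colonizes the <habitat> ."), neutral co-occurrence
sentences, distractor habitat mentions with no relation, and filler.  All
mentions are drawn from a generated habitat lexicon and bacterium taxonomy,
so gazetteer chunking recovers every gold mention; bacterium surface forms
occasionally insert strain markers ("str.", "subsp.") so that name
normalization is exercised.

Generation is template-based, which keeps the linguistic layers (lemma, POS,
dependency heads, concept tags) self-consistent and makes the gold labeling
the exact argmax of the scoring objective under the planted weights, with a
margin of at least 1 (rr variables excepted, see :func:`planted_weights`).
The ``noise`` knob flips gold relation labels and is the only source of
inconsistency between features and labels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .lexicons import (
    DEFAULT_HABITAT_STOPWORDS,
    HabitatOntology,
    NormalizationConfig,
    OntologyNode,
    TaxonomyLexicon,
)
from .model import WeightVector
from .standoff import (
    AnnotationSet,
    Corpus,
    Document,
    EntityAnnotation,
    RelationAnnotation,
    TextSpan,
    Token,
)

_GENERA = (
    "Bacillus", "Clostridium", "Lactobacillus", "Streptococcus",
    "Bifidobacterium", "Pseudomonas", "Vibrio", "Listeria", "Salmonella",
    "Helicobacter", "Campylobacter", "Staphylococcus", "Enterococcus",
    "Acinetobacter",
)
_SPECIES = (
    "longum", "cereus", "pylori", "acidophilus", "jejuni", "subtilis",
    "casei", "enterica", "aureus", "fragilis", "plantarum", "cholerae",
    "faecalis", "monocytogenes",
)
_HAB_NOUNS = (
    "gut", "soil", "milk", "cheese", "skin", "lung", "rumen", "mucosa",
    "sediment", "silage", "wound", "saliva",
)
_HAB_MODIFIERS = (
    "human", "bovine", "infant", "marine", "fermented", "raw", "adult",
    "dairy", "forest", "acidic", "porcine", "nasal",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Per body sentence, a type is drawn: an intra-sentence relation sentence
    with probability ``p_intra_sentence_relation``; a habitat-only sentence in
    the title paragraph, cross-linked to the title bacterium, with probability
    ``p_cross_sentence_relation`` (when the title names no bacterium this
    draw falls back to an intra-sentence relation, so habitats never end up
    silently unrelated); a distractor mention (a lexicon habitat with no
    relation, half the time co-occurring with a bacterium under a neutral
    verb) with probability ``p_distractor_mention``; otherwise filler with no
    lexicon mention.  ``noise`` is the probability of flipping a gold
    relation label after generation.
    """

    n_docs: int = 50
    sentences_per_doc: tuple[int, int] = (4, 8)
    n_bacteria_names: int = 12
    n_habitat_terms: int = 15
    p_title_bacterium: float = 0.9
    p_intra_sentence_relation: float = 0.4
    p_cross_sentence_relation: float = 0.3
    p_distractor_mention: float = 0.15
    p_strain_variant: float = 0.3
    p_other_bacterium: float = 0.3
    localization_verbs: tuple[str, ...] = ("colonize", "infect", "populate", "inhabit")
    neutral_verbs: tuple[str, ...] = ("resemble", "precede", "accompany")
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.p_title_bacterium, self.p_intra_sentence_relation,
            self.p_cross_sentence_relation, self.p_distractor_mention,
            self.noise,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if (
            self.p_intra_sentence_relation
            + self.p_cross_sentence_relation
            + self.p_distractor_mention
            > 1.0
        ):
            raise ValueError("sentence-type probabilities sum above 1")
        if self.n_bacteria_names < 1 or self.n_habitat_terms < 1:
            raise ValueError("lexicon sizes must be at least 1")


# ---------------------------------------------------------------------------
# lexicons
# ---------------------------------------------------------------------------

@dataclass
class _Bacterium:
    name: str  # "Genus species"
    strain: str  # strain code, e.g. "NC270"


def generate_lexicons(
    cfg: GeneratorConfig, rng: random.Random
) -> tuple[HabitatOntology, TaxonomyLexicon, list[_Bacterium], list[str]]:
    combos = [(g, s) for g in _GENERA for s in _SPECIES]
    picks = rng.sample(combos, min(cfg.n_bacteria_names, len(combos)))
    bacteria = []
    for g, s in picks:
        strain = "".join(rng.choices("ABCDEFGHJK", k=2)) + str(rng.randint(100, 999))
        bacteria.append(_Bacterium(name=f"{g} {s}", strain=strain))
    tax_names = [b.name for b in bacteria] + [f"{b.name} {b.strain}" for b in bacteria]

    terms: list[str] = list(_HAB_NOUNS)
    terms += [f"{m} {n}" for m in _HAB_MODIFIERS for n in _HAB_NOUNS]
    habitat_terms = rng.sample(terms, min(cfg.n_habitat_terms, len(terms)))
    nodes = []
    for i, term in enumerate(sorted(habitat_terms), start=1):
        syns = {f"{term} environment"} if rng.random() < 0.4 else set()
        rels = {f"{term} site"} if rng.random() < 0.2 else set()
        nodes.append(OntologyNode(f"OBT:{i:06d}", term, syns, rels))
    ont = HabitatOntology(nodes)
    tax = TaxonomyLexicon(tax_names, NormalizationConfig())
    return ont, tax, bacteria, habitat_terms


# ---------------------------------------------------------------------------
# sentence templates
# ---------------------------------------------------------------------------

@dataclass
class _Tok:
    surface: str
    lemma: str
    pos: str
    head: Optional[int]  # within-sentence index, None = root
    deprel: str
    concept: Optional[str] = None


@dataclass
class _Sentence:
    tokens: list[_Tok]
    # mentions as (etype, first token idx, last token idx) within the sentence
    mentions: list[tuple[str, int, int]] = field(default_factory=list)


def _bacterium_tokens(b: _Bacterium, rng: random.Random, cfg: GeneratorConfig) -> list[str]:
    parts = b.name.split()
    if rng.random() < cfg.p_strain_variant:
        marker = rng.choice(("str.", "subsp."))
        parts = parts + [marker, b.strain]
    return parts


def _mention_toks(surfaces: Sequence[str], etype: str) -> list[_Tok]:
    """Tokens of one mention; heads are filled in by the caller."""
    toks = []
    last = len(surfaces) - 1
    for i, s in enumerate(surfaces):
        if etype == "Bacterium":
            pos, concept = "NNP", "Organism"
            deprel = "compound" if i < last else "nsubj"
        else:
            pos = "JJ" if i < last else "NN"
            concept = "Habitat"
            deprel = "amod" if i < last else "obj"
        toks.append(_Tok(s, s.lower(), pos, None, deprel, concept))
    return toks


def _sent_title_bacterium(b: _Bacterium, rng: random.Random, cfg: GeneratorConfig) -> _Sentence:
    toks = _mention_toks(_bacterium_tokens(b, rng, cfg), "Bacterium")
    last = len(toks) - 1
    for i, t in enumerate(toks):
        t.head = last if i < last else None
    toks[last].deprel = "root"
    toks.append(_Tok(".", ".", ".", last, "punct"))
    return _Sentence(toks, [("Bacterium", 0, last)])


def _sent_title_plain() -> _Sentence:
    toks = [
        _Tok("Overview", "overview", "NN", None, "root"),
        _Tok(".", ".", ".", 0, "punct"),
    ]
    return _Sentence(toks, [])


def _sent_verb_pair(
    b: _Bacterium, verb: str, habitat: str, rng: random.Random, cfg: GeneratorConfig
) -> _Sentence:
    toks: list[_Tok] = []
    b_toks = _mention_toks(_bacterium_tokens(b, rng, cfg), "Bacterium")
    b_last = len(b_toks) - 1
    toks.extend(b_toks)
    v_idx = len(toks)
    toks.append(_Tok(verb + "s", verb, "VBZ", None, "root"))
    for i, t in enumerate(b_toks):
        t.head = b_last if i < b_last else v_idx
    det_idx = len(toks)
    toks.append(_Tok("the", "the", "DT", None, "det"))
    h_toks = _mention_toks(habitat.split(), "Habitat")
    h_first = len(toks)
    h_last = h_first + len(h_toks) - 1
    toks.extend(h_toks)
    for i, t in enumerate(h_toks):
        t.head = h_last if i < len(h_toks) - 1 else v_idx
    toks[det_idx].head = h_last
    toks.append(_Tok(".", ".", ".", v_idx, "punct"))
    return _Sentence(
        toks,
        [("Bacterium", 0, b_last), ("Habitat", h_first, h_last)],
    )


def _sent_cross_habitat(habitat: str) -> _Sentence:
    toks: list[_Tok] = [_Tok("The", "the", "DT", None, "det")]
    h_toks = _mention_toks(habitat.split(), "Habitat")
    h_first = 1
    h_last = h_first + len(h_toks) - 1
    toks.extend(h_toks)
    root_idx = h_last + 2  # after "was"
    for i, t in enumerate(h_toks):
        t.head = h_last if i < len(h_toks) - 1 else root_idx
    h_toks[-1].deprel = "nsubj:pass"
    toks[0].head = h_last
    toks.append(_Tok("was", "be", "VBD", root_idx, "aux:pass"))
    toks.append(_Tok("sampled", "sample", "VBN", None, "root"))
    toks.append(_Tok(".", ".", ".", root_idx, "punct"))
    return _Sentence(toks, [("Habitat", h_first, h_last)])


def _sent_distractor_habitat(habitat: str) -> _Sentence:
    toks: list[_Tok] = [
        _Tok("Researchers", "researcher", "NNS", 1, "nsubj"),
        _Tok("examined", "examine", "VBD", None, "root"),
        _Tok("the", "the", "DT", None, "det"),
    ]
    h_toks = _mention_toks(habitat.split(), "Habitat")
    h_first = 3
    h_last = h_first + len(h_toks) - 1
    toks.extend(h_toks)
    for i, t in enumerate(h_toks):
        t.head = h_last if i < len(h_toks) - 1 else 1
    toks[2].head = h_last
    toks.append(_Tok(".", ".", ".", 1, "punct"))
    return _Sentence(toks, [("Habitat", h_first, h_last)])


def _sent_filler() -> _Sentence:
    toks = [
        _Tok("The", "the", "DT", 1, "det"),
        _Tok("results", "result", "NNS", 3, "nsubj:pass"),
        _Tok("were", "be", "VBD", 3, "aux:pass"),
        _Tok("reported", "report", "VBN", None, "root"),
        _Tok(".", ".", ".", 3, "punct"),
    ]
    return _Sentence(toks, [])


# ---------------------------------------------------------------------------
# document assembly
# ---------------------------------------------------------------------------

_TITLE_KEY = -1  # sentence key of the title in mention references


def _pick_bacterium(
    main: _Bacterium, all_b: list[_Bacterium], rng: random.Random, cfg: GeneratorConfig
) -> _Bacterium:
    if len(all_b) > 1 and rng.random() < cfg.p_other_bacterium:
        return rng.choice([b for b in all_b if b is not main])
    return main


def _generate_document(
    doc_id: str,
    cfg: GeneratorConfig,
    rng: random.Random,
    bacteria: list[_Bacterium],
    habitats: list[str],
) -> tuple[Document, AnnotationSet]:
    main = rng.choice(bacteria)
    has_title_bact = rng.random() < cfg.p_title_bacterium
    title = (
        _sent_title_bacterium(main, rng, cfg) if has_title_bact else _sent_title_plain()
    )

    body: list[tuple[_Sentence, int]] = []  # (sentence, paragraph 1|2)
    # planted relations as ((sent key, mention idx), (sent key, mention idx));
    # sent key: _TITLE_KEY for the title, else index into `body`
    planted: list[tuple[tuple[int, int], tuple[int, int]]] = []

    p_intra = cfg.p_intra_sentence_relation
    p_cross = cfg.p_cross_sentence_relation
    p_dist = cfg.p_distractor_mention
    for _ in range(rng.randint(*cfg.sentences_per_doc)):
        r = rng.random()
        habitat = rng.choice(habitats)
        if r < p_intra or (r < p_intra + p_cross and not has_title_bact):
            b = _pick_bacterium(main, bacteria, rng, cfg)
            verb = rng.choice(cfg.localization_verbs)
            body.append((_sent_verb_pair(b, verb, habitat, rng, cfg), 2))
            key = len(body) - 1
            planted.append(((key, 0), (key, 1)))
        elif r < p_intra + p_cross:
            body.append((_sent_cross_habitat(habitat), 1))
            planted.append(((_TITLE_KEY, 0), (len(body) - 1, 0)))
        elif r < p_intra + p_cross + p_dist:
            if rng.random() < 0.5:
                body.append((_sent_distractor_habitat(habitat), 2))
            else:
                b = _pick_bacterium(main, bacteria, rng, cfg)
                verb = rng.choice(cfg.neutral_verbs)
                body.append((_sent_verb_pair(b, verb, habitat, rng, cfg), 2))
        else:
            body.append((_sent_filler(), 2))

    final_order = [i for i, (_, p) in enumerate(body) if p == 1] + [
        i for i, (_, p) in enumerate(body) if p == 2
    ]
    n_para1 = 1 + sum(1 for _, p in body if p == 1)
    all_sents: list[tuple[int, _Sentence]] = [(_TITLE_KEY, title)] + [
        (i, body[i][0]) for i in final_order
    ]
    para_of_sent = [0 if j < n_para1 else 1 for j in range(len(all_sents))]

    # lay out text, tokens, sentence spans and mention spans
    text_parts: list[str] = []
    tokens: list[Token] = []
    sentence_spans: list[TextSpan] = []
    mention_records: list[tuple[str, TextSpan]] = []
    mention_pos: dict[tuple[int, int], int] = {}
    offset = 0
    for j, (key, sent) in enumerate(all_sents):
        if j > 0:
            sep = "\n\n" if para_of_sent[j] != para_of_sent[j - 1] else " "
            text_parts.append(sep)
            offset += len(sep)
        sent_start = offset
        base = len(tokens)
        tok_spans: list[TextSpan] = []
        for t_idx, tok in enumerate(sent.tokens):
            if t_idx > 0:
                text_parts.append(" ")
                offset += 1
            span = TextSpan(offset, offset + len(tok.surface))
            text_parts.append(tok.surface)
            offset += len(tok.surface)
            tok_spans.append(span)
            tokens.append(
                Token(
                    span=span,
                    surface=tok.surface,
                    lemma=tok.lemma,
                    pos=tok.pos,
                    dep_head=None if tok.head is None else base + tok.head,
                    dep_rel=tok.deprel,
                    concept_tag=tok.concept,
                    is_stopword=tok.surface.lower() in DEFAULT_HABITAT_STOPWORDS,
                )
            )
        sentence_spans.append(TextSpan(sent_start, offset))
        for m_idx, (etype, first, last) in enumerate(sent.mentions):
            mention_pos[(key, m_idx)] = len(mention_records)
            mention_records.append(
                (etype, TextSpan(tok_spans[first].start, tok_spans[last].end))
            )

    text = "".join(text_parts)
    paragraph_spans = [TextSpan(sentence_spans[0].start, sentence_spans[n_para1 - 1].end)]
    if n_para1 < len(all_sents):
        paragraph_spans.append(
            TextSpan(sentence_spans[n_para1].start, sentence_spans[-1].end)
        )
    doc = Document(
        id=doc_id,
        text=text,
        tokens=tokens,
        sentence_spans=sentence_spans,
        paragraph_spans=paragraph_spans,
        title_span=sentence_spans[0],
    )
    doc.validate()

    entities = [
        EntityAnnotation(f"T{i + 1}", etype, (span,), text[span.start:span.end])
        for i, (etype, span) in enumerate(mention_records)
    ]
    rel_pairs = [
        (mention_pos[b_ref], mention_pos[h_ref]) for b_ref, h_ref in planted
    ]

    if cfg.noise > 0:
        kept = [p for p in rel_pairs if rng.random() >= cfg.noise]
        present = set(kept)
        b_idx = [i for i, e in enumerate(entities) if e.etype == "Bacterium"]
        h_idx = [i for i, e in enumerate(entities) if e.etype == "Habitat"]
        for bi in b_idx:
            for hi in h_idx:
                if (bi, hi) not in present and rng.random() < cfg.noise:
                    kept.append((bi, hi))
                    present.add((bi, hi))
        rel_pairs = kept

    relations = []
    seen: set[tuple[int, int]] = set()
    for bi, hi in rel_pairs:
        if (bi, hi) in seen:
            continue
        seen.add((bi, hi))
        relations.append(
            RelationAnnotation(
                f"R{len(relations) + 1}",
                "Localization",
                entities[bi].id,
                entities[hi].id,
            )
        )
    ann = AnnotationSet(entities, relations)
    ann.validate()
    return doc, ann


def generate_corpus(
    cfg: GeneratorConfig,
) -> tuple[Corpus, HabitatOntology, TaxonomyLexicon]:
    """Generate a corpus plus matching lexicons, reproducibly from the seed."""
    rng = random.Random(cfg.seed)
    ont, tax, bacteria, habitats = generate_lexicons(cfg, rng)
    items = []
    for d in range(cfg.n_docs):
        doc, ann = _generate_document(f"synth{d:04d}", cfg, rng, bacteria, habitats)
        items.append((doc, ann))
    return Corpus(items), ont, tax


def planted_weights(cfg: GeneratorConfig) -> WeightVector:
    """Oracle weights under which the generating rule is the score argmax.

    With the generator's zero-noise output, the gold assignment maximizes the
    objective with a margin of at least 1 over every other feasible
    assignment when the rr template is disabled: entity labels are carried by
    the lexicon-overlap flags (gap 2), intra-sentence relations by the
    localization-verb indicator (coefficient +1 vs 0 for the no-relation
    label), and cross-sentence relations by same-paragraph plus
    bacterium-in-title (+1 vs at most -1 for unrelated pairs).  The small rr
    bias turns rr on exactly where both chained relations hold; rr-only
    deviations have a gap of 0.25 (a full unit gap on rr would let an rr gain
    outweigh a gold no-relation label).
    """
    w = WeightVector.zeros()
    w["tr"]["phrase:tax:overlap"] = 2.0
    w["lm"]["phrase:ont:overlap"] = 2.0
    w["loc"]["bias"] = -3.0
    w["loc"]["pair:same_par"] = 2.0
    w["loc"]["pair:in_title"] = 2.0
    for v in cfg.localization_verbs:
        w["loc"][f"pair:verb={v}"] = 4.0
    w["rr"]["bias"] = 0.25
    return w
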