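"""Candidate generation: from a document plus lexicons to the label-bearing
input parts of the link-and-label model.

Phrase candidates are contiguous token runs produced by a pluggable chunker;
a chunk sharing a token with the habitat lexicon becomes a habitat (``lm``)
candidate, one sharing a token with the bacterium taxonomy a bacterium
(``tr``) candidate, and every candidate also carries the auxiliary ``nrol``
(no-role) label.  Relation candidates are the cross product of bacterium and
habitat candidates; relation-pair (``rr``) candidates chain each relation
with its successor in the canonical ordering, keeping the pair set linear in
the number of relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .lexicons import (
    HabitatOntology,
    NormalizationConfig,
    TaxonomyLexicon,
    normalize_bacterium_name,
)
from .standoff import (
    AlignmentError,
    AnnotationSet,
    Document,
    EntityAnnotation,
    TextSpan,
)


class AlignmentAmbiguityError(ValueError):
    """A candidate matches gold entities of two different types."""


@dataclass
class PhraseCandidate:
    id: int
    doc_id: str
    token_indices: tuple[int, ...]  # contiguous token index range
    span: TextSpan
    head_index: int
    in_C_tr: bool
    in_C_lm: bool

    def __post_init__(self) -> None:
        if not (self.in_C_tr or self.in_C_lm):
            raise ValueError("phrase candidate must belong to C_tr or C_lm")
        if self.head_index not in self.token_indices:
            raise ValueError("head outside the candidate's tokens")

    def mention(self, doc: Document) -> str:
        return doc.text[self.span.start:self.span.end]


@dataclass
class RelationCandidate:
    id: int
    bacterium: PhraseCandidate
    habitat: PhraseCandidate

    def __post_init__(self) -> None:
        if self.bacterium is self.habitat:
            raise ValueError("relation arguments must differ")
        if not self.bacterium.in_C_tr or not self.habitat.in_C_lm:
            raise ValueError("relation arguments have wrong candidacy")


@dataclass
class RelationPairCandidate:
    id: int
    first: RelationCandidate
    second: RelationCandidate


@dataclass
class LabelAssignment:
    """Binary values for every tr/lm/nrol/loc/nloc/rr variable of a document.

    Entries for labels a candidate is not eligible for (e.g. ``tr`` of a
    habitat-only phrase) are fixed to 0.
    """

    tr: np.ndarray
    lm: np.ndarray
    nrol: np.ndarray
    loc: np.ndarray
    nloc: np.ndarray
    rr: np.ndarray

    @classmethod
    def zeros(cls, cands: "CandidateSet") -> "LabelAssignment":
        n_p, n_r, n_rr = len(cands.phrases), len(cands.relations), len(cands.relation_pairs)
        return cls(*(np.zeros(n, dtype=np.int8) for n in (n_p, n_p, n_p, n_r, n_r, n_rr)))

    def get(self, label_type: str) -> np.ndarray:
        return getattr(self, label_type)

    def copy(self) -> "LabelAssignment":
        return LabelAssignment(*(self.get(t).copy() for t in ("tr", "lm", "nrol", "loc", "nloc", "rr")))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelAssignment):
            return NotImplemented
        return all(
            np.array_equal(self.get(t), other.get(t))
            for t in ("tr", "lm", "nrol", "loc", "nloc", "rr")
        )


@dataclass
class AlignmentReport:
    """Candidate-recall ceiling: gold items no candidate could carry."""

    n_gold_entities: int = 0
    matched_gold_entities: int = 0
    n_gold_relations: int = 0
    matched_gold_relations: int = 0

    @property
    def entity_recall_ceiling(self) -> float:
        if self.n_gold_entities == 0:
            return 1.0
        return self.matched_gold_entities / self.n_gold_entities

    @property
    def relation_recall_ceiling(self) -> float:
        if self.n_gold_relations == 0:
            return 1.0
        return self.matched_gold_relations / self.n_gold_relations


@dataclass
class CandidateSet:
    """The candidate sets C_tr, C_lm, C_nrol, C_loc and C_rr of one document."""

    doc: Document
    phrases: list[PhraseCandidate] = field(default_factory=list)
    relations: list[RelationCandidate] = field(default_factory=list)
    relation_pairs: list[RelationPairCandidate] = field(default_factory=list)
    gold: Optional[LabelAssignment] = None
    alignment: Optional[AlignmentReport] = None
    # feature caches, filled by features.attach_features
    phi_phrase: Optional[list[dict[str, float]]] = None
    phi_pair: Optional[list[dict[str, float]]] = None
    phi_rr: Optional[list[dict[str, float]]] = None

    def members(self, label_type: str) -> np.ndarray:
        """Boolean mask of candidates eligible for a label type."""
        if label_type in ("tr", "lm"):
            flag = "in_C_tr" if label_type == "tr" else "in_C_lm"
            return np.array([getattr(p, flag) for p in self.phrases], dtype=bool)
        if label_type == "nrol":
            return np.ones(len(self.phrases), dtype=bool)
        if label_type in ("loc", "nloc"):
            return np.ones(len(self.relations), dtype=bool)
        if label_type == "rr":
            return np.ones(len(self.relation_pairs), dtype=bool)
        raise KeyError(label_type)


# ---------------------------------------------------------------------------
# chunkers
# ---------------------------------------------------------------------------

def gold_chunks(doc: Document, ann: AnnotationSet) -> list[TextSpan]:
    """Chunks equal to the extents of the gold entities (for controlled tests)."""
    return sorted({e.extent for e in ann.entities}, key=lambda s: (s.start, s.end))


def load_chunk_file(path: str | Path, doc_id: str) -> list[TextSpan]:
    """External chunk file: ``doc_id<TAB>start<TAB>end`` per line."""
    spans = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d, s, e = line.split("\t")
        if d == doc_id:
            spans.append(TextSpan(int(s), int(e)))
    return sorted(spans, key=lambda s: (s.start, s.end))


def gazetteer_chunks(
    doc: Document,
    ont: HabitatOntology,
    tax: TaxonomyLexicon,
    cfg: NormalizationConfig = NormalizationConfig(),
    max_len: int = 8,
) -> list[TextSpan]:
    """Longest-match gazetteer chunking over the two lexicons.

    A token window matches the habitat lexicon when its case-folded token
    sequence equals some ontology term, and the bacterium taxonomy when its
    normalized form (drop tokens removed) equals some taxonomy name.  At each
    position the longest match wins and scanning resumes after it.
    """
    hab_seqs = {tuple(e.split()) for e in ont.entry_strings}
    tax_seqs = {tuple(n.split()) for n in tax.names}
    spans: list[TextSpan] = []
    for sent in doc.sentence_spans or [TextSpan(0, len(doc.text))]:
        idxs = doc.token_indices_in(sent)
        i = 0
        while i < len(idxs):
            best_j = -1
            for j in range(min(len(idxs), i + max_len), i, -1):
                toks = [doc.tokens[idxs[k]].surface for k in range(i, j)]
                folded = tuple(t.lower() for t in toks)
                norm = tuple(normalize_bacterium_name(" ".join(toks), cfg).split())
                if folded in hab_seqs or (norm and norm in tax_seqs):
                    best_j = j
                    break
            if best_j > 0:
                spans.append(
                    TextSpan(
                        doc.tokens[idxs[i]].span.start,
                        doc.tokens[idxs[best_j - 1]].span.end,
                    )
                )
                i = best_j
            else:
                i += 1
    return spans


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------

def generate_entity_candidates(
    doc: Document,
    chunks: Sequence[TextSpan],
    ont: HabitatOntology,
    tax: TaxonomyLexicon,
    cfg: NormalizationConfig = NormalizationConfig(),
) -> list[PhraseCandidate]:
    """Turn token-aligned chunks into phrase candidates.

    A chunk sharing a (case-folded) token with the habitat lexicon index joins
    C_lm, one sharing a normalized token with the taxonomy index joins C_tr;
    chunks overlapping neither lexicon are discarded.  The head is the token
    whose dependency head lies outside the chunk (the syntactic head) when a
    dependency layer is present, otherwise the last token.
    """
    out: list[PhraseCandidate] = []
    for chunk in chunks:
        token_ids = doc.token_indices_in(chunk)
        if not token_ids:
            raise AlignmentError(f"chunk {chunk} covers no token")
        covered = TextSpan(
            doc.tokens[token_ids[0]].span.start, doc.tokens[token_ids[-1]].span.end
        )
        if (covered.start, covered.end) != (chunk.start, chunk.end):
            raise AlignmentError(f"chunk {chunk} not aligned to token boundaries")
        tokens = [doc.tokens[i] for i in token_ids]
        folded = [t.surface.lower() for t in tokens]
        in_lm = any(t in ont.token_index for t in folded)
        norm_toks = normalize_bacterium_name(
            " ".join(t.surface for t in tokens), cfg
        ).split()
        in_tr = any(t in tax.token_index for t in norm_toks)
        if not (in_tr or in_lm):
            continue
        head = token_ids[-1]
        idset = set(token_ids)
        for i in token_ids:
            h = doc.tokens[i].dep_head
            if h is None or h not in idset:
                head = i
                break
        out.append(
            PhraseCandidate(
                id=len(out),
                doc_id=doc.id,
                token_indices=tuple(token_ids),
                span=chunk,
                head_index=head,
                in_C_tr=in_tr,
                in_C_lm=in_lm,
            )
        )
    return out


def generate_relation_candidates(
    phrases: Sequence[PhraseCandidate],
) -> list[RelationCandidate]:
    """Cross product of bacterium and habitat candidates (self-pairs excluded),
    ordered by (bacterium span start, habitat span start)."""
    pairs = [
        (b, h)
        for b in phrases
        if b.in_C_tr
        for h in phrases
        if h.in_C_lm and h is not b
    ]
    pairs.sort(key=lambda bh: (bh[0].span.start, bh[0].span.end,
                               bh[1].span.start, bh[1].span.end))
    return [RelationCandidate(i, b, h) for i, (b, h) in enumerate(pairs)]


def chain_relation_pairs(
    relations: Sequence[RelationCandidate],
) -> list[RelationPairCandidate]:
    """Chain each relation with its successor: (r_i, r_{i+1}) for i = 1..n-1."""
    return [
        RelationPairCandidate(i, relations[i], relations[i + 1])
        for i in range(len(relations) - 1)
    ]


def build_candidate_set(
    doc: Document,
    chunks: Sequence[TextSpan],
    ont: HabitatOntology,
    tax: TaxonomyLexicon,
    cfg: NormalizationConfig = NormalizationConfig(),
) -> CandidateSet:
    phrases = generate_entity_candidates(doc, chunks, ont, tax, cfg)
    relations = generate_relation_candidates(phrases)
    pairs = chain_relation_pairs(relations)
    return CandidateSet(doc=doc, phrases=phrases, relations=relations, relation_pairs=pairs)


# ---------------------------------------------------------------------------
# gold alignment
# ---------------------------------------------------------------------------

def _entity_matches(cand: PhraseCandidate, ent: EntityAnnotation, mode: str) -> bool:
    if mode == "exact":
        return len(ent.spans) == 1 and ent.spans[0] == cand.span
    if mode == "overlap":
        return any(sp.overlaps(cand.span) for sp in ent.spans)
    raise ValueError(f"unknown alignment mode {mode!r}")


def align_gold(
    cands: CandidateSet,
    gold: AnnotationSet,
    mode: str = "exact",
) -> LabelAssignment:
    """Project gold standoff annotations onto the candidate sets.

    ``tr_k = 1`` iff candidate ``k`` matches a gold Bacterium (exact span match
    by default, any-overlap in ``overlap`` mode) and is a bacterium candidate;
    ``lm`` likewise for Habitat; ``nrol = 1 - tr - lm``.  ``loc_ij = 1`` iff
    the two arguments match the two arguments of one gold Localization;
    ``nloc = 1 - loc``; ``rr = 1`` iff both chained relations are gold.  Gold
    items no candidate could carry are counted in ``cands.alignment`` (the
    candidate-recall ceiling).  The result always satisfies the output
    constraints: gold is feasible by construction.
    """
    y = LabelAssignment.zeros(cands)
    matched_as: dict[int, tuple[str, str]] = {}  # cand idx -> (etype, entity id)
    covered_entities: set[str] = set()
    for k, cand in enumerate(cands.phrases):
        hit_b = hit_h = None
        for ent in gold.entities:
            if not _entity_matches(cand, ent, mode):
                continue
            if ent.etype == "Bacterium" and cand.in_C_tr and hit_b is None:
                hit_b = ent
            elif ent.etype == "Habitat" and cand.in_C_lm and hit_h is None:
                hit_h = ent
        if hit_b is not None and hit_h is not None:
            raise AlignmentAmbiguityError(
                f"candidate {cand.span} matches gold entities of both types"
            )
        if hit_b is not None:
            y.tr[k] = 1
            matched_as[k] = ("Bacterium", hit_b.id)
            covered_entities.add(hit_b.id)
        elif hit_h is not None:
            y.lm[k] = 1
            matched_as[k] = ("Habitat", hit_h.id)
            covered_entities.add(hit_h.id)
        else:
            y.nrol[k] = 1
    gold_rels = {(r.bacterium_arg, r.habitat_arg) for r in gold.relations}
    covered_rels: set[tuple[str, str]] = set()
    for i, rel in enumerate(cands.relations):
        b = matched_as.get(rel.bacterium.id)
        h = matched_as.get(rel.habitat.id)
        if (
            b is not None
            and h is not None
            and b[0] == "Bacterium"
            and h[0] == "Habitat"
            and (b[1], h[1]) in gold_rels
        ):
            y.loc[i] = 1
            covered_rels.add((b[1], h[1]))
        else:
            y.nloc[i] = 1
    for j, pair in enumerate(cands.relation_pairs):
        if y.loc[pair.first.id] and y.loc[pair.second.id]:
            y.rr[j] = 1
    cands.alignment = AlignmentReport(
        n_gold_entities=len(gold.entities),
        matched_gold_entities=len(covered_entities),
        n_gold_relations=len(gold.relations),
        matched_gold_relations=len(covered_rels),
    )
    cands.gold = y
    return y
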