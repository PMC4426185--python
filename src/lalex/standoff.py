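"""BioNLP-ST standoff annotations and CoNLL-style linguistic layers.

Documents are plain text; annotations live in companion files that reference
the text by character offsets (0-based, end-exclusive).  ``T`` lines carry
typed entity spans (possibly discontinuous, fragments separated by ``;``),
``R`` lines carry binary typed relations between entities.  A third companion
file holds a token-level linguistic layer (lemma, POS, dependency head and
relation, optional concept tag) in CoNLL-like columns, one sentence per
blank-line-separated block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional


class StandoffParseError(ValueError):
    """Malformed standoff line; carries the 1-based line number."""


class StandoffIntegrityError(ValueError):
    """Annotation inconsistent with the document text or with itself."""


class AlignmentError(ValueError):
    """Linguistic layer cannot be aligned with the document text."""


@dataclass(frozen=True, order=True)
class TextSpan:
    """Half-open character interval ``[start, end)`` into a document."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "TextSpan") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "TextSpan") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class Token:
    """One token of a document with its linguistic annotations.

    ``dep_head`` is a document-global token index (``None`` for the root of a
    sentence); ``concept_tag`` is an optional external concept category.
    """

    span: TextSpan
    surface: str
    lemma: str = ""
    pos: str = ""
    dep_head: Optional[int] = None
    dep_rel: str = ""
    concept_tag: Optional[str] = None
    is_stopword: bool = False

    @property
    def is_capitalized(self) -> bool:
        return bool(self.surface) and self.surface[0].isupper()


@dataclass
class Document:
    """A text with token / sentence / paragraph segmentation."""

    id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    sentence_spans: list[TextSpan] = field(default_factory=list)
    paragraph_spans: list[TextSpan] = field(default_factory=list)
    title_span: Optional[TextSpan] = None

    def sentence_index_of(self, span: TextSpan) -> Optional[int]:
        """Index of the sentence containing ``span`` entirely, or None."""
        for i, s in enumerate(self.sentence_spans):
            if s.contains(span):
                return i
        return None

    def paragraph_index_of(self, span: TextSpan) -> Optional[int]:
        for i, p in enumerate(self.paragraph_spans):
            if p.contains(span):
                return i
        return None

    def token_indices_in(self, span: TextSpan) -> list[int]:
        return [i for i, t in enumerate(self.tokens) if span.contains(t.span)]

    def validate(self) -> None:
        prev_end = -1
        for tok in self.tokens:
            if tok.span.start < prev_end:
                raise StandoffIntegrityError("tokens overlap or are unordered")
            if self.text[tok.span.start:tok.span.end] != tok.surface:
                raise StandoffIntegrityError(
                    f"token surface {tok.surface!r} does not match text"
                )
            prev_end = tok.span.end
            if self.sentence_spans and self.sentence_index_of(tok.span) is None:
                raise StandoffIntegrityError("token outside every sentence")


@dataclass(frozen=True)
class EntityAnnotation:
    id: str
    etype: str  # "Bacterium" | "Habitat"
    spans: tuple[TextSpan, ...]
    mention: str

    @property
    def extent(self) -> TextSpan:
        return TextSpan(self.spans[0].start, self.spans[-1].end)


@dataclass(frozen=True)
class RelationAnnotation:
    id: str
    rtype: str  # "Localization"
    bacterium_arg: str
    habitat_arg: str


@dataclass
class AnnotationSet:
    entities: list[EntityAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)

    def entity_by_id(self, tid: str) -> EntityAnnotation:
        for e in self.entities:
            if e.id == tid:
                return e
        raise KeyError(tid)

    def validate(self) -> None:
        ids = [e.id for e in self.entities]
        if len(ids) != len(set(ids)):
            raise StandoffIntegrityError("duplicate entity ids")
        by_id = {e.id: e for e in self.entities}
        for r in self.relations:
            if r.bacterium_arg not in by_id or r.habitat_arg not in by_id:
                raise StandoffIntegrityError(f"dangling argument in {r.id}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            sorted(self.entities, key=lambda e: _num_id(e.id))
            == sorted(other.entities, key=lambda e: _num_id(e.id))
            and sorted(self.relations, key=lambda r: _num_id(r.id))
            == sorted(other.relations, key=lambda r: _num_id(r.id))
        )


@dataclass
class Corpus:
    """Training pairs of documents and their gold annotation sets."""

    items: list[tuple[Document, AnnotationSet]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.id for d, _ in self.items]
        if len(ids) != len(set(ids)):
            raise StandoffIntegrityError("duplicate document ids in corpus")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[tuple[Document, AnnotationSet]]:
        return iter(self.items)


def _num_id(tid: str) -> int:
    m = re.match(r"[TR](\d+)$", tid)
    if not m:
        raise StandoffParseError(f"malformed identifier {tid!r}")
    return int(m.group(1))


_T_LINE = re.compile(
    r"^(T\d+)\s+(\S+)\s+(\d+\s+\d+(?:\s*;\s*\d+\s+\d+)*)\s+(.*)$"
)
_R_LINE = re.compile(r"^(R\d+)\s+(\S+)\s+(\S+):(T\d+)\s+(\S+):(T\d+)\s*$")

# role names mapped onto argument slots; the corpus reuses the relation name
# "Localization" for the habitat role
_BACT_ROLES = {"Bacterium"}
_HAB_ROLES = {"Habitat", "Localization"}


def _norm_ws(s: str) -> str:
    return " ".join(s.split())


def parse_standoff(text: str, ann_lines: Iterable[str]) -> AnnotationSet:
    """Parse standoff ``T``/``R`` lines against a document text.

    Offsets are 0-based and end-exclusive.  Discontinuous spans (fragments
    separated by ``;``) are kept as multiple :class:`TextSpan` s; the stored
    mention must equal the text over the spans (fragments joined by a single
    space, whitespace-normalized).
    """
    entities: list[EntityAnnotation] = []
    relations: list[RelationAnnotation] = []
    raw_relations: list[tuple[int, str, str, dict[str, str]]] = []
    for lineno, line in enumerate(ann_lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line.replace("\t", " "))
            if not m:
                raise StandoffParseError(f"line {lineno}: malformed T-line")
            tid, etype, span_str, mention = m.groups()
            spans = []
            for frag in span_str.split(";"):
                s, e = frag.split()
                try:
                    spans.append(TextSpan(int(s), int(e)))
                except ValueError as exc:
                    raise StandoffParseError(f"line {lineno}: {exc}") from exc
            for sp in spans:
                if sp.end > len(text):
                    raise StandoffIntegrityError(
                        f"line {lineno}: span {sp} beyond document end"
                    )
            expected = " ".join(_norm_ws(text[sp.start:sp.end]) for sp in spans)
            if _norm_ws(mention) != expected:
                raise StandoffIntegrityError(
                    f"line {lineno}: mention {mention!r} does not match "
                    f"text {expected!r}"
                )
            if etype in _HAB_ROLES:
                etype = "Habitat"
            entities.append(
                EntityAnnotation(tid, etype, tuple(spans), _norm_ws(mention))
            )
        elif line.startswith("R"):
            m = _R_LINE.match(line.replace("\t", " "))
            if not m:
                raise StandoffParseError(f"line {lineno}: malformed R-line")
            rid, rtype, role1, arg1, role2, arg2 = m.groups()
            args: dict[str, str] = {}
            for role, arg in ((role1, arg1), (role2, arg2)):
                if role in _BACT_ROLES:
                    args["bacterium"] = arg
                elif role in _HAB_ROLES:
                    args["habitat"] = arg
                else:
                    raise StandoffParseError(
                        f"line {lineno}: unknown role {role!r}"
                    )
            if set(args) != {"bacterium", "habitat"}:
                raise StandoffParseError(
                    f"line {lineno}: relation needs one bacterium and one "
                    "habitat argument"
                )
            raw_relations.append((lineno, rid, rtype, args))
        else:
            raise StandoffParseError(
                f"line {lineno}: unsupported record {line.split()[0]!r}"
            )
    by_id = {e.id: e for e in entities}
    for lineno, rid, rtype, args in raw_relations:
        for slot, want in (("bacterium", "Bacterium"), ("habitat", "Habitat")):
            ent = by_id.get(args[slot])
            if ent is None:
                raise StandoffIntegrityError(
                    f"line {lineno}: dangling argument {args[slot]}"
                )
            if ent.etype != want:
                raise StandoffIntegrityError(
                    f"line {lineno}: argument {ent.id} has type {ent.etype}, "
                    f"expected {want}"
                )
        relations.append(
            RelationAnnotation(rid, rtype, args["bacterium"], args["habitat"])
        )
    ann = AnnotationSet(entities, relations)
    ann.validate()
    return ann


def serialize_standoff(ann: AnnotationSet) -> list[str]:
    """Canonical tab-separated standoff lines (T before R, numeric id order)."""
    ann.validate()
    lines: list[str] = []
    for e in sorted(ann.entities, key=lambda e: _num_id(e.id)):
        span_str = ";".join(f"{sp.start} {sp.end}" for sp in e.spans)
        lines.append(f"{e.id}\t{e.etype} {span_str}\t{e.mention}")
    for r in sorted(ann.relations, key=lambda r: _num_id(r.id)):
        lines.append(
            f"{r.id}\t{r.rtype} Bacterium:{r.bacterium_arg} "
            f"Localization:{r.habitat_arg}"
        )
    return lines


def canonical_standoff(text: str, ann_lines: Iterable[str]) -> list[str]:
    return serialize_standoff(parse_standoff(text, ann_lines))


@dataclass(frozen=True)
class ConllDialect:
    """Column order and conventions for the linguistic-layer files.

    ``head`` is a 1-based within-sentence index, 0 meaning the sentence root;
    a blank line separates sentences; ``newpar_marker`` (or two consecutive
    blank lines) separates paragraphs; ``_`` is the empty value.
    """

    columns: tuple[str, ...] = (
        "index", "surface", "lemma", "pos", "head", "deprel", "concept",
    )
    empty: str = "_"
    newpar_marker: str = "# newpar"
    comment_prefix: str = "#"


def parse_linguistic_layer(
    lines: Iterable[str],
    doc: Document,
    dialect: ConllDialect = ConllDialect(),
    stopwords: Optional[set[str]] = None,
) -> Document:
    """Attach a CoNLL-style token layer to ``doc`` and return the new document.

    Token surfaces are aligned against the document text left to right; a
    surface that cannot be found in order raises :class:`AlignmentError`.
    Sentence boundaries come from blank lines, paragraph boundaries from the
    ``newpar`` marker or a double blank line.
    """
    stopwords = stopwords or set()
    col = {name: i for i, name in enumerate(dialect.columns)}
    sentences: list[list[list[str]]] = []
    par_breaks: set[int] = set()  # sentence indices that start a new paragraph
    current: list[list[str]] = []
    blank_run = 0
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip():
            blank_run += 1
            if current:
                sentences.append(current)
                current = []
            if blank_run >= 2:
                par_breaks.add(len(sentences))
            continue
        if line.startswith(dialect.comment_prefix):
            if line.strip() == dialect.newpar_marker:
                if current:
                    sentences.append(current)
                    current = []
                par_breaks.add(len(sentences))
            blank_run = 0
            continue
        blank_run = 0
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < len(dialect.columns):
            fields = fields + [dialect.empty] * (len(dialect.columns) - len(fields))
        current.append(fields)
    if current:
        sentences.append(current)

    tokens: list[Token] = []
    sentence_spans: list[TextSpan] = []
    paragraph_sentences: list[list[int]] = []
    cursor = 0
    for s_idx, rows in enumerate(sentences):
        offset = len(tokens)
        sent_tokens: list[Token] = []
        for rows_i, fields in enumerate(rows):
            surface = fields[col["surface"]]
            pos_in_text = doc.text.find(surface, cursor)
            if pos_in_text < 0:
                raise AlignmentError(
                    f"{doc.id}: token {surface!r} not found after offset {cursor}"
                )
            if doc.text[cursor:pos_in_text].strip():
                raise AlignmentError(
                    f"{doc.id}: unaccounted text before token {surface!r}"
                )
            span = TextSpan(pos_in_text, pos_in_text + len(surface))
            cursor = span.end

            def get(name: str) -> str:
                v = fields[col[name]] if name in col else dialect.empty
                return "" if v == dialect.empty else v

            head_raw = get("head")
            if head_raw in ("", "0"):
                dep_head: Optional[int] = None
            else:
                dep_head = offset + int(head_raw) - 1
            sent_tokens.append(
                Token(
                    span=span,
                    surface=surface,
                    lemma=get("lemma") or surface.lower(),
                    pos=get("pos"),
                    dep_head=dep_head,
                    dep_rel=get("deprel"),
                    concept_tag=get("concept") or None,
                    is_stopword=surface.lower() in stopwords,
                )
            )
        tokens.extend(sent_tokens)
        sentence_spans.append(
            TextSpan(sent_tokens[0].span.start, sent_tokens[-1].span.end)
        )
        if s_idx == 0 or s_idx in par_breaks:
            paragraph_sentences.append([s_idx])
        else:
            paragraph_sentences[-1].append(s_idx)
    if doc.text[cursor:].strip():
        raise AlignmentError(f"{doc.id}: trailing text not covered by tokens")

    paragraph_spans = [
        TextSpan(sentence_spans[g[0]].start, sentence_spans[g[-1]].end)
        for g in paragraph_sentences
    ]
    out = replace(
        doc,
        tokens=tokens,
        sentence_spans=sentence_spans,
        paragraph_spans=paragraph_spans,
        title_span=doc.title_span or (sentence_spans[0] if sentence_spans else None),
    )
    out.validate()
    return out


def serialize_linguistic_layer(
    doc: Document, dialect: ConllDialect = ConllDialect()
) -> list[str]:
    """Inverse of :func:`parse_linguistic_layer` for documents with full layers."""
    lines: list[str] = []
    sent_of_token: list[int] = []
    for tok in doc.tokens:
        idx = doc.sentence_index_of(tok.span)
        assert idx is not None
        sent_of_token.append(idx)
    sent_start: dict[int, int] = {}
    for i, s in enumerate(sent_of_token):
        sent_start.setdefault(s, i)
    par_of_sent = [
        doc.paragraph_index_of(sp) for sp in doc.sentence_spans
    ]
    prev_sent = None
    for i, tok in enumerate(doc.tokens):
        s = sent_of_token[i]
        if prev_sent is not None and s != prev_sent:
            lines.append("")
            if par_of_sent[s] != par_of_sent[prev_sent]:
                lines.append(dialect.newpar_marker)
        prev_sent = s
        within = i - sent_start[s] + 1
        if tok.dep_head is None:
            head = "0"
        else:
            head = str(tok.dep_head - sent_start[s] + 1)
        row = {
            "index": str(within),
            "surface": tok.surface,
            "lemma": tok.lemma or dialect.empty,
            "pos": tok.pos or dialect.empty,
            "head": head,
            "deprel": tok.dep_rel or dialect.empty,
            "concept": tok.concept_tag or dialect.empty,
        }
        lines.append("\t".join(row[c] for c in dialect.columns))
    return lines


# ---------------------------------------------------------------------------
# corpus directory layout: one .txt / .ann / .conll triple per document
# ---------------------------------------------------------------------------

def write_corpus_dir(
    corpus: Corpus,
    out_dir: str | Path,
    dialect: ConllDialect = ConllDialect(),
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc, ann in corpus:
        (out / f"{doc.id}.txt").write_text(doc.text)
        (out / f"{doc.id}.ann").write_text(
            "\n".join(serialize_standoff(ann)) + "\n" if ann.entities or ann.relations else ""
        )
        (out / f"{doc.id}.conll").write_text(
            "\n".join(serialize_linguistic_layer(doc, dialect)) + "\n"
        )


def read_corpus_dir(
    in_dir: str | Path,
    dialect: ConllDialect = ConllDialect(),
    stopwords: Optional[set[str]] = None,
) -> Corpus:
    src = Path(in_dir)
    items = []
    for txt in sorted(src.glob("*.txt")):
        doc_id = txt.stem
        text = txt.read_text()
        doc = Document(id=doc_id, text=text)
        conll = src / f"{doc_id}.conll"
        if conll.exists():
            doc = parse_linguistic_layer(
                conll.read_text().splitlines(), doc, dialect, stopwords
            )
        ann_path = src / f"{doc_id}.ann"
        if not ann_path.exists():
            ann_path = src / f"{doc_id}.a2"
        if ann_path.exists():
            ann = parse_standoff(text, ann_path.read_text().splitlines())
        else:
            ann = AnnotationSet()
        items.append((doc, ann))
    return Corpus(items)
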