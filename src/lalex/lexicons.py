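"""Habitat-ontology and bacterium-taxonomy lexicons.

Provides the normalization and string-similarity primitives used both for
candidate generation (token overlap with a lexicon) and for features
(lexical overlap/containment flags, best ontology match, normalized edit
similarity between mentions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib

#: Tokens stripped from bacterium names before comparison: strain / species /
#: subspecies markers that vary freely between mentions of the same taxon.
DEFAULT_DROP_TOKENS = frozenset(
    {"str.", "str", "spp.", "spp", "strain", "sp.", "sp", "subsp"}
)

#: Small bundled function-word list for habitat phrase normalization.
DEFAULT_HABITAT_STOPWORDS = frozenset(
    {
        "the", "a", "an", "of", "in", "on", "at", "and", "or", "to", "for",
        "with", "by", "from", "as", "is", "was", "were", "be", "this", "that",
    }
)


@dataclass(frozen=True)
class NormalizationConfig:
    bacterium_drop_tokens: frozenset[str] = DEFAULT_DROP_TOKENS
    habitat_stopwords: frozenset[str] = DEFAULT_HABITAT_STOPWORDS
    case_fold: bool = True

    @property
    def _drop_canon(self) -> frozenset[str]:
        return frozenset(t.rstrip(".").lower() for t in self.bacterium_drop_tokens)


@dataclass
class OntologyNode:
    id: str
    name: str
    synonyms: set[str] = field(default_factory=set)
    related_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("ontology node needs a non-empty name")

    def terms(self) -> list[str]:
        return [self.name, *sorted(self.synonyms), *sorted(self.related_terms)]


class HabitatOntology:
    """A flat habitat lexicon: nodes with names, synonyms and related terms.

    ``token_index`` maps each (case-folded) term token to the ids of the nodes
    whose terms contain it; ``entry_strings`` is the set of all case-folded
    term strings, used for containment flags and gazetteer matching.
    """

    def __init__(self, nodes: Iterable[OntologyNode]):
        self.nodes: dict[str, OntologyNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise ValueError(f"duplicate node id {n.id}")
            self.nodes[n.id] = n
        self.token_index: dict[str, set[str]] = {}
        self.entry_strings: set[str] = set()
        for n in self.nodes.values():
            for term in n.terms():
                folded = term.lower()
                self.entry_strings.add(folded)
                for tok in folded.split():
                    self.token_index.setdefault(tok, set()).add(n.id)

    def __len__(self) -> int:
        return len(self.nodes)


class TaxonomyLexicon:
    """Newline-delimited bacterium name list, stored as normalization fixed
    points (names are normalized once on load)."""

    def __init__(self, names: Iterable[str], cfg: NormalizationConfig = NormalizationConfig()):
        self.names: set[str] = {
            n for n in (normalize_bacterium_name(x, cfg) for x in names) if n
        }
        self.token_index: dict[str, set[str]] = {}
        for name in self.names:
            for tok in name.split():
                self.token_index.setdefault(tok, set()).add(name)

    @property
    def entry_strings(self) -> set[str]:
        return self.names

    def __len__(self) -> int:
        return len(self.names)


def normalize_bacterium_name(name: str, cfg: NormalizationConfig = NormalizationConfig()) -> str:
    """Remove strain/species marker tokens and collapse whitespace.

    Drop tokens match as whole tokens, with or without a trailing period;
    the result is case-folded when the config says so.
    """
    drop = cfg._drop_canon
    kept = [
        tok for tok in name.split() if tok.rstrip(".").lower() not in drop
    ]
    out = " ".join(kept)
    return out.lower() if cfg.case_fold else out


def normalize_habitat_phrase(phrase: str, cfg: NormalizationConfig = NormalizationConfig()) -> str:
    """Remove configured stopwords token-wise and collapse whitespace."""
    kept = [t for t in phrase.split() if t.lower() not in cfg.habitat_stopwords]
    out = " ".join(kept)
    return out.lower() if cfg.case_fold else out


def edit_similarity(a: str, b: str) -> float:
    """1 minus the Levenshtein distance normalized by the longer string.

    Symmetric, bounded in [0, 1], equal to 1 iff the strings are equal
    (defined as 1 when both are empty).
    """
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def best_ontology_match(
    phrase: str,
    ont: HabitatOntology,
    cfg: NormalizationConfig = NormalizationConfig(),
) -> tuple[Optional[str], float]:
    """Best-matching ontology node for a (normalized) habitat phrase.

    Maximizes :func:`edit_similarity` over every node name, synonym and
    related term; ties go to the lexicographically smallest node id.  Returns
    ``(None, 0.0)`` for an empty ontology.
    """
    query = phrase.lower() if cfg.case_fold else phrase
    best_id: Optional[str] = None
    best_sim = 0.0
    for node_id in sorted(ont.nodes):
        for term in ont.nodes[node_id].terms():
            cand = term.lower() if cfg.case_fold else term
            sim = edit_similarity(query, cand)
            if sim > best_sim:
                best_sim = sim
                best_id = node_id
    if best_id is None:
        return None, 0.0
    return best_id, best_sim


def lexicon_overlap_flags(
    phrase_tokens: Sequence[str],
    lexicon: HabitatOntology | TaxonomyLexicon,
) -> tuple[bool, bool, bool]:
    """(overlap, containment, inverse containment) of a phrase vs a lexicon.

    overlap: at least one token is shared with some lexicon entry;
    containment: the phrase string occurs inside some entry;
    inverse containment: some entry occurs inside the phrase string.
    Tokens are expected normalized (case-folded) already.
    """
    tokens = [t.lower() for t in phrase_tokens]
    overlap = any(t in lexicon.token_index for t in tokens)
    phrase = " ".join(tokens)
    containment = False
    inverse = False
    if phrase:
        for entry in lexicon.entry_strings:
            if not containment and phrase in entry:
                containment = True
            if not inverse and entry and entry in phrase:
                inverse = True
            if containment and inverse:
                break
    return overlap, containment, inverse


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def load_taxonomy(path: str | Path, cfg: NormalizationConfig = NormalizationConfig()) -> TaxonomyLexicon:
    names = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return TaxonomyLexicon(names, cfg)


def save_taxonomy(tax: TaxonomyLexicon, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(tax.names)) + "\n")


_RELATED_SCOPES = {"RELATED"}


def load_ontology(path: str | Path) -> HabitatOntology:
    """Load an OBO-flavored (``.obo``) or TSV habitat lexicon.

    TSV fallback columns: ``id<TAB>name<TAB>syn|syn<TAB>rel|rel`` (the last
    two optional).
    """
    p = Path(path)
    if p.suffix == ".obo":
        return _load_obo(p)
    nodes = []
    for line in p.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        node_id, name = fields[0], fields[1]
        syns = set(filter(None, fields[2].split("|"))) if len(fields) > 2 else set()
        rels = set(filter(None, fields[3].split("|"))) if len(fields) > 3 else set()
        nodes.append(OntologyNode(node_id, name, syns, rels))
    return HabitatOntology(nodes)


def _load_obo(path: Path) -> HabitatOntology:
    import re

    import obonet

    graph = obonet.read_obo(path)
    syn_re = re.compile(r'"((?:[^"\\]|\\.)*)"\s*(\w+)?')
    nodes = []
    for node_id, data in graph.nodes(data=True):
        name = data.get("name", "")
        if not name:
            continue
        syns: set[str] = set()
        rels: set[str] = set()
        for raw in data.get("synonym", []):
            m = syn_re.search(raw)
            if not m:
                continue
            term, scope = m.group(1), (m.group(2) or "EXACT").upper()
            term = term.replace('\\"', '"')
            (rels if scope in _RELATED_SCOPES else syns).add(term)
        nodes.append(OntologyNode(node_id, name, syns, rels))
    return HabitatOntology(nodes)


def save_ontology_obo(ont: HabitatOntology, path: str | Path) -> None:
    lines = ["format-version: 1.2", ""]
    for node_id in sorted(ont.nodes):
        n = ont.nodes[node_id]
        lines.append("[Term]")
        lines.append(f"id: {n.id}")
        lines.append(f"name: {n.name}")
        for s in sorted(n.synonyms):
            lines.append(f'synonym: "{s}" EXACT []')
        for r in sorted(n.related_terms):
            lines.append(f'synonym: "{r}" RELATED []')
        lines.append("")
    Path(path).write_text("\n".join(lines))
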