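"""Precision / recall / F1 scoring of predicted standoff annotations.

Entities are matched one-to-one greedily in span order; ``strict`` mode
requires the identical span set and type, ``relaxed`` mode accepts any
character overlap (of any fragment) with the same type.  A relation counts
as correct when both of its arguments are matched to the arguments of one
gold relation.  ``sentence`` level restricts both predicted and gold
relations to argument pairs lying within one sentence before counting,
ignoring cross-sentence links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .standoff import AnnotationSet, Document, EntityAnnotation, RelationAnnotation

TARGETS = ("Bacterium", "Habitat", "Localization")


@dataclass
class TargetCounts:
    tp: int = 0
    n_pred: int = 0
    n_gold: int = 0

    @property
    def precision(self) -> float:
        return self.tp / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.n_gold if self.n_gold else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def add(self, other: "TargetCounts") -> None:
        self.tp += other.tp
        self.n_pred += other.n_pred
        self.n_gold += other.n_gold


@dataclass
class EvalReport:
    mode: str = "strict"
    level: str = "document"
    targets: dict[str, TargetCounts] = field(
        default_factory=lambda: {t: TargetCounts() for t in TARGETS}
    )

    def __getitem__(self, target: str) -> TargetCounts:
        return self.targets[target]

    def add(self, other: "EvalReport") -> None:
        for t in TARGETS:
            self.targets[t].add(other.targets[t])

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "level": self.level,
            "targets": {
                t: {
                    "tp": c.tp,
                    "predicted": c.n_pred,
                    "gold": c.n_gold,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f1": c.f1,
                }
                for t, c in self.targets.items()
            },
        }


def _spans_match(pred: EntityAnnotation, gold: EntityAnnotation, mode: str) -> bool:
    if pred.etype != gold.etype:
        return False
    if mode == "strict":
        return pred.spans == gold.spans
    if mode == "relaxed":
        return any(ps.overlaps(gs) for ps in pred.spans for gs in gold.spans)
    raise ValueError(f"unknown evaluation mode {mode!r}")


def match_entities(
    pred: Sequence[EntityAnnotation],
    gold: Sequence[EntityAnnotation],
    mode: str = "strict",
) -> dict[str, str]:
    """Greedy one-to-one entity matching in span order.

    Returns a mapping from predicted entity id to gold entity id.
    """
    order = lambda e: (e.spans[0].start, e.spans[-1].end, e.id)
    matched: dict[str, str] = {}
    used: set[str] = set()
    for p in sorted(pred, key=order):
        for g in sorted(gold, key=order):
            if g.id in used:
                continue
            if _spans_match(p, g, mode):
                matched[p.id] = g.id
                used.add(g.id)
                break
    return matched


def _sentence_level_relations(
    ann: AnnotationSet, doc: Document
) -> list[RelationAnnotation]:
    """Relations whose two arguments lie within one and the same sentence."""
    out = []
    for r in ann.relations:
        b = ann.entity_by_id(r.bacterium_arg)
        h = ann.entity_by_id(r.habitat_arg)
        sb = doc.sentence_index_of(b.extent)
        sh = doc.sentence_index_of(h.extent)
        if sb is not None and sb == sh:
            out.append(r)
    return out


def evaluate(
    pred: AnnotationSet,
    gold: AnnotationSet,
    doc: Optional[Document] = None,
    mode: str = "strict",
    level: str = "document",
    ignore_gold_types: Sequence[str] = (),
) -> EvalReport:
    """Score one document's predictions against gold.

    ``ignore_gold_types`` can drop relation types that were not modelled
    (e.g. part-of links) from the gold before counting; leave empty to count
    them as unrecoverable misses.
    """
    if level not in ("document", "sentence"):
        raise ValueError(f"unknown evaluation level {level!r}")
    gold_entities = list(gold.entities)
    gold_relations = [
        r for r in gold.relations if r.rtype not in ignore_gold_types
    ]
    pred_relations = list(pred.relations)
    if level == "sentence":
        if doc is None:
            raise ValueError("sentence-level evaluation needs the document")
        gold_relations = [
            r for r in _sentence_level_relations(gold, doc)
            if r.rtype not in ignore_gold_types
        ]
        pred_relations = _sentence_level_relations(pred, doc)

    report = EvalReport(mode=mode, level=level)
    matching = match_entities(pred.entities, gold_entities, mode)
    for target in ("Bacterium", "Habitat"):
        c = report[target]
        c.n_pred = sum(1 for e in pred.entities if e.etype == target)
        c.n_gold = sum(1 for e in gold_entities if e.etype == target)
        by_id = {e.id: e for e in pred.entities}
        c.tp = sum(
            1 for pid, gid in matching.items() if by_id[pid].etype == target
        )

    c = report["Localization"]
    c.n_pred = len(pred_relations)
    c.n_gold = len(gold_relations)
    gold_pairs: dict[tuple[str, str], int] = {}
    for r in gold_relations:
        key = (r.bacterium_arg, r.habitat_arg)
        gold_pairs[key] = gold_pairs.get(key, 0) + 1
    for r in pred_relations:
        b = matching.get(r.bacterium_arg)
        h = matching.get(r.habitat_arg)
        if b is None or h is None:
            continue
        key = (b, h)
        if gold_pairs.get(key, 0) > 0:
            gold_pairs[key] -= 1
            c.tp += 1
    return report


def evaluate_corpus(
    triples: Iterable[tuple[AnnotationSet, AnnotationSet, Optional[Document]]],
    mode: str = "strict",
    level: str = "document",
    ignore_gold_types: Sequence[str] = (),
) -> EvalReport:
    """Micro-averaged scores over (pred, gold, doc) triples."""
    total = EvalReport(mode=mode, level=level)
    for pred, gold, doc in triples:
        total.add(evaluate(pred, gold, doc, mode, level, ignore_gold_types))
    return total
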