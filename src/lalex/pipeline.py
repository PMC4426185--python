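"""End-to-end plumbing: corpus -> candidate sets with features and gold.

Thin glue used by the CLI, the tests and the reproduction script; the actual
work happens in :mod:`candidates` and :mod:`features`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .candidates import (
    CandidateSet,
    align_gold,
    build_candidate_set,
    gazetteer_chunks,
    gold_chunks,
    load_chunk_file,
)
from .features import FeatureConfig, attach_features
from .lexicons import HabitatOntology, NormalizationConfig, TaxonomyLexicon
from .standoff import AnnotationSet, Corpus, Document


@dataclass(frozen=True)
class PipelineConfig:
    chunker: str = "gazetteer"  # "gazetteer" | "gold" | path to a chunk file
    align_mode: str = "exact"
    normalization: NormalizationConfig = NormalizationConfig()
    features: FeatureConfig = FeatureConfig()


def prepare_example(
    doc: Document,
    ann: Optional[AnnotationSet],
    ont: HabitatOntology,
    tax: TaxonomyLexicon,
    cfg: PipelineConfig = PipelineConfig(),
) -> CandidateSet:
    if cfg.chunker == "gazetteer":
        chunks = gazetteer_chunks(doc, ont, tax, cfg.normalization)
    elif cfg.chunker == "gold":
        if ann is None:
            raise ValueError("gold chunker needs annotations")
        chunks = gold_chunks(doc, ann)
    else:
        chunks = load_chunk_file(cfg.chunker, doc.id)
    cands = build_candidate_set(doc, chunks, ont, tax, cfg.normalization)
    attach_features(cands, ont, tax, cfg.normalization, cfg.features)
    if ann is not None:
        align_gold(cands, ann, cfg.align_mode)
    return cands


def prepare_corpus(
    corpus: Corpus,
    ont: HabitatOntology,
    tax: TaxonomyLexicon,
    cfg: PipelineConfig = PipelineConfig(),
) -> list[CandidateSet]:
    return [prepare_example(doc, ann, ont, tax, cfg) for doc, ann in corpus]


def candidate_recall(examples: Sequence[CandidateSet]) -> dict[str, float]:
    """Micro-averaged candidate-recall ceiling over prepared examples."""
    ent_matched = ent_total = rel_matched = rel_total = 0
    for ex in examples:
        if ex.alignment is None:
            continue
        ent_matched += ex.alignment.matched_gold_entities
        ent_total += ex.alignment.n_gold_entities
        rel_matched += ex.alignment.matched_gold_relations
        rel_total += ex.alignment.n_gold_relations
    return {
        "entities": ent_matched / ent_total if ent_total else 1.0,
        "relations": rel_matched / rel_total if rel_total else 1.0,
    }
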