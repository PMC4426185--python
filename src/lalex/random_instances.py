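"""Random small instances for validating the solver and the identities.

Used by the validation suite and the reproduction script: random candidate
sets with random sparse features, random weight vectors and random feasible
label assignments.  Deterministic given the ``random.Random`` passed in.
"""

from __future__ import annotations

import random

from .candidates import (
    CandidateSet,
    LabelAssignment,
    PhraseCandidate,
    RelationCandidate,
    chain_relation_pairs,
)
from .model import WeightVector
from .standoff import Document, TextSpan


def make_random_cands(
    rng: random.Random, max_phrases: int = 3, max_relations: int = 2
) -> CandidateSet:
    """A random small candidate set with random sparse feature caches."""
    doc = Document(id="rand", text="x" * 200)
    n_p = rng.randint(1, max_phrases)
    phrases = []
    for k in range(n_p):
        tr = rng.random() < 0.6
        lm = rng.random() < 0.6 or not tr
        phrases.append(
            PhraseCandidate(k, "rand", (k,), TextSpan(k * 7, k * 7 + 3), k, tr, lm)
        )
    rels = []
    for b in phrases:
        for h in phrases:
            if (
                b.in_C_tr and h.in_C_lm and b is not h
                and len(rels) < max_relations and rng.random() < 0.8
            ):
                rels.append(RelationCandidate(len(rels), b, h))
    cands = CandidateSet(
        doc=doc, phrases=phrases, relations=rels,
        relation_pairs=chain_relation_pairs(rels),
    )
    cands.phi_phrase = [
        {"a": rng.uniform(-1, 1), "b": rng.uniform(-1, 1), "bias": 1.0}
        for _ in phrases
    ]
    cands.phi_pair = [{"a": rng.uniform(-1, 1), "bias": 1.0} for _ in rels]
    cands.phi_rr = [{"a": rng.uniform(-1, 1), "bias": 1.0} for _ in cands.relation_pairs]
    return cands


def make_random_weights(rng: random.Random) -> WeightVector:
    W = WeightVector.zeros()
    for blk in W.blocks:
        W[blk]["a"] = rng.uniform(-2, 2)
        W[blk]["b"] = rng.uniform(-2, 2)
        W[blk]["bias"] = rng.uniform(-1, 1)
    return W


def random_labels(rng: random.Random, cands: CandidateSet) -> LabelAssignment:
    """A random feasible label assignment for a candidate set."""
    y = LabelAssignment.zeros(cands)
    for k, p in enumerate(cands.phrases):
        choices = ["nrol"] + (["tr"] if p.in_C_tr else []) + (["lm"] if p.in_C_lm else [])
        y.get(rng.choice(choices))[k] = 1
    for i, rel in enumerate(cands.relations):
        if y.tr[rel.bacterium.id] and y.lm[rel.habitat.id] and rng.random() < 0.5:
            y.loc[i] = 1
        else:
            y.nloc[i] = 1
    for j, pair in enumerate(cands.relation_pairs):
        if y.loc[pair.first.id] and y.loc[pair.second.id] and rng.random() < 0.5:
            y.rr[j] = 1
    return y
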