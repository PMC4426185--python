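"""The link-and-label model core.

A model is a set of six templates, one per label type.  Each template pairs a
label type with a candidate set, a feature function and a block of the weight
vector.  The score of an output assignment is the sum, over templates and
over candidates whose label is on, of the dot product between the template's
weight block and the candidate's feature vector:

    Obj = sum_{k in C_tr}  <W_tr,   phi(x_k)> tr_k
        + sum_{k in C_lm}  <W_lm,   phi(x_k)> lm_k
        + sum_{k in C_nrol}<W_nrol, phi(x_k)> nrol_k
        + sum_{ij in C_loc}<W_loc,  phi(x_ij)> loc_ij
        + sum_{ij in C_loc}<W_nloc, phi(x_ij)> nloc_ij
        + sum_{rr pairs}   <W_rr,   phi(..)>  rr_..

The auxiliary no-role template reuses the phrase feature function (with its
own weight block), and no-localization reuses the pair feature function.  A
per-template ``bias`` feature is part of every candidate vector.

The training loss is the decomposed Hamming loss: per label type p,

    Delta_p = (1/|C_p|) ( sum_i (1 - 2 y'_i) y_i + sum_i y'_i )

with y' the gold labels, averaged over the included label types (by default
the directly targeted ones: tr, lm, loc).  For binary y this equals the
normalized Hamming distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .candidates import CandidateSet, LabelAssignment

__all__ = [
    "LabelAssignment",
    "Template",
    "TEMPLATES",
    "BLOCKS",
    "WeightVector",
    "joint_feature",
    "score",
    "hamming_loss",
    "is_feasible",
]

#: canonical block order
BLOCKS: tuple[str, ...] = ("tr", "lm", "nrol", "loc", "nloc", "rr")

#: blocks taking part in each inference scope
SCOPE_BLOCKS: dict[str, tuple[str, ...]] = {
    "entity": ("tr", "lm", "nrol"),
    "relation": ("loc", "nloc"),
    "joint": ("tr", "lm", "nrol", "loc", "nloc"),
    "joint_rr": ("tr", "lm", "nrol", "loc", "nloc", "rr"),
}


@dataclass(frozen=True)
class Template:
    label_type: str
    candidate_field: str  # CandidateSet attribute holding the candidates
    feature_cache: str  # CandidateSet attribute holding the phi vectors
    weight_block: str


#: The six templates.  no-role shares the phrase feature function of the
#: bacterium/habitat templates; no-localization shares the pair features.
TEMPLATES: tuple[Template, ...] = (
    Template("tr", "phrases", "phi_phrase", "tr"),
    Template("lm", "phrases", "phi_phrase", "lm"),
    Template("nrol", "phrases", "phi_phrase", "nrol"),
    Template("loc", "relations", "phi_pair", "loc"),
    Template("nloc", "relations", "phi_pair", "nloc"),
    Template("rr", "relation_pairs", "phi_rr", "rr"),
)

TEMPLATE_BY_TYPE: dict[str, Template] = {t.label_type: t for t in TEMPLATES}


def sparse_dot(w: Mapping[str, float], phi: Mapping[str, float]) -> float:
    if len(w) > len(phi):
        w, phi = phi, w
    return sum(v * phi[k] for k, v in w.items() if k in phi)


def add_scaled(acc: dict[str, float], vec: Mapping[str, float], s: float = 1.0) -> None:
    for k, v in vec.items():
        acc[k] = acc.get(k, 0.0) + s * v


@dataclass
class WeightVector:
    """Blocked sparse weights W = [W_tr, W_lm, W_nrol, W_loc, W_nloc, W_rr]."""

    blocks: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: {} for b in BLOCKS}
    )

    @classmethod
    def zeros(cls) -> "WeightVector":
        return cls()

    def __getitem__(self, block: str) -> dict[str, float]:
        return self.blocks[block]

    def copy(self) -> "WeightVector":
        return WeightVector({b: dict(w) for b, w in self.blocks.items()})

    def add_scaled(self, other: "BlockedVector", s: float = 1.0) -> None:
        for b, vec in other.items():
            add_scaled(self.blocks.setdefault(b, {}), vec, s)

    def prune(self, eps: float = 0.0) -> None:
        for b in self.blocks:
            self.blocks[b] = {
                k: v for k, v in self.blocks[b].items() if abs(v) > eps
            }

    def norm_sq(self) -> float:
        return sum(v * v for w in self.blocks.values() for v in w.values())

    def to_json(self) -> str:
        return json.dumps({"version": 1, "blocks": self.blocks}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WeightVector":
        data = json.loads(text)
        blocks = {b: dict(data["blocks"].get(b, {})) for b in BLOCKS}
        return cls(blocks)


BlockedVector = dict[str, dict[str, float]]


def blocked_dot(a: BlockedVector, b: BlockedVector) -> float:
    return sum(sparse_dot(a[k], b[k]) for k in a if k in b)


def joint_feature(
    cands: CandidateSet,
    y: LabelAssignment,
    blocks: Optional[Sequence[str]] = None,
) -> BlockedVector:
    """Per block, the sum of phi over candidates whose label is on."""
    wanted = set(blocks) if blocks is not None else set(BLOCKS)
    out: BlockedVector = {}
    for tpl in TEMPLATES:
        if tpl.weight_block not in wanted:
            continue
        phis = getattr(cands, tpl.feature_cache)
        labels = y.get(tpl.label_type)
        items = getattr(cands, tpl.candidate_field)
        if len(labels) != len(items):
            raise ValueError(
                f"label dimension mismatch for {tpl.label_type}: "
                f"{len(labels)} != {len(items)}"
            )
        if phis is None:
            if tpl.label_type == "rr" and not labels.any():
                out.setdefault(tpl.weight_block, {})
                continue
            raise ValueError(f"features not attached for {tpl.feature_cache}")
        acc: dict[str, float] = {}
        for k, on in enumerate(labels):
            if on:
                add_scaled(acc, phis[k])
        out[tpl.weight_block] = acc
    return out


def score(
    W: WeightVector,
    cands: CandidateSet,
    y: LabelAssignment,
    blocks: Optional[Sequence[str]] = None,
) -> float:
    """<W, f(x, y)>: the linear discriminant over the joint features."""
    wanted = set(blocks) if blocks is not None else set(BLOCKS)
    total = 0.0
    for tpl in TEMPLATES:
        if tpl.weight_block not in wanted:
            continue
        labels = y.get(tpl.label_type)
        if not labels.any():
            continue
        phis = getattr(cands, tpl.feature_cache)
        if phis is None:
            raise ValueError(f"features not attached for {tpl.feature_cache}")
        w = W[tpl.weight_block]
        for k, on in enumerate(labels):
            if on:
                total += sparse_dot(w, phis[k])
    return total


DEFAULT_LOSS_TYPES: tuple[str, ...] = ("tr", "lm", "loc")


def hamming_loss(
    cands: CandidateSet,
    y: LabelAssignment,
    gold: LabelAssignment,
    included: Sequence[str] = DEFAULT_LOSS_TYPES,
    weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Decomposed Hamming loss, averaged over the included label types.

    ``weights`` optionally reweights the per-type terms (they are normalized
    to sum to 1); by default the average is unweighted.  A type with an empty
    candidate set contributes 0.
    """
    if weights is None:
        weights = {p: 1.0 for p in included}
    wsum = sum(weights[p] for p in included)
    total = 0.0
    for p in included:
        mask = cands.members(p)
        n = int(mask.sum())
        if n == 0:
            continue
        yp = y.get(p)[mask].astype(np.int64)
        gp = gold.get(p)[mask].astype(np.int64)
        delta = (((1 - 2 * gp) * yp).sum() + gp.sum()) / n
        total += weights[p] / wsum * delta
    return float(total)


def is_feasible(cands: CandidateSet, y: LabelAssignment, with_rr: bool = True) -> bool:
    """Check the output constraints: entity exclusivity, relation exclusivity,
    role links and (optionally) rr links."""
    for k, p in enumerate(cands.phrases):
        tr = int(y.tr[k]) if p.in_C_tr else 0
        lm = int(y.lm[k]) if p.in_C_lm else 0
        if y.tr[k] and not p.in_C_tr:
            return False
        if y.lm[k] and not p.in_C_lm:
            return False
        if tr + lm + int(y.nrol[k]) != 1:
            return False
    for i, rel in enumerate(cands.relations):
        if int(y.loc[i]) + int(y.nloc[i]) != 1:
            return False
        if y.loc[i] and (not y.tr[rel.bacterium.id] or not y.lm[rel.habitat.id]):
            return False
    if with_rr:
        for j, pair in enumerate(cands.relation_pairs):
            if y.rr[j] and (not y.loc[pair.first.id] or not y.loc[pair.second.id]):
                return False
    return True


def save_weights(W: WeightVector, path: str | Path) -> None:
    Path(path).write_text(W.to_json())


def load_weights(path: str | Path) -> WeightVector:
    return WeightVector.from_json(Path(path).read_text())
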