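"""Margin-rescaling structured SVM trained with cutting planes.

The trainer minimizes the n-slack objective

    min_{W, xi >= 0}  1/2 ||W||^2 + C sum_i xi_i
    s.t.  for every example i and competitor y:
          <W, Psi(x_i, y_i) - Psi(x_i, y)> >= Delta(y_i, y) - xi_i

by repeatedly solving the loss-augmented inference per example (the
most-violated competitor under the current weights), adding violated
constraints to a working set and re-solving the quadratic sub-problem over
that set.  Training stops when no violation exceeds the tolerance ``e``.

The working-set QP is solved in the dual (one simplex-with-slack of radius
C per example) by deterministic coordinate ascent with within-example
pairwise (SMO-style) exchange steps.

Variants (matching the experimental settings):

==========  =======================  ==========================
variant     training                 prediction
==========  =======================  ==========================
LO          entity + relation,       independent
            independent
L+I         same weights as LO       joint
IBT-I       joint (role links on)    independent
IBT+I       joint                    joint
IBT+IG1     joint + rr (Same-B)      joint + rr
IBT+IG2     joint + rr (Same-B and   joint + rr
            Sim-BH)
==========  =======================  ==========================
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .candidates import CandidateSet, LabelAssignment
from .features import FeatureConfig
from .inference import VariantConfigError, build_problem, solve
from .model import (
    SCOPE_BLOCKS,
    BlockedVector,
    WeightVector,
    blocked_dot,
    hamming_loss,
    joint_feature,
    score,
)
from .standoff import AnnotationSet, Document, EntityAnnotation, RelationAnnotation

VARIANTS = ("LO", "L+I", "IBT-I", "IBT+I", "IBT+IG1", "IBT+IG2")

_VARIANT_PREDICTION = {
    "LO": "independent",
    "L+I": "joint",
    "IBT-I": "independent",
    "IBT+I": "joint",
    "IBT+IG1": "joint",
    "IBT+IG2": "joint",
}


def feature_config_for(variant: str, base: FeatureConfig = FeatureConfig()) -> FeatureConfig:
    """The feature configuration a variant requires (rr features for IG)."""
    if variant == "IBT+IG1":
        return FeatureConfig(
            word=base.word, phrase=base.phrase, pair=base.pair,
            relpair_same_b=True, relpair_sim_bh=False,
            parse_fallback=base.parse_fallback, hashing_dim=base.hashing_dim,
        )
    if variant == "IBT+IG2":
        return FeatureConfig(
            word=base.word, phrase=base.phrase, pair=base.pair,
            relpair_same_b=True, relpair_sim_bh=True,
            parse_fallback=base.parse_fallback, hashing_dim=base.hashing_dim,
        )
    return base


@dataclass
class TrainingConfig:
    """Structured-SVM settings.

    ``C`` is the trade-off between training error and margin and ``tol`` the
    violation tolerance for termination (the e parameter); the defaults are
    the untuned setting C = 0.01, e = 1e-4 with margin rescaling.  The seed
    only controls the order in which examples are visited.
    """

    C: float = 0.01
    tol: float = 1e-4
    max_iterations: int = 200
    variant: str = "IBT+I"
    seed: int = 0
    loss_types: tuple[str, ...] = ("tr", "lm", "loc")
    qp_max_passes: int = 5000
    qp_tol: float = 1e-14

    def __post_init__(self) -> None:
        if self.C <= 0 or self.tol <= 0:
            raise ValueError("C and tol must be positive")
        if self.variant not in VARIANTS:
            raise VariantConfigError(f"unknown variant {self.variant!r}")


@dataclass
class TrainingReport:
    iterations: int = 0
    converged: bool = True
    final_max_violation: float = 0.0
    working_set_size: int = 0
    qp_objectives: list[float] = field(default_factory=list)
    slacks: list[float] = field(default_factory=list)  # final xi_i per example


@dataclass
class TrainedModel:
    weights: WeightVector
    config: TrainingConfig
    feature_config: FeatureConfig = FeatureConfig()
    report: TrainingReport = field(default_factory=TrainingReport)
    sub_reports: dict[str, TrainingReport] = field(default_factory=dict)


class _WorkingSet:
    """Dual working set of margin-rescaling constraints."""

    def __init__(self, n_examples: int, c_eff: float, qp_max_passes: int, qp_tol: float):
        self.c_eff = c_eff
        self.qp_max_passes = qp_max_passes
        self.qp_tol = qp_tol
        self.owner: list[int] = []
        self.delta: list[float] = []
        self.dpsi: list[BlockedVector] = []
        self.alpha = np.zeros(0)
        self.H = np.zeros((0, 0))
        self.keys: set[tuple[int, bytes]] = set()
        self.n_examples = n_examples

    def __len__(self) -> int:
        return len(self.owner)

    def contains(self, key: tuple[int, bytes]) -> bool:
        return key in self.keys

    def add(self, i: int, key: tuple[int, bytes], delta: float, dpsi: BlockedVector) -> None:
        m = len(self.owner)
        self.owner.append(i)
        self.delta.append(delta)
        self.dpsi.append(dpsi)
        self.keys.add(key)
        new_col = np.array([blocked_dot(dpsi, d) for d in self.dpsi])
        H = np.zeros((m + 1, m + 1))
        H[:m, :m] = self.H
        H[m, :] = new_col
        H[:, m] = new_col
        self.H = H
        self.alpha = np.append(self.alpha, 0.0)

    def solve_qp(self) -> float:
        """Deterministic SMO-style coordinate ascent on the dual; returns the
        dual objective value (equal to the primal at optimum)."""
        m = len(self.owner)
        if m == 0:
            return 0.0
        H = self.H
        delta = np.asarray(self.delta)
        alpha = self.alpha
        groups: dict[int, list[int]] = {}
        for c, i in enumerate(self.owner):
            groups.setdefault(i, []).append(c)
        ha = H @ alpha
        group_sum = {i: alpha[idx].sum() for i, idx in groups.items()}

        def objective() -> float:
            return float(delta @ alpha - 0.5 * alpha @ ha)

        obj = objective()
        for _ in range(self.qp_max_passes):
            improved = 0.0
            for c in range(m):
                g = delta[c] - ha[c]
                cap = self.c_eff - group_sum[self.owner[c]] + alpha[c]
                if H[c, c] > 0:
                    new = min(max(alpha[c] + g / H[c, c], 0.0), cap)
                else:
                    new = cap if g > 0 else 0.0
                d = new - alpha[c]
                if d != 0.0:
                    improved += g * d - 0.5 * H[c, c] * d * d
                    alpha[c] = new
                    group_sum[self.owner[c]] += d
                    ha += d * H[:, c]
            for idx in groups.values():
                if len(idx) < 2:
                    continue
                for ai in range(len(idx)):
                    for bi in range(ai + 1, len(idx)):
                        a, b = idx[ai], idx[bi]
                        q = H[a, a] + H[b, b] - 2.0 * H[a, b]
                        g = (delta[a] - ha[a]) - (delta[b] - ha[b])
                        if q > 0:
                            t = g / q
                        else:
                            t = np.inf if g > 0 else -np.inf
                        t = min(max(t, -alpha[a]), alpha[b])
                        if t != 0.0:
                            improved += g * t - 0.5 * q * t * t
                            alpha[a] += t
                            alpha[b] -= t
                            ha += t * (H[:, a] - H[:, b])
            obj += improved
            if improved < self.qp_tol * (1.0 + abs(obj)):
                break
        self.alpha = alpha
        return objective()

    def weights(self, blocks: Sequence[str]) -> WeightVector:
        W = WeightVector({b: {} for b in blocks})
        for a, dpsi in zip(self.alpha, self.dpsi):
            if a != 0.0:
                W.add_scaled(dpsi, float(a))
        return W

    def slacks(self, W: WeightVector) -> np.ndarray:
        xi = np.zeros(self.n_examples)
        for c, i in enumerate(self.owner):
            margin = blocked_dot(W.blocks, self.dpsi[c])
            xi[i] = max(xi[i], self.delta[c] - margin)
        return np.maximum(xi, 0.0)


def _blocked_diff(a: BlockedVector, b: BlockedVector) -> BlockedVector:
    out: BlockedVector = {}
    for blk in set(a) | set(b):
        d = dict(a.get(blk, {}))
        for k, v in b.get(blk, {}).items():
            d[k] = d.get(k, 0.0) - v
        out[blk] = {k: v for k, v in d.items() if v != 0.0}
    return out


def _label_key(prob_scope: str, y: LabelAssignment) -> bytes:
    return b"".join(
        y.get(t).tobytes() for t in ("tr", "lm", "nrol", "loc", "nloc", "rr")
    )


def _cutting_plane(
    examples: Sequence[CandidateSet],
    scope: str,
    included: tuple[str, ...],
    cfg: TrainingConfig,
) -> tuple[WeightVector, TrainingReport]:
    blocks = SCOPE_BLOCKS[scope]
    report = TrainingReport()
    W = WeightVector({b: {} for b in blocks})
    n = len(examples)
    if n == 0:
        return W, report
    for ex in examples:
        if ex.gold is None:
            raise ValueError("training requires aligned gold labels")
    included = tuple(t for t in included if t in blocks)
    rng = random.Random(cfg.seed)
    ws = _WorkingSet(n, cfg.C, cfg.qp_max_passes, cfg.qp_tol)
    psi_gold = [joint_feature(ex, ex.gold, blocks) for ex in examples]
    xi = np.zeros(n)
    order = list(range(n))
    max_violation = 0.0
    for it in range(cfg.max_iterations):
        rng.shuffle(order)
        added = 0
        max_violation = 0.0
        for i in order:
            ex = examples[i]
            prob = build_problem(W, ex, scope, loss_terms=(ex.gold, included))
            if prob.n_vars == 0:
                continue
            y_hat = solve(prob, lexicographic=False)
            loss = hamming_loss(ex, y_hat, ex.gold, included)
            margin = score(W, ex, ex.gold, blocks) - score(W, ex, y_hat, blocks)
            violation = loss - margin - xi[i]
            max_violation = max(max_violation, violation)
            if violation > cfg.tol:
                key = (i, _label_key(scope, y_hat))
                if ws.contains(key):
                    continue
                dpsi = _blocked_diff(psi_gold[i], joint_feature(ex, y_hat, blocks))
                ws.add(i, key, loss, dpsi)
                added += 1
        report.iterations = it + 1
        if added == 0:
            break
        report.qp_objectives.append(ws.solve_qp())
        W = ws.weights(blocks)
        xi = ws.slacks(W)
    else:
        report.converged = False
    report.final_max_violation = max(0.0, max_violation)
    report.working_set_size = len(ws)
    report.slacks = [float(x) for x in xi]
    if report.converged and report.final_max_violation > cfg.tol:
        report.converged = False
    return W, report


def train(examples: Sequence[CandidateSet], cfg: TrainingConfig) -> TrainedModel:
    """Train the weight blocks for a variant on candidate sets with gold.

    LO (and L+I) trains two independent models: the entity blocks under
    entity exclusivity with loss over {tr, lm}, and the relation blocks under
    relation exclusivity with loss over {loc}.  The IBT variants train all
    blocks jointly under the full constraint set (plus rr links for the IG
    variants, which add the relation-pair block).
    """
    variant = cfg.variant
    model = TrainedModel(
        weights=WeightVector.zeros(),
        config=cfg,
        feature_config=feature_config_for(variant),
    )
    if variant in ("LO", "L+I"):
        w_ent, rep_ent = _cutting_plane(
            examples, "entity", tuple(t for t in cfg.loss_types if t in ("tr", "lm")), cfg
        )
        w_rel, rep_rel = _cutting_plane(examples, "relation", ("loc",), cfg)
        for b, w in list(w_ent.blocks.items()) + list(w_rel.blocks.items()):
            model.weights.blocks[b] = w
        model.sub_reports = {"entity": rep_ent, "relation": rep_rel}
        model.report = TrainingReport(
            iterations=max(rep_ent.iterations, rep_rel.iterations),
            converged=rep_ent.converged and rep_rel.converged,
            final_max_violation=max(
                rep_ent.final_max_violation, rep_rel.final_max_violation
            ),
            working_set_size=rep_ent.working_set_size + rep_rel.working_set_size,
        )
        return model
    scope = "joint_rr" if variant in ("IBT+IG1", "IBT+IG2") else "joint"
    if scope == "joint_rr":
        for ex in examples:
            if ex.relation_pairs and ex.phi_rr is None:
                raise VariantConfigError(
                    f"variant {variant} needs relation-pair features attached"
                )
    w, rep = _cutting_plane(examples, scope, cfg.loss_types, cfg)
    for b, vec in w.blocks.items():
        model.weights.blocks[b] = vec
    model.report = rep
    return model


def predict(
    model: TrainedModel,
    cands: CandidateSet,
    mode: Optional[str] = None,
) -> LabelAssignment:
    """Predict labels for one document.

    ``independent`` mode solves the entity and the relation problems
    separately (multi-class entity typing plus binary relation
    classification); ``joint`` mode solves one problem under the full
    constraint set, adding rr variables when the model carries a relation-pair
    block.  The default mode follows the model's variant.
    """
    variant = model.config.variant
    if mode is None:
        mode = _VARIANT_PREDICTION[variant]
    if mode not in ("independent", "joint"):
        raise VariantConfigError(f"unknown prediction mode {mode!r}")
    W = model.weights
    if mode == "independent":
        y = solve(build_problem(W, cands, "entity"))
        y_rel = solve(build_problem(W, cands, "relation"))
        y.loc = y_rel.loc
        y.nloc = y_rel.nloc
        return y
    use_rr = variant in ("IBT+IG1", "IBT+IG2") and bool(W["rr"])
    scope = "joint_rr" if use_rr else "joint"
    return solve(build_problem(W, cands, scope))


def training_loss(
    model: TrainedModel,
    examples: Sequence[CandidateSet],
    included: Optional[tuple[str, ...]] = None,
) -> float:
    """Mean decomposed Hamming loss of the model's predictions on examples."""
    if not examples:
        return 0.0
    included = included or model.config.loss_types
    total = 0.0
    for ex in examples:
        y = predict(model, ex)
        total += hamming_loss(ex, y, ex.gold, included)
    return total / len(examples)


def to_standoff(
    pred: LabelAssignment,
    cands: CandidateSet,
    doc: Document,
    strict: bool = True,
) -> AnnotationSet:
    """Materialize a predicted assignment as standoff annotations.

    Entities get T ids in span order; each loc relation references its
    arguments' entities.  With ``strict=True`` a relation whose argument is
    not labeled as the matching entity type raises (joint predictions always
    satisfy the role links, so this only triggers on independently predicted
    labels); with ``strict=False`` such arguments are materialized with the
    type the relation requires.
    """
    typed: dict[tuple[int, str], int] = {}  # (phrase idx, etype) -> order key
    for k, p in enumerate(cands.phrases):
        if pred.tr[k]:
            typed[(k, "Bacterium")] = k
        if pred.lm[k]:
            typed[(k, "Habitat")] = k
    rel_args: list[tuple[int, int]] = []
    for i, rel in enumerate(cands.relations):
        if not pred.loc[i]:
            continue
        b, h = rel.bacterium.id, rel.habitat.id
        if (b, "Bacterium") not in typed or (h, "Habitat") not in typed:
            if strict:
                raise ValueError(
                    "infeasible prediction: localization with an unlabeled argument"
                )
            typed.setdefault((b, "Bacterium"), b)
            typed.setdefault((h, "Habitat"), h)
        rel_args.append((b, h))
    ordered = sorted(
        typed, key=lambda kt: (cands.phrases[kt[0]].span.start,
                               cands.phrases[kt[0]].span.end, kt[1])
    )
    tid: dict[tuple[int, str], str] = {}
    entities = []
    for n, (k, etype) in enumerate(ordered, start=1):
        p = cands.phrases[k]
        tid[(k, etype)] = f"T{n}"
        entities.append(
            EntityAnnotation(f"T{n}", etype, (p.span,), p.mention(doc))
        )
    relations = [
        RelationAnnotation(
            f"R{n}", "Localization",
            tid[(b, "Bacterium")], tid[(h, "Habitat")],
        )
        for n, (b, h) in enumerate(
            sorted(
                rel_args,
                key=lambda bh: (
                    cands.phrases[bh[0]].span.start, cands.phrases[bh[1]].span.start
                ),
            ),
            start=1,
        )
    ]
    ann = AnnotationSet(entities, relations)
    ann.validate()
    return ann
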