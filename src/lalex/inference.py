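"""Constrained argmax over label assignments as an exact 0/1 linear program.

Both prediction and the loss-augmented inference of training maximize a
linear objective over binary label variables subject to the structural
constraints

    entity exclusivity:    tr_k + lm_k + nrol_k = 1          (per phrase)
    relation exclusivity:  loc_ij + nloc_ij = 1              (per relation)
    role link:             loc_ij <= tr_i,  loc_ij <= lm_j   (per relation)
    rr link:               rr <= loc_first, rr <= loc_second (per chained pair)

Problems are solved exactly with HiGHS (``scipy.optimize.milp`` with zero MIP
gap).  Ties are broken deterministically: among optima, the lexicographically
smallest variable vector in canonical order (all tr, then lm, loc, nrol,
nloc, rr) is returned, i.e. zeros are preferred on earlier variables.  A
brute-force enumerator with the same contract serves as validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .candidates import CandidateSet, LabelAssignment
from .model import SCOPE_BLOCKS, WeightVector, sparse_dot

CONSTRAINT_NAMES = (
    "entity_exclusivity",
    "relation_exclusivity",
    "role_link",
    "rr_link",
)

SCOPE_CONSTRAINTS: dict[str, frozenset[str]] = {
    "entity": frozenset({"entity_exclusivity"}),
    "relation": frozenset({"relation_exclusivity"}),
    "joint": frozenset({"entity_exclusivity", "relation_exclusivity", "role_link"}),
    "joint_rr": frozenset(
        {"entity_exclusivity", "relation_exclusivity", "role_link", "rr_link"}
    ),
}

#: canonical variable-type order (zeros preferred on earlier variables, so the
#: auxiliary labels, which come last, absorb ties)
_TYPE_ORDER = ("tr", "lm", "loc", "nrol", "nloc", "rr")


class InferenceError(RuntimeError):
    pass


class ProblemSizeError(ValueError):
    pass


class VariantConfigError(ValueError):
    pass


@dataclass
class InferenceProblem:
    """A binary linear program over the label variables of one document."""

    variables: list[tuple[str, int]]  # (label type, candidate index), canonical order
    coeffs: np.ndarray
    constraints: frozenset[str]
    # structural info, indexed by candidate index
    phrase_vars: dict[int, dict[str, int]] = field(default_factory=dict)
    relation_vars: dict[int, dict[str, int]] = field(default_factory=dict)
    relation_args: dict[int, tuple[int, int]] = field(default_factory=dict)
    rr_vars: dict[int, int] = field(default_factory=dict)
    rr_links: dict[int, tuple[int, int]] = field(default_factory=dict)
    sizes: tuple[int, int, int] = (0, 0, 0)  # (#phrases, #relations, #pairs)

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def to_assignment(self, x: np.ndarray) -> LabelAssignment:
        n_p, n_r, n_rr = self.sizes
        y = LabelAssignment(
            *(np.zeros(n, dtype=np.int8) for n in (n_p, n_p, n_p, n_r, n_r, n_rr))
        )
        for (label_type, idx), val in zip(self.variables, x):
            y.get(label_type)[idx] = int(round(float(val)))
        return y

    def vector_of(self, y: LabelAssignment) -> np.ndarray:
        return np.array(
            [int(y.get(t)[i]) for t, i in self.variables], dtype=np.int64
        )


def build_problem(
    W: WeightVector,
    cands: CandidateSet,
    scope: str,
    loss_terms: Optional[tuple[LabelAssignment, Sequence[str]]] = None,
) -> InferenceProblem:
    """Assemble the (optionally loss-augmented) inference problem.

    The objective coefficient of each label variable is the dot product of
    its weight block with its feature vector.  With ``loss_terms=(gold,
    included)``, the decomposed Hamming loss adds ``(1 - 2 gold_i)/(m |C_p|)``
    to each included variable's coefficient (the constant sum-of-gold term is
    dropped: it does not move the argmax).
    """
    if scope not in SCOPE_CONSTRAINTS:
        raise VariantConfigError(f"unknown inference scope {scope!r}")
    blocks = SCOPE_BLOCKS[scope]
    if "rr" in blocks and cands.relation_pairs and cands.phi_rr is None:
        raise VariantConfigError(
            "rr variables requested but relation-pair features are not attached"
        )
    n_p, n_r, n_rr = len(cands.phrases), len(cands.relations), len(cands.relation_pairs)

    entries: dict[str, list[tuple[int, float]]] = {t: [] for t in _TYPE_ORDER}
    if "tr" in blocks:
        for k, p in enumerate(cands.phrases):
            if p.in_C_tr:
                entries["tr"].append((k, sparse_dot(W["tr"], cands.phi_phrase[k])))
            if p.in_C_lm:
                entries["lm"].append((k, sparse_dot(W["lm"], cands.phi_phrase[k])))
            entries["nrol"].append((k, sparse_dot(W["nrol"], cands.phi_phrase[k])))
    if "loc" in blocks:
        for i in range(n_r):
            entries["loc"].append((i, sparse_dot(W["loc"], cands.phi_pair[i])))
            entries["nloc"].append((i, sparse_dot(W["nloc"], cands.phi_pair[i])))
    if "rr" in blocks:
        for j in range(n_rr):
            entries["rr"].append((j, sparse_dot(W["rr"], cands.phi_rr[j])))

    if loss_terms is not None:
        gold, included = loss_terms
        m = len(included)
        for p_type in included:
            if not entries[p_type]:
                continue
            size = int(cands.members(p_type).sum())
            if size == 0:
                continue
            gold_arr = gold.get(p_type)
            entries[p_type] = [
                (idx, coef + (1 - 2 * int(gold_arr[idx])) / (m * size))
                for idx, coef in entries[p_type]
            ]

    variables: list[tuple[str, int]] = []
    coeffs: list[float] = []
    for t in _TYPE_ORDER:
        for idx, coef in entries[t]:
            variables.append((t, idx))
            coeffs.append(coef)
    var_pos = {v: i for i, v in enumerate(variables)}

    prob = InferenceProblem(
        variables=variables,
        coeffs=np.asarray(coeffs, dtype=float),
        constraints=SCOPE_CONSTRAINTS[scope],
        sizes=(n_p, n_r, n_rr),
    )
    for k, p in enumerate(cands.phrases):
        d = {}
        if ("tr", k) in var_pos:
            d["tr"] = var_pos[("tr", k)]
        if ("lm", k) in var_pos:
            d["lm"] = var_pos[("lm", k)]
        if ("nrol", k) in var_pos:
            d["nrol"] = var_pos[("nrol", k)]
        if d:
            prob.phrase_vars[k] = d
    for i, rel in enumerate(cands.relations):
        if ("loc", i) in var_pos:
            prob.relation_vars[i] = {
                "loc": var_pos[("loc", i)],
                "nloc": var_pos[("nloc", i)],
            }
            prob.relation_args[i] = (rel.bacterium.id, rel.habitat.id)
    for j, pair in enumerate(cands.relation_pairs):
        if ("rr", j) in var_pos:
            prob.rr_vars[j] = var_pos[("rr", j)]
            prob.rr_links[j] = (pair.first.id, pair.second.id)
    return prob


def _constraint_rows(prob: InferenceProblem) -> tuple[np.ndarray, np.ndarray]:
    """(A_eq, A_ub) dense rows; A_eq x = 1, A_ub x <= 0."""
    n = prob.n_vars
    eq_rows = []
    ub_rows = []
    if "entity_exclusivity" in prob.constraints:
        for d in prob.phrase_vars.values():
            row = np.zeros(n)
            for pos in d.values():
                row[pos] = 1.0
            eq_rows.append(row)
    if "relation_exclusivity" in prob.constraints:
        for d in prob.relation_vars.values():
            row = np.zeros(n)
            row[d["loc"]] = 1.0
            row[d["nloc"]] = 1.0
            eq_rows.append(row)
    if "role_link" in prob.constraints:
        for i, d in prob.relation_vars.items():
            b, h = prob.relation_args[i]
            for arg_type, arg_idx in (("tr", b), ("lm", h)):
                row = np.zeros(n)
                row[d["loc"]] = 1.0
                row[prob.phrase_vars[arg_idx][arg_type]] = -1.0
                ub_rows.append(row)
    if "rr_link" in prob.constraints:
        for j, pos in prob.rr_vars.items():
            r1, r2 = prob.rr_links[j]
            for r in (r1, r2):
                row = np.zeros(n)
                row[pos] = 1.0
                row[prob.relation_vars[r]["loc"]] = -1.0
                ub_rows.append(row)
    A_eq = np.array(eq_rows) if eq_rows else np.zeros((0, n))
    A_ub = np.array(ub_rows) if ub_rows else np.zeros((0, n))
    return A_eq, A_ub


def assignment_satisfies(prob: InferenceProblem, x: np.ndarray) -> bool:
    """Constraint check independent of the solver."""
    A_eq, A_ub = _constraint_rows(prob)
    x = np.asarray(x, dtype=float)
    if A_eq.size and not np.allclose(A_eq @ x, 1.0):
        return False
    if A_ub.size and (A_ub @ x > 1e-9).any():
        return False
    return bool(np.all((np.round(x) == 0) | (np.round(x) == 1)))


_MILP_OPTIONS = {"mip_rel_gap": 0.0}


def _milp_solve(
    c: np.ndarray,
    A_eq: np.ndarray,
    A_ub: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
) -> Optional[np.ndarray]:
    """Maximize c.x over the feasible binaries; None when infeasible."""
    n = len(c)
    constraints = []
    if A_eq.size:
        constraints.append(LinearConstraint(A_eq, 1.0, 1.0))
    if A_ub.size:
        constraints.append(LinearConstraint(A_ub, -np.inf, 0.0))
    res = milp(
        c=-c,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(lb, ub),
        options=_MILP_OPTIONS,
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise InferenceError(f"solver failure: {res.message}")
    return np.round(res.x).astype(np.int64)


def solve(prob: InferenceProblem, lexicographic: bool = True) -> LabelAssignment:
    """Exact constrained argmax with deterministic tie-breaking.

    With ``lexicographic=True`` (default) the returned assignment is, among
    all optima, the lexicographically smallest variable vector in canonical
    order: after the first solve, variables are fixed to 0 one at a time
    whenever doing so preserves the optimal value.  Training's inner loop
    disables this (any optimum is a most-violated output).
    """
    n = prob.n_vars
    if n == 0:
        return prob.to_assignment(np.zeros(0))
    A_eq, A_ub = _constraint_rows(prob)
    lb = np.zeros(n)
    ub = np.ones(n)
    x = _milp_solve(prob.coeffs, A_eq, A_ub, lb, ub)
    if x is None:
        raise InferenceError("inference problem infeasible")
    if not lexicographic:
        return prob.to_assignment(x)
    best = float(prob.coeffs @ x)
    tol = 1e-9 * (1.0 + abs(best))
    for i in range(n):
        if x[i] == 0:
            ub[i] = 0.0  # already consistent with preferring 0 here
            continue
        ub[i] = 0.0
        trial = _milp_solve(prob.coeffs, A_eq, A_ub, lb, ub)
        if trial is not None and float(prob.coeffs @ trial) >= best - tol:
            x = trial
        else:
            ub[i] = 1.0
            lb[i] = 1.0
    return prob.to_assignment(x)


def brute_force_argmax(
    prob: InferenceProblem, max_vars: int = 24
) -> LabelAssignment:
    """Exhaustive enumeration over feasible assignments (validation oracle).

    Same objective and tie-breaking contract as :func:`solve`; refuses
    problems with more than ``max_vars`` variables.
    """
    import itertools

    n = prob.n_vars
    if n > max_vars:
        raise ProblemSizeError(f"{n} variables exceed the brute-force cap {max_vars}")
    if n == 0:
        return prob.to_assignment(np.zeros(0))

    groups: list[list[np.ndarray]] = []  # candidate partial vectors per group
    grouped_positions: set[int] = set()

    def unit_options(positions: list[int], exclusive: bool) -> list[np.ndarray]:
        opts = []
        combos = (
            [tuple(1 if i == j else 0 for i in range(len(positions))) for j in range(len(positions))]
            if exclusive
            else list(itertools.product((0, 1), repeat=len(positions)))
        )
        for combo in combos:
            v = np.zeros(n, dtype=np.int64)
            for pos, val in zip(positions, combo):
                v[pos] = val
            opts.append(v)
        return opts

    if prob.phrase_vars:
        exclusive = "entity_exclusivity" in prob.constraints
        for d in prob.phrase_vars.values():
            groups.append(unit_options(list(d.values()), exclusive))
            grouped_positions.update(d.values())
    if prob.relation_vars:
        exclusive = "relation_exclusivity" in prob.constraints
        for d in prob.relation_vars.values():
            groups.append(unit_options([d["loc"], d["nloc"]], exclusive))
            grouped_positions.update(d.values())
    for pos in prob.rr_vars.values():
        groups.append(unit_options([pos], exclusive=False))
        grouped_positions.add(pos)
    assert len(grouped_positions) == n

    best_obj = -np.inf
    best_vec: Optional[tuple[int, ...]] = None
    for parts in itertools.product(*groups):
        x = np.sum(parts, axis=0)
        if "role_link" in prob.constraints:
            ok = True
            for i, d in prob.relation_vars.items():
                b, h = prob.relation_args[i]
                if x[d["loc"]] and (
                    not x[prob.phrase_vars[b]["tr"]]
                    or not x[prob.phrase_vars[h]["lm"]]
                ):
                    ok = False
                    break
            if not ok:
                continue
        if "rr_link" in prob.constraints:
            ok = True
            for j, pos in prob.rr_vars.items():
                r1, r2 = prob.rr_links[j]
                if x[pos] and (
                    not x[prob.relation_vars[r1]["loc"]]
                    or not x[prob.relation_vars[r2]["loc"]]
                ):
                    ok = False
                    break
            if not ok:
                continue
        obj = float(prob.coeffs @ x)
        vec = tuple(int(v) for v in x)
        if obj > best_obj or (obj == best_obj and (best_vec is None or vec < best_vec)):
            best_obj = obj
            best_vec = vec
    if best_vec is None:
        raise InferenceError("no feasible assignment")
    return prob.to_assignment(np.asarray(best_vec))
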