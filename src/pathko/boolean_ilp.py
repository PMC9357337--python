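"""Integer linear program encoding the Boolean semantics of a pathway.

Every entity *i* carries a binary activity variable ``E_i``. The constraint
system translates each interaction family into linear inequalities:

component (AND)
    ``E_i >= sum(E_b) - (N - 1)`` and ``N * E_i <= sum(E_b)`` over the
    component parents, so the child is active iff every component is.
member (OR)
    ``N * E_i >= sum(E_b)`` and ``E_i <= sum(E_b)``, so the child is active
    iff at least one member is.
activation/inhibition balance
    an integer variable ``F_i = sum(E_b, b in activators) - sum(E_b, b in
    inhibitors)`` and the big-M switch ``M * (E_i - 1) <= F_i - w``. With
    integer ``F_i`` and any weight ``0.5 < w <= 1`` this forces ``E_i = 0``
    whenever inhibitors outweigh-or-tie activators, and leaves ``E_i``
    unconstrained otherwise (activation is necessary, not sufficient). The
    balance pair is imposed only on complexes and abstracts — genes are
    network entries whose global regulation individual pathways do not
    capture.

One problem instance fixes a single forced-active entity ``E_a = 1``
(a complex or abstract standing in for a process the cell must sustain),
optionally a knockout ``E_g = 0``, and minimises the number of lowly
expressed genes active in the solution. :func:`brute_force_min` provides an
independent exhaustive-enumeration oracle for small networks.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .pathway_io import ABSTRACT, COMPLEX, GENE, PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "IlpProblem",
    "IlpSolution",
    "SolverError",
    "OPTIMAL",
    "INFEASIBLE",
    "build_problem",
    "solve",
    "brute_force_min",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"


class SolverError(RuntimeError):
    """The backend failed for a reason other than infeasibility."""


@dataclass(frozen=True)
class ModelConfig:
    """Constants of the constraint system.

    big_m:
        The big-M switch constant of the balance constraint. Must exceed
        the largest parent count plus one so the switch never binds
        spuriously; validated at build time.
    w:
        Activation weight. Any value in (0.5, 1] is semantically identical
        because the balance F_i is integer: activation requires strictly
        more active activators than inhibitors.
    brute_force_cap:
        Maximum entity count accepted by the enumeration oracle.
    """

    big_m: float = 1000.0
    w: float = 0.51
    brute_force_cap: int = 20

    def __post_init__(self) -> None:
        if not 0.5 < self.w <= 1.0:
            raise ValueError(f"w must lie in (0.5, 1], got {self.w}")
        if self.big_m <= 0:
            raise ValueError(f"big_m must be positive, got {self.big_m}")
        if self.brute_force_cap < 1:
            raise ValueError("brute_force_cap must be >= 1")


@dataclass
class IlpProblem:
    """One built (pathway, active, optional knockout) instance.

    Columns 0..n_entities-1 are the binary activity variables ``E_i`` in
    ``entity_index`` order; the remaining columns are the integer balance
    variables ``F_i`` for the entities in ``balance_index``. Inequalities
    are stored as ``a_ub x <= b_ub``; the balance definitions plus the
    forced-active / knockout pins are equalities ``a_eq x = b_eq``.
    """

    network_name: str
    entity_index: dict[str, int]
    balance_index: dict[str, int]
    a_ub: np.ndarray
    b_ub: np.ndarray
    a_eq: np.ndarray
    b_eq: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    objective_genes: tuple[str, ...]
    forced_active: str
    knockout: str | None
    config: ModelConfig

    @property
    def n_variables(self) -> int:
        return len(self.entity_index) + len(self.balance_index)

    @property
    def n_constraints(self) -> int:
        return len(self.b_ub) + len(self.b_eq)

    def to_lp(self) -> str:
        """Render the instance in CPLEX LP text format (for inspection)."""
        names = [""] * self.n_variables
        for e, j in self.entity_index.items():
            names[j] = f"E_{j}"
        for e, j in self.balance_index.items():
            names[j] = f"F_{j}"

        def _expr(row: np.ndarray) -> str:
            terms = []
            for j, coef in enumerate(row):
                if coef == 0:
                    continue
                sign = "+" if coef >= 0 else "-"
                terms.append(f"{sign} {abs(coef):g} {names[j]}")
            return " ".join(terms) or "0"

        lines = ["Minimize", " obj: " + _expr(self.objective), "Subject To"]
        for k, (row, b) in enumerate(zip(self.a_ub, self.b_ub)):
            lines.append(f" c{k}: {_expr(row)} <= {b:g}")
        for k, (row, b) in enumerate(zip(self.a_eq, self.b_eq)):
            lines.append(f" e{k}: {_expr(row)} = {b:g}")
        lines.append("Bounds")
        for j, (lo, hi) in enumerate(zip(self.lower, self.upper)):
            lines.append(f" {lo:g} <= {names[j]} <= {hi:g}")
        lines.append("Generals")
        lines.append(" " + " ".join(names))
        lines.append("End")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IlpSolution:
    """Outcome of one instance.

    Only ``status`` and ``objective_value`` are contract-stable; the
    assignment is one optimum among possibly many and is reported for
    diagnostics only.
    """

    status: str
    objective_value: int | None
    assignment: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.status not in (OPTIMAL, INFEASIBLE):
            raise ValueError(f"unknown status {self.status!r}")


def _validate_instance(
    network: PathwayNetwork,
    active: str,
    knockout: str | None,
) -> None:
    if active not in network:
        raise ValueError(f"{network.name}: unknown entity {active!r}")
    if network.entities[active].entity_class == GENE:
        raise ValueError(
            f"{network.name}: forced active {active!r} must be a complex "
            "or abstract"
        )
    if knockout is not None:
        if knockout not in network:
            raise ValueError(f"{network.name}: unknown entity {knockout!r}")
        if network.entities[knockout].entity_class != GENE:
            raise ValueError(
                f"{network.name}: knockout {knockout!r} must be a gene"
            )


def build_problem(
    network: PathwayNetwork,
    lowly_expressed: Iterable[str],
    active: str,
    knockout: str | None = None,
    config: ModelConfig = ModelConfig(),
) -> IlpProblem:
    """Assemble the constraint system for one instance.

    ``lowly_expressed`` is the set L of lowly expressed genes; the objective
    counts the active members of L that are entities of this network.
    Entities without parents are free binaries (unless forced or knocked
    out).
    """
    _validate_instance(network, active, knockout)
    lowly = frozenset(lowly_expressed)

    ids = sorted(network.entities)
    entity_index = {e: j for j, e in enumerate(ids)}

    parent_sets = {e: network.parents(e) for e in ids}
    max_parents = max((p.n for p in parent_sets.values()), default=0)
    if config.big_m <= max_parents + 1:
        raise ValueError(
            f"big_m={config.big_m} must exceed the maximum parent count "
            f"plus one ({max_parents + 1})"
        )

    balance_ids = [
        e
        for e in ids
        if network.entities[e].entity_class in (COMPLEX, ABSTRACT)
        and (parent_sets[e].activators or parent_sets[e].inhibitors)
    ]
    n_ent = len(ids)
    balance_index = {e: n_ent + j for j, e in enumerate(balance_ids)}
    n_var = n_ent + len(balance_ids)

    rows_ub: list[np.ndarray] = []
    b_ub: list[float] = []
    rows_eq: list[np.ndarray] = []
    b_eq: list[float] = []

    def _row() -> np.ndarray:
        return np.zeros(n_var)

    for e in ids:
        i = entity_index[e]
        p = parent_sets[e]
        if p.component:
            cols = [entity_index[b] for b in p.component]
            n = len(cols)
            # E_i >= sum(E_b) - (N - 1)
            row = _row()
            row[cols] = 1.0
            row[i] = -1.0
            rows_ub.append(row)
            b_ub.append(n - 1)
            # N * E_i <= sum(E_b)
            row = _row()
            row[i] = n
            row[cols] = row[cols] - 1.0
            rows_ub.append(row)
            b_ub.append(0.0)
        if p.member:
            cols = [entity_index[b] for b in p.member]
            n = len(cols)
            # N * E_i >= sum(E_b)
            row = _row()
            row[cols] = 1.0
            row[i] = row[i] - n
            rows_ub.append(row)
            b_ub.append(0.0)
            # E_i <= sum(E_b)
            row = _row()
            row[i] = 1.0
            row[cols] = row[cols] - 1.0
            rows_ub.append(row)
            b_ub.append(0.0)
        if e in balance_index:
            f = balance_index[e]
            # F_i = sum(activators) - sum(inhibitors)
            row = _row()
            row[f] = 1.0
            for b in p.activators:
                row[entity_index[b]] -= 1.0
            for b in p.inhibitors:
                row[entity_index[b]] += 1.0
            rows_eq.append(row)
            b_eq.append(0.0)
            # M * (E_i - 1) <= F_i - w
            row = _row()
            row[i] = config.big_m
            row[f] = -1.0
            rows_ub.append(row)
            b_ub.append(config.big_m - config.w)

    # forced active and optional knockout, as explicit equality pins
    row = _row()
    row[entity_index[active]] = 1.0
    rows_eq.append(row)
    b_eq.append(1.0)
    if knockout is not None:
        row = _row()
        row[entity_index[knockout]] = 1.0
        rows_eq.append(row)
        b_eq.append(0.0)

    lower = np.zeros(n_var)
    upper = np.ones(n_var)
    for e, f in balance_index.items():
        lower[f] = -len(parent_sets[e].inhibitors)
        upper[f] = len(parent_sets[e].activators)

    objective_genes = tuple(
        g for g in network.genes if g in lowly
    )
    objective = np.zeros(n_var)
    for g in objective_genes:
        objective[entity_index[g]] = 1.0

    if network.has_cycles():
        logger.debug("%s: network contains cycles", network.name)

    def _mat(rows: list[np.ndarray], width: int) -> np.ndarray:
        return np.array(rows) if rows else np.empty((0, width))

    return IlpProblem(
        network_name=network.name,
        entity_index=entity_index,
        balance_index=balance_index,
        a_ub=_mat(rows_ub, n_var),
        b_ub=np.array(b_ub),
        a_eq=_mat(rows_eq, n_var),
        b_eq=np.array(b_eq),
        lower=lower,
        upper=upper,
        objective=objective,
        objective_genes=objective_genes,
        forced_active=active,
        knockout=knockout,
        config=config,
    )


def solve(problem: IlpProblem) -> IlpSolution:
    """Solve one instance exactly (HiGHS branch-and-cut via scipy).

    Returns the optimal objective value (the minimum number of lowly
    expressed genes active) or infeasible status. Any other backend outcome
    raises :class:`SolverError`.
    """
    constraints = []
    if len(problem.b_ub):
        constraints.append(
            LinearConstraint(problem.a_ub, -np.inf, problem.b_ub)
        )
    if len(problem.b_eq):
        constraints.append(
            LinearConstraint(problem.a_eq, problem.b_eq, problem.b_eq)
        )
    res = milp(
        c=problem.objective,
        constraints=constraints,
        integrality=np.ones(problem.n_variables),
        bounds=Bounds(problem.lower, problem.upper),
    )
    if res.status == 2:
        return IlpSolution(INFEASIBLE, None, {})
    if res.status != 0 or res.x is None:
        raise SolverError(
            f"{problem.network_name}: solver failed "
            f"(status {res.status}: {res.message})"
        )
    x = np.rint(res.x).astype(int)
    assignment = {e: int(x[j]) for e, j in problem.entity_index.items()}
    return IlpSolution(OPTIMAL, int(round(res.fun)), assignment)


def brute_force_min(
    network: PathwayNetwork,
    lowly_expressed: Iterable[str],
    active: str,
    knockout: str | None = None,
    config: ModelConfig = ModelConfig(),
) -> IlpSolution:
    """Exhaustive Boolean enumeration oracle for small networks.

    Enumerates all 2^n activity assignments, keeps those satisfying the
    component/member/balance semantics (with the balance F_i recomputed
    directly from the activator and inhibitor sets), the forced active and
    the optional knockout, and returns the minimum count of active lowly
    expressed genes. Independent of the constraint-matrix builder by
    construction; used to cross-check :func:`solve`.
    """
    _validate_instance(network, active, knockout)
    ids = sorted(network.entities)
    n = len(ids)
    if n > config.brute_force_cap:
        raise ValueError(
            f"{network.name}: {n} entities exceeds the enumeration cap "
            f"({config.brute_force_cap})"
        )
    lowly = frozenset(lowly_expressed)
    idx = {e: j for j, e in enumerate(ids)}

    states = np.array(
        list(itertools.product((0, 1), repeat=n)), dtype=np.int8
    ).reshape(-1, n)
    feasible = np.ones(len(states), dtype=bool)
    for e in ids:
        i = idx[e]
        p = network.parents(e)
        child = states[:, i].astype(np.int64)
        if p.component:
            cols = [idx[b] for b in p.component]
            total = states[:, cols].sum(axis=1)
            feasible &= child >= total - (len(cols) - 1)
            feasible &= len(cols) * child <= total
        if p.member:
            cols = [idx[b] for b in p.member]
            total = states[:, cols].sum(axis=1)
            feasible &= len(cols) * child >= total
            feasible &= child <= total
        if network.entities[e].entity_class in (COMPLEX, ABSTRACT) and (
            p.activators or p.inhibitors
        ):
            balance = states[:, [idx[b] for b in p.activators]].sum(axis=1) - states[
                :, [idx[b] for b in p.inhibitors]
            ].sum(axis=1)
            feasible &= config.big_m * (child - 1) <= balance - config.w
    feasible &= states[:, idx[active]] == 1
    if knockout is not None:
        feasible &= states[:, idx[knockout]] == 0

    lowly_cols = [
        idx[g] for g in network.genes if g in lowly
    ]
    cost = (
        states[:, lowly_cols].sum(axis=1)
        if lowly_cols
        else np.zeros(len(states), dtype=np.int64)
    )
    hits = np.flatnonzero(feasible)
    if not len(hits):
        return IlpSolution(INFEASIBLE, None, {})
    best = hits[np.argmin(cost[hits])]
    assignment = {e: int(states[best, idx[e]]) for e in ids}
    return IlpSolution(OPTIMAL, int(cost[best]), assignment)
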