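"""Flux balance analysis and related LP operations.

All operations assemble a sparse LP/MILP from the model's stoichiometry —
steady state (``S v = 0``) over every metabolite, flux bounds per reaction
— and hand it to SciPy's HiGHS interfaces.  Exchange reactions written in
the export direction supply the system boundary, so the balance runs over
all metabolites.

Feasibility/optimality tolerances follow a single package-wide constant,
:data:`TOLERANCE` (1e-6 absolute).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .conditions import ConditionSet
from .errors import OptimizationError, ValidationError
from .generule import GeneRule
from .model import (
    INFEASIBLE,
    MAXIMIZE,
    OPTIMAL,
    UNBOUNDED,
    FluxSolution,
    Model,
    Reaction,
)

#: Absolute feasibility/optimality tolerance used throughout the package.
TOLERANCE = 1e-6

_FWD_SUFFIX = "__fwd"
_BWD_SUFFIX = "__bwd"


class LPData:
    """Assembled LP arrays for one model (internal, shared with analyses)."""

    def __init__(self, model: Model):
        model.validate()
        self.reaction_ids: List[str] = list(model.reactions)
        self.metabolite_ids: List[str] = list(model.metabolites)
        rxn_index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        met_index = {mid: i for i, mid in enumerate(self.metabolite_ids)}
        rows, cols, vals = [], [], []
        for rid, rxn in model.reactions.items():
            j = rxn_index[rid]
            for mid, coef in rxn.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(float(coef))
        self.stoichiometry = sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolite_ids), len(self.reaction_ids)),
        )
        self.bounds = [
            (r.lower_bound, r.upper_bound) for r in model.reactions.values()
        ]
        self.objective = np.array(
            [r.objective_coefficient for r in model.reactions.values()], dtype=float
        )
        self.maximize = model.objective_direction == MAXIMIZE
        self.rxn_index = rxn_index


_STATUS_MAP = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


def _solve(
    data: LPData,
    cost: np.ndarray,
    a_ub: Optional[sparse.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
    extra_eq: Optional[Tuple[sparse.spmatrix, np.ndarray]] = None,
):
    a_eq = data.stoichiometry
    b_eq = np.zeros(a_eq.shape[0])
    if extra_eq is not None:
        a_eq = sparse.vstack([a_eq, extra_eq[0]], format="csr")
        b_eq = np.concatenate([b_eq, np.asarray(extra_eq[1], dtype=float)])
    res = linprog(
        cost,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=data.bounds,
        method="highs",
    )
    status = _STATUS_MAP.get(res.status)
    if status is None:
        raise OptimizationError(
            f"LP solver returned unexpected status: {res.message}", status=res.status
        )
    return status, res


def fba(model: Model) -> FluxSolution:
    """Flux balance analysis: optimize the model objective subject to
    steady state and flux bounds.

    Returns a :class:`FluxSolution`; ``fluxes`` is populated only when the
    problem is optimal.  A structurally invalid model (e.g. a dangling
    metabolite id) raises :class:`ValidationError` before any solve.
    """
    data = LPData(model)
    sign = -1.0 if data.maximize else 1.0
    status, res = _solve(data, sign * data.objective)
    if status != OPTIMAL:
        return FluxSolution(status=status)
    fluxes = dict(zip(data.reaction_ids, (float(v) for v in res.x)))
    return FluxSolution(
        status=OPTIMAL,
        objective_value=float(data.objective @ res.x),
        fluxes=fluxes,
    )


def _objective_row(data: LPData, fraction_of_optimum: float, optimum: float):
    """Inequality row constraining the objective near its optimum."""
    if data.maximize:
        threshold = fraction_of_optimum * optimum
        row = sparse.csr_matrix(-data.objective)
        rhs = np.array([-threshold])
    else:
        threshold = optimum + (1.0 - fraction_of_optimum) * abs(optimum)
        row = sparse.csr_matrix(data.objective)
        rhs = np.array([threshold])
    return row, rhs


def fva(
    model: Model,
    reaction_ids: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 1.0,
) -> Dict[str, Tuple[float, float]]:
    """Flux variability analysis.

    For each requested reaction, minimize and maximize its flux subject to
    the objective staying within ``fraction_of_optimum`` of the FBA
    optimum.  Returns ``{reaction_id: (min, max)}``.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    data = LPData(model)
    if reaction_ids is None:
        reaction_ids = list(data.reaction_ids)
    else:
        reaction_ids = list(reaction_ids)
        missing = [rid for rid in reaction_ids if rid not in data.rxn_index]
        if missing:
            raise ValidationError(f"unknown reaction ids in FVA request: {missing}")
    base = fba(model)
    if not base.is_optimal:
        raise OptimizationError(
            f"FVA requires an optimal base model; FBA status was {base.status!r}",
            status=base.status,
        )
    row, rhs = _objective_row(data, fraction_of_optimum, base.objective_value)
    # Relax by the solver tolerance so the optimum itself stays feasible.
    rhs = rhs + TOLERANCE
    result: Dict[str, Tuple[float, float]] = {}
    n = len(data.reaction_ids)
    for rid in reaction_ids:
        j = data.rxn_index[rid]
        cost = np.zeros(n)
        cost[j] = 1.0
        status_lo, res_lo = _solve(data, cost, a_ub=row, b_ub=rhs)
        status_hi, res_hi = _solve(data, -cost, a_ub=row, b_ub=rhs)
        if status_lo != OPTIMAL or status_hi != OPTIMAL:
            raise OptimizationError(
                f"FVA subproblem for {rid!r} not optimal "
                f"(min: {status_lo}, max: {status_hi})"
            )
        vmin = float(res_lo.x[j])
        vmax = float(res_hi.x[j])
        if vmin > vmax:  # numerical noise at a unique optimum
            vmin = vmax = 0.5 * (vmin + vmax)
        result[rid] = (vmin, vmax)
    return result


def evaluate_gene_rule(rule: GeneRule, inactive_genes: Iterable[str] = ()) -> bool:
    """Evaluate a gene rule with the listed genes inactive (false).

    Unknown gene ids in ``inactive_genes`` are ignored; an empty rule is
    always true (the reaction is not gene-associated).
    """
    if isinstance(rule, str):
        rule = GeneRule.parse(rule)
    return rule.evaluate(inactive_genes)


def knockout_genes(model: Model, gene_ids: Iterable[str]) -> Model:
    """Return a copy in which every reaction whose gene rule evaluates
    false under the knockout has its bounds closed to (0, 0).

    The input model is not modified.  Gene ids absent from ``model.genes``
    raise :class:`ValidationError` listing the offenders.
    """
    gene_ids = set(gene_ids)
    unknown = gene_ids - model.genes
    if unknown:
        raise ValidationError(f"unknown gene ids in knockout set: {sorted(unknown)}")
    new = model.copy()
    for rxn in new.reactions.values():
        if not rxn.gene_rule.evaluate(gene_ids):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return new


def split_reversible(model: Model) -> Tuple[Model, Dict[str, Tuple[str, str]]]:
    """Split every reversible reaction into irreversible forward/backward
    halves.

    A reaction with ``lower_bound < 0`` is replaced by a forward copy with
    bounds ``(0, max(0, ub))`` and a backward copy with reversed
    stoichiometry and bounds ``(max(0, -ub), -lb)``; any original flux v
    maps to ``v_fwd - v_bwd`` and optima are preserved.  Returns the split
    model and ``{original_id: (forward_id, backward_id)}``.
    """
    new = Model(
        id=model.id,
        genes=set(model.genes),
        objective_direction=model.objective_direction,
    )
    new.metabolites = {mid: m.copy() for mid, m in model.metabolites.items()}
    mapping: Dict[str, Tuple[str, str]] = {}
    for rxn in model.reactions.values():
        if not rxn.reversible:
            new.add_reaction(rxn.copy())
            continue
        fwd_id = rxn.id + _FWD_SUFFIX
        bwd_id = rxn.id + _BWD_SUFFIX
        for generated in (fwd_id, bwd_id):
            if generated in model.reactions:
                raise ValidationError(
                    f"cannot split {rxn.id!r}: generated id {generated!r} "
                    "collides with an existing reaction"
                )
        fwd = Reaction(
            id=fwd_id,
            stoichiometry=dict(rxn.stoichiometry),
            lower_bound=0.0,
            upper_bound=max(0.0, rxn.upper_bound),
            gene_rule=rxn.gene_rule,
            objective_coefficient=rxn.objective_coefficient,
            name=rxn.name,
            is_exchange=rxn.is_exchange,
        )
        bwd = Reaction(
            id=bwd_id,
            stoichiometry={mid: -c for mid, c in rxn.stoichiometry.items()},
            lower_bound=max(0.0, -rxn.upper_bound),
            upper_bound=-rxn.lower_bound,
            gene_rule=rxn.gene_rule,
            objective_coefficient=-rxn.objective_coefficient,
            name=rxn.name,
            is_exchange=rxn.is_exchange,
        )
        new.add_reaction(fwd)
        new.add_reaction(bwd)
        mapping[rxn.id] = (fwd_id, bwd_id)
    return new, mapping


def merge_split_fluxes(
    fluxes: Dict[str, float], mapping: Dict[str, Tuple[str, str]]
) -> Dict[str, float]:
    """Map fluxes of a split model back to original reaction ids
    (``v = v_fwd - v_bwd``)."""
    merged: Dict[str, float] = {}
    split_ids = {sid for pair in mapping.values() for sid in pair}
    for rid, value in fluxes.items():
        if rid not in split_ids:
            merged[rid] = value
    for rid, (fwd_id, bwd_id) in mapping.items():
        merged[rid] = fluxes[fwd_id] - fluxes[bwd_id]
    return merged


def apply_conditions(model: Model, conditions: ConditionSet) -> Model:
    """Return a copy with the condition set's exchange bounds applied.

    Every reaction id listed in the condition set must exist in the model;
    unknown ids raise :class:`ValidationError` listing the offenders.
    """
    conditions.validate()
    unknown = [rid for rid in conditions.exchange_bounds if rid not in model.reactions]
    if unknown:
        raise ValidationError(
            f"condition set {conditions.id!r} references unknown reactions "
            f"{sorted(unknown)}"
        )
    new = model.copy()
    for rid, (lo, hi) in conditions.exchange_bounds.items():
        rxn = new.reactions[rid]
        rxn.lower_bound = float(lo)
        rxn.upper_bound = float(hi)
    return new
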