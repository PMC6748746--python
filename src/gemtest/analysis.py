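"""Model validation analyses.

The reusable computations behind project test cases:

* :func:`energetic_consistency_check` — the thermodynamic-inconsistency
  diagnostic: close all uptake, force the ATPase to carry flux 1, and ask
  whether the model can still balance.  A feasible solution means an
  internal cycle is performing work for free.
* :func:`flux_minimization` — fix biomass, split reversible reactions and
  minimize total enzymatic flux (a proxy for minimal protein investment).
* :func:`essential_genes` / :func:`compare_essentiality` — single-gene
  knockout screening and the confusion-matrix comparison against observed
  (e.g. transposon-insertion, TraDIS-style) essentiality calls.
* :func:`product_scan` — maximal export of candidate products under a
  growth condition.
* :func:`minimize_active_reactions` — MILP: smallest number of reactions
  that still supports the required biomass yield (big-M indicator
  formulation).
* :func:`fva_against_measurements` — FVA ranges vs measured flux
  intervals, the assertion body of data-driven tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .conditions import ConditionSet
from .errors import DiagnosticError, OptimizationError, ValidationError
from .model import MAXIMIZE, OPTIMAL, FluxSolution, Model
from .optimize import (
    LPData,
    TOLERANCE,
    _solve,
    apply_conditions,
    fba,
    fva,
    knockout_genes,
    merge_split_fluxes,
    split_reversible,
)

#: Default growth threshold below which a knockout is called lethal
#: (absolute objective units).
ESSENTIALITY_THRESHOLD = 1e-6


@dataclass
class EssentialityResult:
    """Outcome of a single-gene knockout screen."""

    essential_genes: Set[str]
    growth_by_gene: Dict[str, float]
    wild_type_objective: float
    threshold: float


@dataclass
class ConsistencyDiagnosis:
    """Outcome of the energetic-consistency diagnostic.

    ``consistent`` is False iff a witness exists: a feasible flux
    distribution driving the ATPase with all uptake closed.
    """

    consistent: bool
    witness: Optional[FluxSolution] = None


def energetic_consistency_check(
    model: Model, atpase_id: str, close_transporters: bool = False
) -> ConsistencyDiagnosis:
    """Diagnose thermodynamically infeasible internal cycles.

    A copy of the model has every exchange uptake closed (exchange lower
    bounds raised to at least 0) and the ATPase fixed to flux exactly 1;
    the zero-objective feasibility LP is then solved.  Infeasibility
    proves no free-energy cycle can drive the ATPase — the model is
    energetically consistent.  A feasible solution is returned as the
    witness for manual inspection.

    ``close_transporters=True`` additionally closes the reverse direction
    of every multi-compartment (transport) reaction, for models whose
    boundary is not expressed purely through exchange reactions.
    """
    if atpase_id not in model.reactions:
        raise DiagnosticError(f"ATPase reaction {atpase_id!r} not in model")
    work = model.copy()
    for rxn in work.reactions.values():
        rxn.objective_coefficient = 0.0
        if rxn.is_exchange:
            rxn.lower_bound = max(0.0, rxn.lower_bound)
        elif close_transporters:
            compartments = {
                work.metabolites[mid].compartment for mid in rxn.stoichiometry
            }
            if len(compartments) > 1:
                rxn.lower_bound = max(0.0, rxn.lower_bound)
    atpase = work.reactions[atpase_id]
    if not atpase.lower_bound <= 1.0 <= atpase.upper_bound:
        raise DiagnosticError(
            f"diagnostic setup failure: cannot fix ATPase {atpase_id!r} to "
            f"flux 1 outside its bounds "
            f"({atpase.lower_bound}, {atpase.upper_bound})"
        )
    atpase.lower_bound = 1.0
    atpase.upper_bound = 1.0
    solution = fba(work)
    if solution.is_optimal:
        return ConsistencyDiagnosis(consistent=False, witness=solution)
    return ConsistencyDiagnosis(consistent=True, witness=None)


def flux_minimization(
    model: Model,
    objective_fixed_fraction: float = 1.0,
    enzymatic_ids: Optional[Iterable[str]] = None,
) -> Tuple[float, FluxSolution]:
    """Minimize total enzymatic flux at a fixed biomass yield.

    The model objective is fixed at ``objective_fixed_fraction`` times its
    FBA optimum, reversible reactions are split into irreversible halves,
    and the sum of fluxes over the enzymatic reactions is minimized.
    ``enzymatic_ids`` defaults to every non-exchange reaction (the biomass
    pseudo-reaction included).  Returns the minimal total and a witnessing
    solution mapped back to original reaction ids.
    """
    base = fba(model)
    if not base.is_optimal:
        raise OptimizationError(
            f"flux minimization requires an optimal model; FBA status was "
            f"{base.status!r}",
            status=base.status,
        )
    target = objective_fixed_fraction * base.objective_value
    if enzymatic_ids is None:
        enzymatic = {rid for rid, r in model.reactions.items() if not r.is_exchange}
    else:
        enzymatic = set(enzymatic_ids)
        unknown = enzymatic - set(model.reactions)
        if unknown:
            raise ValidationError(
                f"unknown enzymatic reaction ids: {sorted(unknown)}"
            )
    split, mapping = split_reversible(model)
    data = LPData(split)
    n = len(data.reaction_ids)

    def original_id(rid: str) -> str:
        for orig, (fwd, bwd) in mapping.items():
            if rid in (fwd, bwd):
                return orig
        return rid

    cost = np.zeros(n)
    for j, rid in enumerate(data.reaction_ids):
        if original_id(rid) in enzymatic:
            cost[j] = 1.0
    fix_row = sparse.csr_matrix(data.objective)
    status, res = _solve(
        data, cost, extra_eq=(fix_row, np.array([target]))
    )
    if status != OPTIMAL:
        raise OptimizationError(
            f"model infeasible with objective fixed at {target:g} "
            f"(fraction {objective_fixed_fraction})",
            status=status,
        )
    fluxes = merge_split_fluxes(
        dict(zip(data.reaction_ids, (float(v) for v in res.x))), mapping
    )
    total = float(res.fun)
    return total, FluxSolution(status=OPTIMAL, objective_value=total, fluxes=fluxes)


def essential_genes(
    model: Model, threshold: float = ESSENTIALITY_THRESHOLD
) -> EssentialityResult:
    """Single-gene knockout screen over every declared gene.

    A gene is essential iff the FBA optimum after its knockout falls
    below ``threshold`` (an infeasible knockout counts as zero growth).
    Raises if the wild type itself does not grow above the threshold.
    """
    wild = fba(model)
    if not wild.is_optimal or wild.objective_value <= threshold:
        raise OptimizationError(
            "model does not grow; essentiality undefined "
            f"(wild-type status {wild.status!r}, objective "
            f"{wild.objective_value:g}, threshold {threshold:g})"
        )
    growth: Dict[str, float] = {}
    for gene in sorted(model.genes):
        mutant = knockout_genes(model, {gene})
        solution = fba(mutant)
        growth[gene] = solution.objective_value if solution.is_optimal else 0.0
    essential = {g for g, v in growth.items() if v < threshold}
    return EssentialityResult(
        essential_genes=essential,
        growth_by_gene=growth,
        wild_type_objective=wild.objective_value,
        threshold=threshold,
    )


def compare_essentiality(
    result: EssentialityResult,
    observed_essential: Set[str],
    observed_nonessential: Set[str],
) -> Dict[str, int]:
    """Confusion counts of predicted vs observed essentiality.

    Genes absent from both observed sets are ignored; overlapping
    observed sets are an error.
    """
    observed_essential = set(observed_essential)
    observed_nonessential = set(observed_nonessential)
    overlap = observed_essential & observed_nonessential
    if overlap:
        raise ValidationError(
            f"genes {sorted(overlap)} appear in both observed sets"
        )
    predicted = result.essential_genes
    return {
        "TP": len(predicted & observed_essential),
        "FP": len(predicted & observed_nonessential),
        "TN": len(observed_nonessential - predicted),
        "FN": len(observed_essential - predicted),
    }


def product_scan(
    model: Model,
    product_exchange_ids: Iterable[str],
    conditions: Optional[ConditionSet] = None,
    open_bound: float = 1000.0,
) -> Dict[str, float]:
    """Maximal export flux for each candidate product exchange.

    For each listed exchange the scan opens its export upper bound (to
    ``open_bound`` if currently tighter), sets it as the sole maximization
    objective and solves; everything else is left untouched.  A value of
    0 means the product is not producible under the given conditions.
    """
    product_exchange_ids = list(product_exchange_ids)
    unknown = [rid for rid in product_exchange_ids if rid not in model.reactions]
    if unknown:
        raise ValidationError(f"unknown product exchange ids: {sorted(unknown)}")
    base = apply_conditions(model, conditions) if conditions else model.copy()
    results: Dict[str, float] = {}
    for pid in product_exchange_ids:
        work = base.copy()
        for rxn in work.reactions.values():
            rxn.objective_coefficient = 0.0
        target = work.reactions[pid]
        target.upper_bound = max(target.upper_bound, open_bound)
        target.objective_coefficient = 1.0
        work.objective_direction = MAXIMIZE
        solution = fba(work)
        if not solution.is_optimal:
            raise OptimizationError(
                f"product scan for {pid!r} did not solve "
                f"(status {solution.status!r})",
                status=solution.status,
            )
        value = solution.objective_value
        results[pid] = value if value > TOLERANCE else 0.0
    return results


def minimize_active_reactions(
    model: Model, biomass_fraction: float = 1.0
) -> Tuple[int, Set[str]]:
    """Smallest set of reactions supporting the required biomass yield.

    MILP with one binary indicator per reaction: flux is coupled to its
    indicator by big-M constraints (M = the largest bound magnitude in
    the model), the objective flux is constrained to at least
    ``biomass_fraction`` × the FBA optimum, and the number of active
    indicators is minimized.  Returns the minimal count and one
    witnessing active set.
    """
    base = fba(model)
    if not base.is_optimal:
        raise OptimizationError(
            f"MILP requires an optimal base model; FBA status was "
            f"{base.status!r}",
            status=base.status,
        )
    data = LPData(model)
    n = len(data.reaction_ids)
    big_m = max(
        max(abs(lo), abs(hi)) for lo, hi in data.bounds
    )
    stoich = sparse.hstack(
        [data.stoichiometry, sparse.csr_matrix((data.stoichiometry.shape[0], n))],
        format="csr",
    )
    eye = sparse.eye(n, format="csr")
    m_eye = big_m * eye
    coupling_upper = sparse.hstack([eye, -m_eye], format="csr")  # v - M y <= 0
    coupling_lower = sparse.hstack([-eye, -m_eye], format="csr")  # -v - M y <= 0
    obj_row = sparse.hstack(
        [sparse.csr_matrix(data.objective), sparse.csr_matrix((1, n))], format="csr"
    )
    target = biomass_fraction * base.objective_value
    if data.maximize:
        objective_constraint = LinearConstraint(
            obj_row, lb=target - TOLERANCE, ub=np.inf
        )
    else:
        objective_constraint = LinearConstraint(
            obj_row,
            lb=-np.inf,
            ub=target + (1.0 - biomass_fraction) * abs(target) + TOLERANCE,
        )
    constraints = [
        LinearConstraint(stoich, lb=0.0, ub=0.0),
        LinearConstraint(coupling_upper, lb=-np.inf, ub=0.0),
        LinearConstraint(coupling_lower, lb=-np.inf, ub=0.0),
        objective_constraint,
    ]
    lower = np.array([lo for lo, _ in data.bounds] + [0.0] * n)
    upper = np.array([hi for _, hi in data.bounds] + [1.0] * n)
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    integrality = np.concatenate([np.zeros(n), np.ones(n)])
    res = milp(
        cost,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lower, upper),
    )
    if res.status != 0:
        raise OptimizationError(
            f"MILP did not solve to optimality: {res.message}", status=res.status
        )
    indicators = res.x[n:]
    active = {
        rid for rid, y in zip(data.reaction_ids, indicators) if y > 0.5
    }
    return len(active), active


def fva_against_measurements(
    model: Model,
    measured: Dict[str, Tuple[float, float]],
    fraction_of_optimum: float = 1.0,
) -> Dict[str, dict]:
    """Compare model FVA flux ranges against measured flux intervals.

    For each measured reaction the model range at the given
    fraction-of-optimum is computed and intersected with the measured
    closed interval; ``overlaps`` is True iff the intersection is
    nonempty (interval ends touching counts, to solver tolerance).
    """
    missing = [rid for rid in measured if rid not in model.reactions]
    if missing:
        raise ValidationError(f"measured reaction ids not in model: {sorted(missing)}")
    ranges = fva(model, list(measured), fraction_of_optimum=fraction_of_optimum)
    report: Dict[str, dict] = {}
    for rid, (lo, hi) in measured.items():
        if lo > hi:
            raise ValidationError(
                f"measured interval for {rid!r} inverted ({lo} > {hi})"
            )
        vmin, vmax = ranges[rid]
        overlaps = (lo <= vmax + TOLERANCE) and (vmin <= hi + TOLERANCE)
        report[rid] = {"overlaps": overlaps, "model_range": (vmin, vmax)}
    return report


def read_measured_fluxes(path) -> Dict[str, Tuple[float, float]]:
    """Read a measured-flux interval file.

    Plain text, one reaction per line: ``reaction_id<TAB or spaces>lo hi``.
    Lines starting with ``#`` and blank lines are ignored.
    """
    measured: Dict[str, Tuple[float, float]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'reaction_id lo hi', got {line!r}"
                )
            rid, lo, hi = parts
            measured[rid] = (float(lo), float(hi))
    return measured
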