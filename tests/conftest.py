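"""Shared fixtures and independent oracles.

The oracle helpers build a COBRApy/GLPK problem directly from the raw
fields of a native model — deliberately bypassing the package's own
converter and scipy LP assembly — so objective values can be checked
against a fully independent formulation and solver.
"""

import itertools
import math

import cobra
import pytest

from gemtest import fixtures
from gemtest.model import MAXIMIZE


def build_oracle_cobra(model) -> cobra.Model:
    """Independent conversion of a native model into a COBRApy model."""
    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [
            cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites.values()
        ]
    )
    reactions = [
        cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        for r in model.reactions.values()
    ]
    cm.add_reactions(reactions)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cm.metabolites.get_by_id(mid): c for mid, c in r.stoichiometry.items()}
        )
    objective = {
        cm.reactions.get_by_id(r.id): r.objective_coefficient
        for r in model.reactions.values()
        if r.objective_coefficient
    }
    if objective:
        cm.objective = objective
    cm.objective_direction = "max" if model.objective_direction == MAXIMIZE else "min"
    return cm


def oracle_fba_objective(model):
    """FBA optimum from the independent formulation; None if infeasible."""
    value = build_oracle_cobra(model).slim_optimize(error_value=float("nan"))
    return None if math.isnan(value) else float(value)


def oracle_fva_range(model, reaction_id, fraction_of_optimum=1.0):
    """FVA interval for one reaction from COBRApy's own FVA."""
    from cobra.flux_analysis import flux_variability_analysis

    cm = build_oracle_cobra(model)
    frame = flux_variability_analysis(
        cm, [reaction_id], fraction_of_optimum=fraction_of_optimum
    )
    return float(frame.loc[reaction_id, "minimum"]), float(
        frame.loc[reaction_id, "maximum"]
    )


def oracle_flux_min_total(model, fraction=1.0):
    """Minimal total enzymatic flux from an independent absolute-value LP
    formulation (auxiliary |v| variables on the COBRApy/GLPK problem,
    rather than reversible splitting)."""
    cm = build_oracle_cobra(model)
    optimum = cm.slim_optimize(error_value=float("nan"))
    assert not math.isnan(optimum)
    target = fraction * optimum
    fix = cm.problem.Constraint(
        cm.objective.expression, lb=target - 1e-9, ub=target + 1e-9
    )
    extras = [fix]
    terms = []
    for r in model.reactions.values():
        if r.is_exchange:
            continue
        flux = cm.reactions.get_by_id(r.id).flux_expression
        t = cm.problem.Variable(f"abs_{r.id}", lb=0)
        extras += [
            t,
            cm.problem.Constraint(flux - t, ub=0),
            cm.problem.Constraint(-flux - t, ub=0),
        ]
        terms.append(t)
    cm.add_cons_vars(extras)
    cm.objective = cm.problem.Objective(sum(terms), direction="min")
    value = cm.slim_optimize(error_value=float("nan"))
    assert not math.isnan(value)
    return float(value)


def oracle_min_active_count(model, biomass_fraction=1.0, tol=1e-6):
    """Exhaustive 2^n subset enumeration for the minimal active reaction
    set; only practical for the small fixture networks."""
    cm = build_oracle_cobra(model)
    optimum = cm.slim_optimize(error_value=float("nan"))
    assert not math.isnan(optimum)
    target = biomass_fraction * optimum
    reaction_ids = [r.id for r in cm.reactions]
    saved = {r.id: r.bounds for r in cm.reactions}
    best = len(reaction_ids)
    for size in range(len(reaction_ids) + 1):
        found = False
        for subset in itertools.combinations(reaction_ids, size):
            active = set(subset)
            for rid in reaction_ids:
                rxn = cm.reactions.get_by_id(rid)
                rxn.bounds = saved[rid] if rid in active else (0.0, 0.0)
            value = cm.slim_optimize(error_value=float("nan"))
            if not math.isnan(value) and value >= target - tol:
                found = True
                break
        if found:
            best = size
            break
    for rid in reaction_ids:
        cm.reactions.get_by_id(rid).bounds = saved[rid]
    return best


@pytest.fixture
def toy_parallel():
    return fixtures.make_toy_parallel()


@pytest.fixture
def toy_chain():
    return fixtures.make_toy_chain()


@pytest.fixture
def toy_loop():
    return fixtures.make_toy_loop()


@pytest.fixture
def toy_project(tmp_path, toy_parallel):
    """A scaffolded project around TOY_PARALLEL with the design fixtures
    registered."""
    from gemtest import project as project_module

    config = project_module.create_project(tmp_path / "proj", toy_parallel)
    ko, child = fixtures.make_design_fixtures(toy_parallel)
    project_module.add_design(config, ko)
    project_module.add_design(config, child)
    return config
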