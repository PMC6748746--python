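"""Converters between the native model and COBRApy objects.

Used behind the SBML reader/writer (COBRApy's libsbml-based SBML L3+FBC
support is the community standard) and available to users who want to
hand a materialized design to the wider COBRA ecosystem.

Notes on lossiness: genes reach a COBRApy model only through
gene-reaction rules, so a declared gene that no rule references does not
survive a trip through COBRApy/SBML.  COBRApy's SBML reader reports an
absent species charge as 0, so charge 0 is normalized back to "not
specified" here; a genuinely zero charge is not distinguishable after an
SBML round trip (charge is annotation-only for these analyses).
"""

from __future__ import annotations

import cobra

from .generule import GeneRule
from .model import MAXIMIZE, MINIMIZE, Metabolite, Model, Reaction


def to_cobra(model: Model) -> cobra.Model:
    """Build an equivalent :class:`cobra.Model`."""
    model.validate()
    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [
            cobra.Metabolite(
                m.id,
                name=m.name,
                compartment=m.compartment,
                formula=m.formula,
                charge=m.charge,
            )
            for m in model.metabolites.values()
        ]
    )
    reactions = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(
            rxn.id,
            name=rxn.name,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        reactions.append(cr)
    cm.add_reactions(reactions)
    for rxn in model.reactions.values():
        cr = cm.reactions.get_by_id(rxn.id)
        cr.add_metabolites(
            {cm.metabolites.get_by_id(mid): c for mid, c in rxn.stoichiometry.items()}
        )
        rule = rxn.gene_rule.to_string()
        if rule:
            cr.gene_reaction_rule = rule
    cm.objective = {
        cm.reactions.get_by_id(r.id): r.objective_coefficient
        for r in model.objective_reactions
    }
    cm.objective_direction = "max" if model.objective_direction == MAXIMIZE else "min"
    return cm


def from_cobra(cm: cobra.Model) -> Model:
    """Build a native :class:`Model` from a COBRApy model."""
    model = Model(
        id=cm.id or "model",
        objective_direction=MAXIMIZE if cm.objective_direction == "max" else MINIMIZE,
    )
    for met in cm.metabolites:
        model.add_metabolite(
            Metabolite(
                id=met.id,
                name=met.name or "",
                compartment=met.compartment or "c",
                formula=met.formula or None,
                charge=None if not met.charge else int(met.charge),
            )
        )
    for rxn in cm.reactions:
        model.add_reaction(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gene_rule=GeneRule.parse(rxn.gene_reaction_rule or ""),
                objective_coefficient=float(rxn.objective_coefficient),
                name=rxn.name or "",
            )
        )
    model.genes |= {g.id for g in cm.genes}
    model.validate()
    return model
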