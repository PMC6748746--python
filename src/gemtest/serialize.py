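"""Canonical dict/JSON forms of model components.

Shared by the JSON model dialect and the design-delta documents.  The
serialization is canonical — keys sorted, lists ordered by id, fixed
indentation, trailing newline — so re-saving an unchanged object is
byte-identical and version-control diffs stay minimal.
"""

from __future__ import annotations

import json
from typing import Dict

from .generule import GeneRule
from .model import MAXIMIZE, MINIMIZE, Metabolite, Model, Reaction
from .model import _default_is_exchange  # shared heuristic


#: JSON-schema fragment for one full reaction record.
REACTION_RECORD_SCHEMA = {
    "type": "object",
    "required": ["id", "metabolites", "lower_bound", "upper_bound"],
    "properties": {
        "id": {"type": "string", "minLength": 1},
        "name": {"type": "string"},
        "metabolites": {
            "type": "object",
            "minProperties": 1,
            "additionalProperties": {"type": "number"},
        },
        "lower_bound": {"type": "number"},
        "upper_bound": {"type": "number"},
        "gene_reaction_rule": {"type": "string"},
        "objective_coefficient": {"type": "number"},
        "notes": {"type": "object"},
    },
}

#: JSON-schema fragment for one metabolite record.
METABOLITE_RECORD_SCHEMA = {
    "type": "object",
    "required": ["id"],
    "properties": {
        "id": {"type": "string", "minLength": 1},
        "name": {"type": "string"},
        "compartment": {"type": "string"},
        "formula": {"type": ["string", "null"]},
        "charge": {"type": ["integer", "null"]},
    },
}


def canonical_dumps(obj) -> str:
    """Serialize to canonical JSON text (sorted keys, 2-space indent)."""
    return json.dumps(obj, sort_keys=True, indent=2, separators=(",", ": ")) + "\n"


def metabolite_to_dict(met: Metabolite) -> dict:
    return {
        "id": met.id,
        "name": met.name,
        "compartment": met.compartment,
        "formula": met.formula,
        "charge": met.charge,
    }


def metabolite_from_dict(data: dict) -> Metabolite:
    return Metabolite(
        id=str(data["id"]),
        name=str(data.get("name") or ""),
        compartment=str(data.get("compartment") or "c"),
        formula=data.get("formula"),
        charge=None if data.get("charge") is None else int(data["charge"]),
    )


def reaction_to_dict(rxn: Reaction) -> dict:
    record = {
        "id": rxn.id,
        "name": rxn.name,
        "metabolites": {mid: float(c) for mid, c in sorted(rxn.stoichiometry.items())},
        "lower_bound": float(rxn.lower_bound),
        "upper_bound": float(rxn.upper_bound),
        "gene_reaction_rule": rxn.gene_rule.to_string(),
        "objective_coefficient": float(rxn.objective_coefficient),
    }
    # The exchange flag is derivable from id + stoichiometry by the default
    # heuristic; store it only when it deviates, to keep the COBRA-style
    # records clean while staying lossless.
    if bool(rxn.is_exchange) != _default_is_exchange(rxn.id, rxn.stoichiometry):
        record["notes"] = {"is_exchange": bool(rxn.is_exchange)}
    return record


def reaction_from_dict(data: dict) -> Reaction:
    notes = data.get("notes") or {}
    is_exchange = notes.get("is_exchange")
    return Reaction(
        id=str(data["id"]),
        stoichiometry={str(m): float(c) for m, c in data["metabolites"].items()},
        lower_bound=float(data["lower_bound"]),
        upper_bound=float(data["upper_bound"]),
        gene_rule=GeneRule.parse(data.get("gene_reaction_rule") or ""),
        objective_coefficient=float(data.get("objective_coefficient") or 0.0),
        name=str(data.get("name") or ""),
        is_exchange=None if is_exchange is None else bool(is_exchange),
    )


def model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "version": "1",
        "objective_direction": "max" if model.objective_direction == MAXIMIZE else "min",
        "metabolites": [
            metabolite_to_dict(m)
            for _, m in sorted(model.metabolites.items())
        ],
        "reactions": [
            reaction_to_dict(r) for _, r in sorted(model.reactions.items())
        ],
        "genes": [{"id": g, "name": ""} for g in sorted(model.genes)],
    }


def model_from_dict(data: dict) -> Model:
    model = Model(
        id=str(data.get("id") or "model"),
        objective_direction=(
            MINIMIZE if data.get("objective_direction") == "min" else MAXIMIZE
        ),
    )
    for met in data.get("metabolites", ()):
        model.add_metabolite(metabolite_from_dict(met))
    declared = {str(g["id"]) for g in data.get("genes", ())}
    for rxn in data.get("reactions", ()):
        model.add_reaction(reaction_from_dict(rxn))
    model.genes |= declared
    model.validate()
    return model
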