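"""Strain-design deltas.

A :class:`StrainDesign` stores the *difference* between a wild-type base
model and a derived strain — added/removed/modified reactions,
metabolites and genes, optional embedded growth conditions — instead of a
redundant model copy.  Designs are hereditary: a design may point at a
parent design, and applying it applies the whole ancestor chain
root-first, so curation of the base model automatically propagates into
every derived strain.

Deltas serialize to versioned, canonically formatted JSON documents that
diff cleanly under version control.  This is an id-wise semantic delta,
deliberately *not* a line-level text diff.

A *programmatic* design carries no stored change lists; it is an
executable hook (a ``transform(model)`` function in a project design
file) re-evaluated against the current base model each time it is
applied — useful for transformations, such as MILP reformulations, that
should track future base-model edits automatically.
"""

from __future__ import annotations

import importlib.util
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Union

import jsonschema

from .conditions import ConditionSet
from .errors import DeltaError, ValidationError
from .model import Metabolite, Model, Reaction
from .optimize import apply_conditions
from .serialize import (
    METABOLITE_RECORD_SCHEMA,
    REACTION_RECORD_SCHEMA,
    canonical_dumps,
    metabolite_from_dict,
    metabolite_to_dict,
    reaction_from_dict,
    reaction_to_dict,
)

SCHEMA_VERSION = "1.0"

#: Entry-point function name a programmatic design file must expose.
PROGRAMMATIC_ENTRY_POINT = "transform"

Resolver = Union[None, Dict[str, "StrainDesign"], Callable[[str], "StrainDesign"]]


@dataclass
class StrainDesign:
    """A hierarchical model delta.

    ``reactions_modified`` holds *full replacement records* — a modified
    reaction is specified completely, not as a per-field patch.
    Metabolite additions are upserts (add-or-replace), which is how a
    changed formula or charge is expressed, since there is no separate
    modified list for metabolites.
    """

    id: str
    name: str = ""
    description: str = ""
    parent: Optional[str] = None
    reactions_added: List[Reaction] = field(default_factory=list)
    reactions_removed: List[str] = field(default_factory=list)
    reactions_modified: List[Reaction] = field(default_factory=list)
    metabolites_added: List[Metabolite] = field(default_factory=list)
    metabolites_removed: List[str] = field(default_factory=list)
    genes_added: List[str] = field(default_factory=list)
    genes_removed: List[str] = field(default_factory=list)
    conditions: Optional[ConditionSet] = None
    objective_direction: Optional[str] = None
    is_programmatic: bool = False
    transform: Optional[Callable[[Model], Model]] = None

    def validate(self) -> None:
        if not self.id:
            raise DeltaError("design id must be nonempty")
        added = {r.id for r in self.reactions_added}
        modified = {r.id for r in self.reactions_modified}
        removed = set(self.reactions_removed)
        for a, b, what in (
            (added, removed, "added and removed"),
            (added, modified, "added and modified"),
            (removed, modified, "removed and modified"),
        ):
            clash = a & b
            if clash:
                raise DeltaError(
                    f"design {self.id!r}: reactions {sorted(clash)} appear in "
                    f"both the {what} lists"
                )
        if self.is_programmatic and (
            self.reactions_added
            or self.reactions_removed
            or self.reactions_modified
            or self.metabolites_added
            or self.metabolites_removed
            or self.genes_added
            or self.genes_removed
            or self.conditions is not None
        ):
            raise DeltaError(
                f"design {self.id!r}: a programmatic design must have empty "
                "stored change lists"
            )

    @property
    def is_empty(self) -> bool:
        return not (
            self.is_programmatic
            or self.reactions_added
            or self.reactions_removed
            or self.reactions_modified
            or self.metabolites_added
            or self.metabolites_removed
            or self.genes_added
            or self.genes_removed
            or self.conditions
            or self.objective_direction
        )


@dataclass
class DeltaDocument:
    """Serialized wrapper: schema version plus one design."""

    schema_version: str
    design: StrainDesign


# ---------------------------------------------------------------------------
# diff / apply / flatten

def diff_models(base: Model, modified: Model) -> StrainDesign:
    """Compute the minimal id-wise delta turning ``base`` into ``modified``.

    Shared ids whose records differ in any field produce a full
    replacement entry; field-identical entries never appear.
    """
    base.validate()
    modified.validate()
    design = StrainDesign(
        id=f"diff_{base.id}_to_{modified.id}",
        description=f"Computed difference between {base.id!r} and {modified.id!r}",
    )
    base_rxns, mod_rxns = set(base.reactions), set(modified.reactions)
    design.reactions_added = [
        modified.reactions[rid].copy() for rid in sorted(mod_rxns - base_rxns)
    ]
    design.reactions_removed = sorted(base_rxns - mod_rxns)
    design.reactions_modified = [
        modified.reactions[rid].copy()
        for rid in sorted(base_rxns & mod_rxns)
        if not base.reactions[rid].equals(modified.reactions[rid])
    ]
    base_mets, mod_mets = set(base.metabolites), set(modified.metabolites)
    changed_mets = {
        mid
        for mid in base_mets & mod_mets
        if metabolite_to_dict(base.metabolites[mid])
        != metabolite_to_dict(modified.metabolites[mid])
    }
    design.metabolites_added = [
        modified.metabolites[mid].copy()
        for mid in sorted((mod_mets - base_mets) | changed_mets)
    ]
    design.metabolites_removed = sorted(base_mets - mod_mets)
    design.genes_added = sorted(modified.genes - base.genes)
    design.genes_removed = sorted(base.genes - modified.genes)
    if base.objective_direction != modified.objective_direction:
        design.objective_direction = modified.objective_direction
    design.validate()
    return design


def _resolve(resolver: Resolver, design_id: str, for_design: str) -> StrainDesign:
    if resolver is None:
        raise DeltaError(
            f"design {for_design!r} has parent {design_id!r} but no resolver "
            "was provided"
        )
    try:
        if isinstance(resolver, dict):
            return resolver[design_id]
        return resolver(design_id)
    except DeltaError:
        raise
    except Exception as exc:
        raise DeltaError(
            f"cannot resolve parent design {design_id!r} "
            f"(required by {for_design!r}): {exc}"
        ) from exc


def resolve_chain(design: StrainDesign, resolver: Resolver) -> List[StrainDesign]:
    """Ancestor chain root-first, ending with ``design``; cycles raise."""
    chain = [design]
    seen = {design.id}
    current = design
    while current.parent is not None:
        parent = _resolve(resolver, current.parent, current.id)
        if parent.id in seen:
            raise DeltaError(
                f"cycle in design parent chain at {parent.id!r} "
                f"(while resolving {design.id!r})"
            )
        chain.append(parent)
        seen.add(parent.id)
        current = parent
    chain.reverse()
    return chain


def _apply_one(model: Model, design: StrainDesign) -> Model:
    design.validate()
    if design.is_programmatic:
        if design.transform is None:
            raise DeltaError(
                f"programmatic design {design.id!r} has no loaded transform; "
                "load it with load_programmatic_design"
            )
        try:
            result = design.transform(model.copy())
        except Exception as exc:
            raise DeltaError(
                f"programmatic design {design.id!r} raised: {exc}"
            ) from exc
        if not isinstance(result, Model):
            raise DeltaError(
                f"programmatic design {design.id!r} did not return a Model"
            )
        return result

    def fail(message: str):
        raise DeltaError(f"design {design.id!r}: {message}")

    # removals (reactions first; metabolite/gene removals are checked after
    # modifications, since a replacement record in the same delta may drop
    # the reference that would otherwise block them)
    for rid in design.reactions_removed:
        if rid not in model.reactions:
            fail(f"cannot remove unknown reaction {rid!r}")
        model.remove_reaction(rid)
    # additions (metabolite additions are upserts)
    for met in design.metabolites_added:
        if met.id in model.metabolites:
            model.metabolites[met.id] = met.copy()
        else:
            model.add_metabolite(met.copy())
    for gid in design.genes_added:
        model.genes.add(gid)
    for rxn in design.reactions_added:
        if rxn.id in model.reactions:
            fail(f"cannot add reaction {rxn.id!r}: id already present")
        model.add_reaction(rxn.copy())
    # modifications (full replacement)
    for rxn in design.reactions_modified:
        if rxn.id not in model.reactions:
            fail(f"cannot modify unknown reaction {rxn.id!r}")
        model.reactions[rxn.id] = rxn.copy()
        model.genes |= rxn.gene_rule.genes
    # deferred removals
    for mid in design.metabolites_removed:
        try:
            model.remove_metabolite(mid)
        except ValidationError as exc:
            fail(str(exc))
    for gid in design.genes_removed:
        if gid not in model.genes:
            fail(f"cannot remove unknown gene {gid!r}")
        users = [
            r.id for r in model.reactions.values() if gid in r.gene_rule.genes
        ]
        if users:
            fail(
                f"cannot remove gene {gid!r}: still referenced by gene rules "
                f"of {sorted(users)}"
            )
        model.genes.discard(gid)
    if design.objective_direction is not None:
        model.objective_direction = design.objective_direction
    if design.conditions is not None:
        model = apply_conditions(model, design.conditions)
    return model


def apply_design(
    base: Model, design: StrainDesign, resolver: Resolver = None
) -> Model:
    """Materialize a design: apply its ancestor chain root-first, then the
    design itself, to a copy of ``base`` (never mutating it)."""
    model = base.copy()
    for link in resolve_chain(design, resolver):
        model = _apply_one(model, link)
    model.validate()
    return model


def flatten_design(design: StrainDesign, resolver: Resolver = None) -> StrainDesign:
    """Collapse a design chain into one parent-free delta whose application
    equals applying the chain; later changes override earlier ones id-wise.

    Chains containing a programmatic design cannot be flattened (the hook
    is opaque) and raise :class:`DeltaError`.
    """
    chain = resolve_chain(design, resolver)
    if any(d.is_programmatic for d in chain):
        raise DeltaError(
            f"design chain of {design.id!r} contains a programmatic design "
            "and cannot be flattened"
        )

    rxn_ops: Dict[str, tuple] = {}
    met_ops: Dict[str, tuple] = {}
    genes_added: Dict[str, None] = {}
    genes_removed: Dict[str, None] = {}
    merged_bounds: Dict[str, tuple] = {}
    objective_direction: Optional[str] = None

    def fail(d: StrainDesign, message: str):
        raise DeltaError(f"design {d.id!r} (while flattening {design.id!r}): {message}")

    for d in chain:
        d.validate()
        for rid in d.reactions_removed:
            prev = rxn_ops.get(rid)
            if prev is None or prev[0] == "modified":
                rxn_ops[rid] = ("removed",)
            elif prev[0] == "added":
                del rxn_ops[rid]
            else:
                fail(d, f"reaction {rid!r} removed twice in the chain")
            merged_bounds.pop(rid, None)
        for mid in d.metabolites_removed:
            prev = met_ops.get(mid)
            if prev is None:
                met_ops[mid] = ("removed",)
            elif prev[0] == "added":
                del met_ops[mid]
            else:
                fail(d, f"metabolite {mid!r} removed twice in the chain")
        for gid in d.genes_removed:
            if gid in genes_added:
                del genes_added[gid]
            else:
                genes_removed[gid] = None
        for met in d.metabolites_added:
            met_ops[met.id] = ("added", met)
        for gid in d.genes_added:
            genes_removed.pop(gid, None)
            genes_added[gid] = None
        for rxn in d.reactions_added:
            prev = rxn_ops.get(rxn.id)
            if prev is None:
                rxn_ops[rxn.id] = ("added", rxn)
            elif prev[0] == "removed":
                rxn_ops[rxn.id] = ("modified", rxn)  # remove + re-add = replace
            else:
                fail(d, f"reaction {rxn.id!r} added on top of an existing entry")
            merged_bounds.pop(rxn.id, None)
        for rxn in d.reactions_modified:
            prev = rxn_ops.get(rxn.id)
            if prev is None or prev[0] == "modified":
                rxn_ops[rxn.id] = ("modified", rxn)
            elif prev[0] == "added":
                rxn_ops[rxn.id] = ("added", rxn)
            else:
                fail(d, f"reaction {rxn.id!r} modified after removal")
            merged_bounds.pop(rxn.id, None)
        if d.objective_direction is not None:
            objective_direction = d.objective_direction
        if d.conditions is not None:
            for rid, bounds in d.conditions.exchange_bounds.items():
                merged_bounds[rid] = bounds

    flat = StrainDesign(
        id=design.id,
        name=design.name,
        description=design.description,
        objective_direction=objective_direction,
    )
    for rid in sorted(rxn_ops):
        op = rxn_ops[rid]
        if op[0] == "added":
            flat.reactions_added.append(op[1].copy())
        elif op[0] == "removed":
            flat.reactions_removed.append(rid)
        else:
            flat.reactions_modified.append(op[1].copy())
    for mid in sorted(met_ops):
        op = met_ops[mid]
        if op[0] == "added":
            flat.metabolites_added.append(op[1].copy())
        else:
            flat.metabolites_removed.append(mid)
    flat.genes_added = sorted(genes_added)
    flat.genes_removed = sorted(genes_removed)
    if merged_bounds:
        flat.conditions = ConditionSet(
            id=f"{design.id}_conditions",
            exchange_bounds=dict(sorted(merged_bounds.items())),
        )
    flat.validate()
    return flat


# ---------------------------------------------------------------------------
# JSON document serialization

_REACTION_SCHEMA = REACTION_RECORD_SCHEMA
_METABOLITE_SCHEMA = METABOLITE_RECORD_SCHEMA

_CONDITIONS_SCHEMA = {
    "type": "object",
    "properties": {
        "id": {"type": "string"},
        "description": {"type": "string"},
        "exchange_bounds": {
            "type": "object",
            "additionalProperties": {
                "type": "array",
                "items": {"type": "number"},
                "minItems": 2,
                "maxItems": 2,
            },
        },
    },
}

DELTA_SCHEMA = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "Strain design delta document",
    "type": "object",
    "required": ["schema_version", "design"],
    "properties": {
        "schema_version": {"const": SCHEMA_VERSION},
        "design": {
            "type": "object",
            "required": ["id"],
            "properties": {
                "id": {"type": "string", "minLength": 1},
                "name": {"type": "string"},
                "description": {"type": "string"},
                "parent": {"type": ["string", "null"]},
                "reactions_added": {"type": "array", "items": _REACTION_SCHEMA},
                "reactions_removed": {
                    "type": "array",
                    "items": {"type": "string"},
                },
                "reactions_modified": {"type": "array", "items": _REACTION_SCHEMA},
                "metabolites_added": {
                    "type": "array",
                    "items": _METABOLITE_SCHEMA,
                },
                "metabolites_removed": {
                    "type": "array",
                    "items": {"type": "string"},
                },
                "genes_added": {"type": "array", "items": {"type": "string"}},
                "genes_removed": {"type": "array", "items": {"type": "string"}},
                "conditions": {
                    "oneOf": [{"type": "null"}, _CONDITIONS_SCHEMA]
                },
                "objective_direction": {
                    "enum": ["maximize", "minimize", None]
                },
            },
        },
    },
}


def design_to_dict(design: StrainDesign) -> dict:
    if design.is_programmatic:
        raise DeltaError(
            f"programmatic design {design.id!r} cannot be serialized; it is "
            "defined by its executable design file"
        )
    design.validate()
    conditions = None
    if design.conditions is not None:
        conditions = {"id": design.conditions.id, **design.conditions.to_dict()}
    return {
        "id": design.id,
        "name": design.name,
        "description": design.description,
        "parent": design.parent,
        "reactions_added": [
            reaction_to_dict(r)
            for r in sorted(design.reactions_added, key=lambda r: r.id)
        ],
        "reactions_removed": sorted(design.reactions_removed),
        "reactions_modified": [
            reaction_to_dict(r)
            for r in sorted(design.reactions_modified, key=lambda r: r.id)
        ],
        "metabolites_added": [
            metabolite_to_dict(m)
            for m in sorted(design.metabolites_added, key=lambda m: m.id)
        ],
        "metabolites_removed": sorted(design.metabolites_removed),
        "genes_added": sorted(design.genes_added),
        "genes_removed": sorted(design.genes_removed),
        "conditions": conditions,
        "objective_direction": design.objective_direction,
    }


def design_from_dict(data: dict) -> StrainDesign:
    conditions = None
    if data.get("conditions") is not None:
        cdata = data["conditions"]
        conditions = ConditionSet.from_dict(cdata.get("id", "embedded"), cdata)
    design = StrainDesign(
        id=str(data["id"]),
        name=str(data.get("name") or ""),
        description=str(data.get("description") or ""),
        parent=data.get("parent"),
        reactions_added=[reaction_from_dict(r) for r in data.get("reactions_added", ())],
        reactions_removed=[str(r) for r in data.get("reactions_removed", ())],
        reactions_modified=[
            reaction_from_dict(r) for r in data.get("reactions_modified", ())
        ],
        metabolites_added=[
            metabolite_from_dict(m) for m in data.get("metabolites_added", ())
        ],
        metabolites_removed=[str(m) for m in data.get("metabolites_removed", ())],
        genes_added=[str(g) for g in data.get("genes_added", ())],
        genes_removed=[str(g) for g in data.get("genes_removed", ())],
        conditions=conditions,
        objective_direction=data.get("objective_direction"),
    )
    design.validate()
    return design


def validate_delta_document(data: dict) -> None:
    """Validate a raw document against the published schema; raise
    :class:`DeltaError` carrying the JSON-pointer of the violation."""
    validator = jsonschema.Draft202012Validator(DELTA_SCHEMA)
    errors = sorted(validator.iter_errors(data), key=lambda e: list(e.absolute_path))
    if errors:
        first = errors[0]
        pointer = "/" + "/".join(str(p) for p in first.absolute_path)
        raise DeltaError(
            f"design document violates schema {SCHEMA_VERSION} at {pointer!r}: "
            f"{first.message}"
        )


def save_design(design: StrainDesign, path) -> DeltaDocument:
    """Write a design as a canonical JSON document; two saves of the same
    design are byte-identical."""
    document = DeltaDocument(schema_version=SCHEMA_VERSION, design=design)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "design": design_to_dict(design),
    }
    validate_delta_document(payload)
    Path(path).write_text(canonical_dumps(payload))
    return document


def load_design(path) -> StrainDesign:
    """Load and schema-validate a design document; returns the design."""
    import json

    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DeltaError(f"design file {path} is not valid JSON: {exc}") from exc
    validate_delta_document(data)
    return design_from_dict(data["design"])


# ---------------------------------------------------------------------------
# programmatic designs

def load_programmatic_design(project, design_id: str) -> StrainDesign:
    """Load an executable design from a project's designs directory.

    The file ``<designs_dir>/<design_id>.py`` must expose a function
    ``transform(model) -> Model``.  The returned design has
    ``is_programmatic=True`` and dispatches to the hook when applied.
    Hook failures are wrapped in :class:`DeltaError` naming the design.
    """
    designs_dir = Path(getattr(project, "designs_path", project))
    path = designs_dir / f"{design_id}.py"
    if not path.exists():
        raise DeltaError(f"no programmatic design file {path}")
    spec = importlib.util.spec_from_file_location(f"gemtest_design_{design_id}", path)
    module = importlib.util.module_from_spec(spec)
    try:
        spec.loader.exec_module(module)
    except Exception as exc:
        raise DeltaError(f"design file {path} failed to import: {exc}") from exc
    hook = getattr(module, PROGRAMMATIC_ENTRY_POINT, None)
    if not callable(hook):
        raise DeltaError(
            f"design file {path} does not define the entry point "
            f"{PROGRAMMATIC_ENTRY_POINT!r} (a function taking and returning "
            "a Model)"
        )
    return StrainDesign(
        id=design_id,
        name=str(getattr(module, "NAME", design_id)),
        description=(module.__doc__ or "").strip(),
        parent=getattr(module, "PARENT", None),
        is_programmatic=True,
        transform=hook,
    )


def export_design_as_model(
    base: Model,
    design: StrainDesign,
    resolver: Resolver,
    format: str,
    path,
) -> None:
    """Materialize a design against ``base`` and write the full model in
    ``"sbml"`` or ``"json"`` format."""
    from . import io_formats

    model = apply_design(base, design, resolver)
    if format == "json":
        io_formats.write_json_model(model, path)
    elif format == "sbml":
        io_formats.write_sbml(model, path)
    else:
        raise DeltaError(
            f"unsupported export format {format!r}; expected 'sbml' or 'json'"
        )
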