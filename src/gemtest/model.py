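"""Constraint-based model data structures.

The in-memory containers every other module builds on: :class:`Metabolite`,
:class:`Reaction` (with bounds, stoichiometry and a :class:`GeneRule`),
:class:`Model` and :class:`FluxSolution`.

Conventions
-----------
* Fluxes and bounds are in mmol gDW⁻¹ h⁻¹ throughout.
* Stoichiometric coefficients are signed: negative = consumed.
* Exchange reactions are written in the export direction (``M →``), so a
  negative flux (and a negative lower bound) denotes uptake.
* ``is_exchange`` marks a reaction as an environment boundary exchange.
  It defaults to the community heuristic — single-metabolite stoichiometry
  and an id starting with ``EX_`` — and may be set explicitly for
  differently named exchanges.  A flagged exchange must have exactly one
  stoichiometric entry; boundary drains such as a biomass pseudo-reaction
  are *not* exchanges unless flagged.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

from .errors import ValidationError
from .generule import EMPTY_RULE, GeneRule

MAXIMIZE = "maximize"
MINIMIZE = "minimize"

#: Default magnitude used for an unconstrained flux bound.
DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """A chemical species in a compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be nonempty")

    def copy(self) -> "Metabolite":
        return _copy.deepcopy(self)


def _default_is_exchange(reaction_id: str, stoichiometry: Dict[str, float]) -> bool:
    return len(stoichiometry) == 1 and reaction_id.startswith("EX_")


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and a gene rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  ``is_exchange=None`` means "apply the default
    heuristic" (single entry + ``EX_`` prefix).
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_rule: GeneRule = EMPTY_RULE
    objective_coefficient: float = 0.0
    name: str = ""
    is_exchange: Optional[bool] = None

    def __post_init__(self):
        if isinstance(self.gene_rule, str):
            self.gene_rule = GeneRule.parse(self.gene_rule)
        if self.is_exchange is None:
            self.is_exchange = _default_is_exchange(self.id, self.stoichiometry)

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be nonempty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: stoichiometry is empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ValidationError(
                f"reaction {self.id!r}: flagged as exchange but has "
                f"{len(self.stoichiometry)} stoichiometric entries"
            )
        for value in self.stoichiometry.values():
            if not math.isfinite(value) or value == 0:
                raise ValidationError(
                    f"reaction {self.id!r}: stoichiometric coefficients must be "
                    "finite and nonzero"
                )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        new = _copy.copy(self)
        new.stoichiometry = dict(self.stoichiometry)
        return new

    def equals(self, other: "Reaction") -> bool:
        """Field-wise equality over all constraint-relevant fields."""
        return (
            self.id == other.id
            and self.stoichiometry == other.stoichiometry
            and self.lower_bound == other.lower_bound
            and self.upper_bound == other.upper_bound
            and self.gene_rule == other.gene_rule
            and self.objective_coefficient == other.objective_coefficient
            and self.name == other.name
            and bool(self.is_exchange) == bool(other.is_exchange)
        )


class Model:
    """A constraint-based metabolic model.

    Metabolites and reactions are stored in insertion-ordered registries
    keyed by id; ids must be unique within their namespace.  ``genes`` is
    the declared gene set; every gene referenced from a gene rule must be
    declared (``validate`` enforces this).
    """

    def __init__(
        self,
        id: str = "model",
        metabolites: Optional[List[Metabolite]] = None,
        reactions: Optional[List[Reaction]] = None,
        genes: Optional[Set[str]] = None,
        objective_direction: str = MAXIMIZE,
    ):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.genes: Set[str] = set(genes or ())
        self.objective_direction = objective_direction
        for met in metabolites or ():
            self.add_metabolite(met)
        for rxn in reactions or ():
            self.add_reaction(rxn)

    # -- construction -------------------------------------------------

    def add_metabolite(self, metabolite: Metabolite) -> Metabolite:
        metabolite.validate()
        if metabolite.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {metabolite.id!r}")
        self.metabolites[metabolite.id] = metabolite
        return metabolite

    def add_reaction(self, reaction: Reaction) -> Reaction:
        reaction.validate()
        if reaction.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {reaction.id!r}")
        self.reactions[reaction.id] = reaction
        self.genes |= reaction.gene_rule.genes
        return reaction

    def remove_reaction(self, reaction_id: str) -> None:
        if reaction_id not in self.reactions:
            raise ValidationError(f"unknown reaction id {reaction_id!r}")
        del self.reactions[reaction_id]

    def remove_metabolite(self, metabolite_id: str) -> None:
        if metabolite_id not in self.metabolites:
            raise ValidationError(f"unknown metabolite id {metabolite_id!r}")
        users = [
            r.id for r in self.reactions.values() if metabolite_id in r.stoichiometry
        ]
        if users:
            raise ValidationError(
                f"metabolite {metabolite_id!r} is still referenced by "
                f"reactions {sorted(users)}"
            )
        del self.metabolites[metabolite_id]

    # -- queries -------------------------------------------------------

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    @property
    def objective_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.objective_coefficient != 0]

    def copy(self) -> "Model":
        new = Model(
            id=self.id,
            genes=set(self.genes),
            objective_direction=self.objective_direction,
        )
        new.metabolites = {mid: m.copy() for mid, m in self.metabolites.items()}
        new.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        return new

    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError on failure."""
        if self.objective_direction not in (MAXIMIZE, MINIMIZE):
            raise ValidationError(
                f"objective_direction must be {MAXIMIZE!r} or {MINIMIZE!r}"
            )
        for met in self.metabolites.values():
            met.validate()
        for rxn in self.reactions.values():
            rxn.validate()
            dangling = set(rxn.stoichiometry) - set(self.metabolites)
            if dangling:
                raise ValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites "
                    f"{sorted(dangling)}"
                )
            undeclared = rxn.gene_rule.genes - self.genes
            if undeclared:
                raise ValidationError(
                    f"reaction {rxn.id!r} gene rule references undeclared genes "
                    f"{sorted(undeclared)}"
                )

    def functionally_equal(self, other: "Model") -> bool:
        """Same id sets, bounds, stoichiometries, rules and objective setup.

        Model ids and insertion order are not compared; this is the
        equality used by delta round-trip guarantees.
        """
        if set(self.metabolites) != set(other.metabolites):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        if self.genes != other.genes:
            return False
        if self.objective_direction != other.objective_direction:
            return False
        for rid, rxn in self.reactions.items():
            if not rxn.equals(other.reactions[rid]):
                return False
        for mid, met in self.metabolites.items():
            o = other.metabolites[mid]
            if (met.name, met.compartment, met.formula, met.charge) != (
                o.name,
                o.compartment,
                o.formula,
                o.charge,
            ):
                return False
        return True

    def __repr__(self):
        return (
            f"<Model {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>"
        )


OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``fluxes`` is present iff ``status == "optimal"``.  Only the objective
    value is contractual: at a degenerate optimum individual fluxes are
    not unique and must only be constrained via FVA intervals.
    """

    status: str
    objective_value: float = 0.0
    fluxes: Optional[Dict[str, float]] = None

    @property
    def is_optimal(self) -> bool:
        return self.status == OPTIMAL
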