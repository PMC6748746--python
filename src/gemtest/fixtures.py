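"""Programmatic toy-model and design generators.

Every model used in the test surface is built here, in memory, by pure
functions of their arguments — no downloads, no bundled data files.

The three named fixtures:

``TOY_PARALLEL``
    Two redundant routes from substrate A to precursor C (direct R3, or
    the R1/R2 chain), a biomass drain on C and a closed product exchange
    EX_C.  FBA optimum 10 (limited by the A uptake bound); no essential
    genes.
``TOY_CHAIN``
    The same network without the direct route: the sole chain makes g1
    and g2 essential.
``TOY_LOOP``
    TOY_CHAIN plus an ATP/ADP pair, an ATPase and an erroneous free
    ADP→ATP regeneration reaction — a thermodynamically inconsistent
    internal cycle that the energetic-consistency diagnostic must catch.

:func:`make_random_model` plants a guaranteed substrate→biomass path and
decorates it with random intermediate topology, so every generated
instance is feasible without rejection sampling.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .conditions import ConditionSet
from .delta import StrainDesign
from .generule import GeneRule
from .model import Metabolite, Model, Reaction

#: Reaction id of the erroneous regeneration cycle in TOY_LOOP.
LOOP_ERROR_REACTION = "R_ERR"
#: Reaction id of the ATPase in TOY_LOOP.
LOOP_ATPASE = "ATPASE"


def make_toy_parallel() -> Model:
    """Six-reaction network with two parallel routes A→C; FBA optimum 10."""
    model = Model(id="toy_parallel")
    for mid in ("A", "B", "C"):
        model.add_metabolite(Metabolite(id=mid, compartment="c"))
    model.add_reaction(Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0))
    model.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, "g1"))
    model.add_reaction(Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, 1000.0, "g2"))
    model.add_reaction(Reaction("R3", {"A": -1.0, "C": 1.0}, 0.0, 1000.0, "g3"))
    model.add_reaction(
        Reaction("BIOMASS", {"C": -1.0}, 0.0, 1000.0, objective_coefficient=1.0)
    )
    model.add_reaction(Reaction("EX_C", {"C": -1.0}, 0.0, 0.0))
    model.validate()
    return model


def make_toy_chain() -> Model:
    """TOY_PARALLEL without the direct route R3; g1 and g2 are essential."""
    model = make_toy_parallel()
    model.remove_reaction("R3")
    model.genes.discard("g3")
    model.id = "toy_chain"
    model.validate()
    return model


def make_toy_loop() -> Model:
    """TOY_CHAIN plus an erroneous ATP-regenerating internal cycle."""
    model = make_toy_chain()
    model.id = "toy_loop"
    model.add_metabolite(Metabolite(id="ATP", compartment="c"))
    model.add_metabolite(Metabolite(id="ADP", compartment="c"))
    model.add_reaction(Reaction(LOOP_ATPASE, {"ATP": -1.0, "ADP": 1.0}, 0.0, 1000.0))
    # The deliberate curation error: ATP regenerated for free from ADP.
    model.add_reaction(
        Reaction(LOOP_ERROR_REACTION, {"ADP": -1.0, "ATP": 1.0}, 0.0, 1000.0)
    )
    model.validate()
    return model


def make_design_fixtures(base: Model) -> Tuple[StrainDesign, StrainDesign]:
    """A reusable knockout design and its heterologous-production child.

    The knockout design removes the chain entry reaction R1; the child
    (parent = knockout) adds a product metabolite P, a heterologous
    pathway reaction R_H (C→P, gene gH) and an open export EX_P.
    """
    if "R1" not in base.reactions:
        raise ValueError("design fixtures expect a base model containing R1")
    ko = StrainDesign(
        id="ko_r1",
        name="R1 knockout",
        description="Reusable knockout of the chain entry reaction",
        reactions_removed=["R1"],
        genes_removed=sorted(base.reactions["R1"].gene_rule.genes),
    )
    child = StrainDesign(
        id="prod_p",
        name="Heterologous P production",
        description="Adds a C→P pathway and product export on top of ko_r1",
        parent="ko_r1",
        metabolites_added=[Metabolite(id="P", compartment="c")],
        genes_added=["gH"],
        reactions_added=[
            Reaction("R_H", {"C": -1.0, "P": 1.0}, 0.0, 1000.0, "gH"),
            Reaction("EX_P", {"P": -1.0}, 0.0, 1000.0),
        ],
    )
    return ko, child


def make_condition_fixtures() -> Tuple[ConditionSet, ConditionSet]:
    """A reduced-uptake condition and a fully closed condition for the toys."""
    limited = ConditionSet(
        id="limited_a",
        description="A uptake restricted to 5",
        exchange_bounds={"EX_A": (-5.0, 1000.0)},
    )
    closed = ConditionSet(
        id="closed",
        description="All uptake closed",
        exchange_bounds={"EX_A": (0.0, 1000.0)},
    )
    return limited, closed


_GENE_POOL = ("gA", "gB", "gC", "gD", "gE")


def _random_rule(rng: np.random.Generator) -> str:
    kind = rng.integers(0, 4)
    a, b, c = rng.choice(len(_GENE_POOL), size=3, replace=False)
    if kind == 0:
        return ""
    if kind == 1:
        return _GENE_POOL[a]
    if kind == 2:
        return f"{_GENE_POOL[a]} and {_GENE_POOL[b]}"
    return f"({_GENE_POOL[a]} and {_GENE_POOL[b]}) or {_GENE_POOL[c]}"


def make_random_model(
    seed: int, n_metabolites: int = 6, n_reactions: int = 10
) -> Model:
    """Seeded, reproducible, guaranteed-feasible random network.

    A substrate uptake, a linear path through every metabolite and a
    biomass drain are planted first (``n_metabolites + 1`` reactions);
    the remaining budget becomes random intermediate reactions with
    random stoichiometry, reversibility and gene rules.  All bounds are
    finite, so the instance is bounded as well as feasible.
    """
    if n_metabolites < 2:
        raise ValueError("n_metabolites must be >= 2")
    n_planted = n_metabolites + 1
    if n_reactions < n_planted:
        raise ValueError(
            f"n_reactions must be >= n_metabolites + 1 (= {n_planted}) "
            "to fit the planted path"
        )
    rng = np.random.default_rng(seed)
    model = Model(id=f"random_{seed}")
    mets = [f"M{i}" for i in range(n_metabolites)]
    for mid in mets:
        model.add_metabolite(Metabolite(id=mid, compartment="c"))
    model.add_reaction(Reaction("EX_M0", {"M0": -1.0}, -10.0, 1000.0))
    for i in range(n_metabolites - 1):
        rule = f"gp{i}" if i % 2 == 0 else ""
        model.add_reaction(
            Reaction(f"P{i}", {mets[i]: -1.0, mets[i + 1]: 1.0}, 0.0, 1000.0, rule)
        )
    model.add_reaction(
        Reaction(
            "BIOMASS", {mets[-1]: -1.0}, 0.0, 1000.0, objective_coefficient=1.0
        )
    )
    for k in range(n_reactions - n_planted):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        chosen = rng.choice(n_metabolites, size=n_sub + n_prod, replace=False)
        stoich = {}
        for idx in chosen[:n_sub]:
            stoich[mets[idx]] = -float(rng.integers(1, 3))
        for idx in chosen[n_sub:]:
            stoich[mets[idx]] = float(rng.integers(1, 3))
        reversible = rng.random() < 0.3
        model.add_reaction(
            Reaction(
                f"R_EXTRA{k}",
                stoich,
                -10.0 if reversible else 0.0,
                100.0,
                _random_rule(rng),
            )
        )
    model.validate()
    return model


def mutate_model(model: Model, seed: int, n_ops: int = 3) -> Model:
    """Return a randomly edited copy of ``model`` (bounds tweaks, gene-rule
    changes, removal of non-planted reactions, new metabolites/reactions).

    The planted path is never touched, so mutants of
    :func:`make_random_model` outputs stay feasible.  Used to build
    (base, modified) pairs for delta round-trip properties.
    """
    rng = np.random.default_rng(seed)
    new = model.copy()
    extra_ids = [rid for rid in new.reactions if rid.startswith("R_EXTRA")]
    counter = 0
    for _ in range(n_ops):
        op = rng.integers(0, 4)
        if op == 0 and extra_ids:  # tweak bounds
            rid = extra_ids[int(rng.integers(0, len(extra_ids)))]
            rxn = new.reactions[rid]
            rxn.lower_bound = float(rng.choice([-10.0, -5.0, 0.0]))
            rxn.upper_bound = float(rng.choice([10.0, 100.0, 1000.0]))
        elif op == 1 and extra_ids:  # replace gene rule
            rid = extra_ids[int(rng.integers(0, len(extra_ids)))]
            new.reactions[rid].gene_rule = GeneRule.parse(_random_rule(rng))
        elif op == 2 and extra_ids:  # remove an extra reaction
            rid = extra_ids.pop(int(rng.integers(0, len(extra_ids))))
            new.remove_reaction(rid)
        else:  # add a metabolite plus a reaction producing it
            mid = f"M_NEW{counter}"
            while mid in new.metabolites:
                counter += 1
                mid = f"M_NEW{counter}"
            source = list(model.metabolites)[
                int(rng.integers(0, len(model.metabolites)))
            ]
            new.add_metabolite(Metabolite(id=mid, compartment="c"))
            new.add_reaction(
                Reaction(f"R_NEW{counter}", {source: -1.0, mid: 1.0}, 0.0, 100.0)
            )
            counter += 1
    # drop gene ids no longer used by any rule so validation stays tight
    used = set()
    for rxn in new.reactions.values():
        used |= rxn.gene_rule.genes
    new.genes = used
    new.validate()
    return new
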