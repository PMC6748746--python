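"""Source templates written into freshly scaffolded projects."""

SCAFFOLD_TESTS = '''\
"""Default model validation tests (scaffolded at project creation).

These run against every registered design via the wildcard selector, so
new strain designs are validated automatically.  Add project-specific
test cases below; each test function takes ``(model, project)`` and uses
plain ``assert`` statements.
"""
from gemtest import fba
from gemtest.testing import model_test_selector


def test_model_loads(model, project):
    """The default model parses and contains reactions."""
    assert len(model.reactions) > 0


def test_model_grows(model, project):
    """FBA on the default model reaches a positive objective."""
    solution = fba(model)
    assert solution.status == "optimal"
    assert solution.objective_value > 1e-6


@model_test_selector(design_ids="*")
def test_design_applies_and_grows(model, project):
    """Every registered design materializes into a model that still grows."""
    solution = fba(model)
    assert solution.status == "optimal"
    assert solution.objective_value > 1e-6
'''

MILP_DESIGN_SOURCE = '''\
"""Minimal active reaction set (programmatic design).

Reformulates the model as a mixed-integer problem: one binary indicator
per reaction, flux coupled to its indicator, biomass fixed at the
wild-type optimum, and the number of active reactions minimized.  Every
reaction outside one minimal active set is then closed.  Because the
reduction is recomputed from the current base model at load time, later
curation of the base is reflected automatically.
"""
from gemtest.analysis import minimize_active_reactions

NAME = "Minimal active reaction set"


def transform(model):
    count, active = minimize_active_reactions(model, biomass_fraction=1.0)
    reduced = model.copy()
    reduced.id = model.id + "_minimal"
    for reaction in reduced.reactions.values():
        if reaction.id not in active:
            reaction.lower_bound = 0.0
            reaction.upper_bound = 0.0
    return reduced
'''

MEASURED_FLUX_EXAMPLE = """\
# Measured flux intervals (e.g. 13C flux tracking), one reaction per line:
# reaction_id  lower  upper
R3  2  8
"""
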