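# gemtest

Test-driven development tooling for genome-scale metabolic models (GSMMs).

Constraint-based models of metabolism are never finished: genome
annotations improve, cofactors get corrected, heterologous pathways are
bolted on for strain engineering. Every such edit risks silently breaking
behaviour that was painstakingly validated before — growth on a defined
medium, the set of essential genes, a product spectrum. `gemtest` treats a
model the way software engineers treat code: validation criteria become
repeatable test cases, strains become *design deltas* layered on a
wild-type base model, and everything lives in flat, diffable files that
version control can track.

It is aimed at modellers who curate GSMMs over time (systems biology,
industrial biotechnology, synthetic biology) and want regressions caught
automatically.

## What it does

* **Core simulation** — flux balance analysis (FBA: maximize an objective
  flux c·v subject to steady state S·v = 0 and bounds l ≤ v ≤ u), flux
  variability analysis (FVA), gene knockouts through boolean AND/OR
  gene-reaction rules, reversible-reaction splitting and growth-condition
  application. LPs and MILPs are assembled sparsely and solved with HiGHS.
* **Strain-design deltas** — `diff_models(base, modified)` produces the
  minimal id-wise delta (added / removed / modified reactions,
  metabolites, genes); deltas serialize to canonical, schema-validated
  JSON; designs inherit from parent designs and re-apply root-first, so
  curation of the base propagates automatically into every derived
  strain. Programmatic designs are executable transformations re-evaluated
  against the current base (a minimal-active-reaction MILP design ships as
  a template).
* **Projects** — one directory holding models (canonical JSON dialect,
  SBML import/export), named condition sets (exchange-bound maps), designs
  and test cases, registered in a flat YAML config.
* **Validation analyses** — energetic-consistency diagnostic (close all
  uptake, force the ATPase to flux 1, feasibility ⇒ a thermodynamically
  inconsistent cycle), flux minimization at fixed biomass, single-gene
  essentiality screens with confusion-matrix comparison against observed
  (e.g. transposon-sequencing) calls, product-export scans, FVA-vs-measured
  flux interval checks, and a big-M MILP for the minimal active reaction
  set.
* **Test runner** — discovers `tests/test_*.py` files in a project, expands
  each test over models × conditions × designs via the
  `model_test_selector` decorator, runs every instance against a freshly
  materialized model and emits machine-readable JSON reports; the CLI exit
  status is 0 iff nothing failed.

## Worked example

```python
from gemtest import fba, diff_models, apply_design, essential_genes
from gemtest.fixtures import make_toy_parallel
from gemtest import project, testing

base = make_toy_parallel()          # A taken up (≤10), two routes A→C, biomass drains C
print(fba(base).objective_value)    # 10.0  — growth limited by the uptake bound

# engineer a strain: delete the direct route
strain = base.copy()
strain.remove_reaction("R3")
strain.genes.discard("g3")
design = diff_models(base, strain)
print(design.reactions_removed)     # ['R3']
print(sorted(essential_genes(apply_design(base, design)).essential_genes))
                                    # ['g1', 'g2']  — the chain route is now essential

# make it a version-controlled project with scaffolded tests
config = project.create_project("demo_project", base)
report = testing.run_tests(config)
print(report.counts)                # {'pass': 2, 'fail': 0, 'error': 0}
```

The printed numbers mean: the wild type grows at 10 flux units (all
uptake routed to biomass); after the knockout design both remaining chain
genes become essential; and the scaffolded project tests (model loads,
model grows) pass.

The same operations are available from the shell:

```bash
gemtest init demo_project toy_parallel.json
gemtest test --project demo_project --report-json report.json
gemtest export sbml strain.xml --project demo_project --design my_design
gemtest fixtures write examples/
```

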