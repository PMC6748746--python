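# Methods

This note records the models, conventions, numerical choices and known
limitations behind `gemtest`, at the level of detail a maintainer needs
to judge what a passing test suite does and does not demonstrate.

## Constraint-based model and conventions

A model is a stoichiometric matrix S (metabolites × reactions), per-
reaction flux bounds l ≤ v ≤ u and a linear objective c·v (direction
stored explicitly, default maximize). All fluxes and bounds are in
mmol · gDW⁻¹ · h⁻¹; design deltas carry bounds in the same units.
Flux balance analysis solves

    optimize c·v   subject to   S v = 0,   l ≤ v ≤ u.

**Exchange convention.** Exchange reactions are written in the export
direction (`M →`): negative flux is uptake and a negative lower bound
permits uptake. This is the dominant community convention and matters
because nothing else in the file formats pins it down.

**Exchange vs boundary drain.** `is_exchange` is a stored flag that must
imply single-metabolite stoichiometry; it defaults to the heuristic
*single entry and id prefixed `EX_`*. A biomass pseudo-reaction is a
single-entry boundary drain but *not* an exchange: it counts as an
enzymatic reaction in flux minimization and is untouched by the
uptake-closing diagnostic. The flag can be set explicitly for exchanges
with non-standard ids (it then round-trips through the JSON dialect via
a `notes` entry).

**Gene rules.** Boolean AND/OR expressions over gene ids, parsed with
`and` binding tighter than `or`; connectives are case-insensitive. `not`
is rejected outright — negative gene associations have no agreed
knockout semantics, and accepting them silently would corrupt
essentiality predictions. A reaction whose rule evaluates false under a
knockout set has its bounds closed to (0, 0). Unknown gene ids in a
query knockout set are ignored by rule evaluation but rejected (with the
offending ids listed) by `knockout_genes`, which takes declared genes as
its contract.

**Degenerate optima.** Only objective values are contractual. At a
degenerate optimum individual fluxes are not unique (HiGHS and GLPK
routinely pick different vertices), so tests and user test cases must
constrain individual fluxes only through FVA intervals.

## LP / MILP machinery

Problems are assembled sparsely (CSR) and handed to SciPy's HiGHS
interfaces (`linprog`, `milp`). One package-wide absolute tolerance,
`TOLERANCE = 1e-6`, is used for feasibility margins, essentiality
thresholds (default), interval-overlap slack and near-optimality
relaxations; FVA relaxes the objective constraint by this amount so the
optimum itself remains feasible, which means a fully coupled reaction
can report a range like (10 − 1e−6, 10).

* **FVA** at fraction f: for maximization the constraint is
  c·v ≥ f · optimum; for minimization c·v ≤ optimum + (1 − f)·|optimum|.
* **Reversible splitting** replaces each reaction with lower bound < 0 by
  a forward copy (0, max(0, u)) and a reversed-stoichiometry backward
  copy (max(0, −u), −l); fluxes map back as v = v_fwd − v_bwd and optima
  are preserved exactly.
* **Flux minimization** fixes c·v = f · optimum (equality), splits
  reversibles so all enzymatic fluxes are nonnegative, and minimizes
  their sum. "Enzymatic" defaults to every non-exchange reaction,
  biomass included; the set is overridable per call.
* **Minimal active reactions** (MILP): binary indicator yᵢ per reaction,
  coupling |vᵢ| ≤ M yᵢ with a single uniform big-M equal to the largest
  bound magnitude in the model (the tightest uniform valid choice without
  per-reaction analysis), biomass constrained to ≥ f · optimum, minimize
  Σ yᵢ. A reaction with a strictly positive lower bound is forcibly
  active, which is the intended semantics. Finite bounds everywhere keep
  big-M well behaved; models with unbounded reactions should be given
  explicit large bounds first.
* **Energetic-consistency diagnostic**: on a copy, every exchange lower
  bound is raised to ≥ 0 (no uptake), all objective coefficients are
  zeroed and the named ATPase is fixed to flux exactly 1; plain
  feasibility is then tested. Feasible ⇒ an internal cycle performs work
  for free (the solution is returned as a witness for inspection);
  infeasible ⇒ consistent. Whether multi-compartment transport reactions
  should also be closed is genuinely ambiguous for models whose boundary
  is not purely exchange reactions; the default closes exchanges only,
  and `close_transporters=True` widens the closure to reactions spanning
  more than one compartment.
* **Product scans** maximize each candidate export in turn. Because
  product exchanges are commonly shipped closed, the scan opens the
  candidate's export *upper* bound (to 1000 if tighter) during its own
  maximization; lower bounds and all other reactions are untouched.
  Values at or below tolerance report as exactly 0 ("not producible").

## Design deltas

A delta stores full replacement records for modified reactions — not
per-field patches — so its meaning is unambiguous if the record schema
gains fields. There is no separate "metabolites modified" list;
metabolite additions are defined as upserts (add-or-replace), which is
how a formula or charge change is expressed. Deltas are *semantic*,
id-wise differences, deliberately not line-level text diffs; the
canonical JSON serialization (sorted keys, id-ordered lists, fixed
indentation, trailing newline) is what makes them version-control
friendly: re-saving an unchanged design or model is byte-identical.

Application order within one delta: reaction removals, then additions
(metabolites, genes, reactions), then modifications, then metabolite and
gene removals, then embedded conditions. Metabolite/gene removals are
checked last because a replacement record in the same delta may be what
drops the final reference to them — the diff of a single edit session
frequently pairs a rule rewrite with the removal of the now-unused gene,
and the pair must re-apply cleanly for the round-trip guarantee
apply(base, diff(base, m)) ≡ m to hold. Removing a metabolite or gene
that is still referenced after modifications is an error (no silent
cascade), as is adding an id that already exists.

Parent chains apply root-first and must be acyclic; `flatten_design`
merges a chain into one parent-free delta with child-wins override
semantics (remove-then-re-add collapses to a modification; a later
reaction record supersedes earlier condition entries for the same id).
Programmatic designs — executable `transform(model)` hooks in a
project's designs directory — are opaque and therefore refuse
flattening and serialization; they are trusted project code, re-evaluated
against the current base at each application (no sandboxing). Delta
documents are validated against a published JSON schema (version "1.0");
violations report the JSON-pointer of the offending element.

## Projects and the test runner

A project is a directory with a flat `project.yml` registry, models in
the canonical JSON dialect (SBML always available for import/export),
`conditions.yml` (a YAML map of exchange-bound sets), `designs/` and
`tests/`. Scaffolding writes a fixed tree — byte-stable given the same
inputs — whose default tests assert that the model loads, grows, and
that every registered design still yields a growing model (the wildcard
selector picks up designs added later automatically).

The runner expands each test over the full cartesian product of its
selector's model ids × condition ids × design ids (empty lists mean: the
default model, unconstrained, wild type). Every instance gets a freshly
materialized model — load, apply conditions, apply design, a design's
embedded conditions last so they override project conditions on
conflicting reactions — which is what makes outcomes independent of
execution order. Assertion failures record `fail`; any other exception,
including an unloadable test file, records `error` without aborting the
run. Test ids are stable strings, `file::function[model/conditions/design]`,
so JSON reports diff cleanly between model versions.

## Formats

The JSON dialect follows COBRA-style field names (`metabolites`,
`reactions` with `metabolites` coefficient maps, `lower_bound`/
`upper_bound`, `gene_reaction_rule`, `objective_coefficient`) and is
loadable by COBRApy directly; unknown top-level keys warn rather than
fail, for forward compatibility. SBML targets Level 3 Version 1 with FBC
v2 through COBRApy/libsbml; files are pre-checked with libsbml so that
malformed XML reports line numbers and non-FBC files get an instructive
error. Known losses through SBML: declared genes referenced by no rule,
and the distinction between "charge 0" and "charge unspecified" (the
reader reports both as 0; charge is annotation-only here). MATLAB `.mat`
export is deliberately unsupported (binary, low test value), as are
kinetic laws, events and rich annotations.

## Fixture networks and what they show

All test inputs are generated programmatically. `TOY_PARALLEL` (six
reactions) has two redundant routes from substrate A to precursor C, so
its FBA optimum (10, set by the uptake bound) survives any single gene
knockout; `TOY_CHAIN` removes the direct route, making g1 and g2
essential; `TOY_LOOP` adds an ATP/ADP pair with an erroneous free
ADP→ATP regeneration, the minimal thermodynamically inconsistent cycle
the diagnostic must flag (witness ATPase flux exactly 1) and must stop
flagging once the bad reaction is removed. `make_random_model(seed)`
plants a substrate→…→biomass path through every metabolite before adding
random intermediate reactions (random stoichiometry up to coefficient 2,
~30 % reversible, gene rules drawn from a five-gene pool), so every
instance is feasible by construction — no rejection sampling — and
bounded because all bounds are finite. Default size is 6 metabolites /
10 reactions: large enough for nontrivial topology, small enough that a
hundred instances solve in seconds.

These networks exercise the machinery, not biology: they have no
compartments beyond the cytosol, no cofactor coupling in growth, no
realistic degeneracy, and are orders of magnitude smaller than a
genome-scale reconstruction (hundreds of reactions and genes). Passing
tests therefore demonstrate correctness of the algorithms and formats,
not predictive validity on any real organism — that is exactly the gap
user-written project test cases with experimental data are meant to
fill.

The acceptance script runs the LP-agreement check on 100 seeded random
networks (the absolute-value flux-minimization oracle on 25 of them —
the slowest oracle, and a subsample keeps the script responsive), 100
delta round-trip pairs, exhaustive 2^n subset enumeration on the ≤ 10
reaction fixtures, and three shuffled runner repeats; sizes chosen so
the whole script completes in well under a minute on one CPU.

## Verification strategy

The LP/MILP implementations are never checked against themselves: tests
rebuild each problem independently in COBRApy/GLPK (different modelling
layer, different solver) and compare objectives; flux minimization is
cross-checked against an absolute-value-variable formulation instead of
reversible splitting; the MILP against exhaustive subset enumeration;
the JSON dialect against COBRApy's own loader. Diff/apply, flattening
and the test runner are checked by round-trip, equivalence and
order-shuffling properties on both fixed and seeded random inputs.

## Known limitations

* No thermodynamic (loopless) or dynamic FBA variants, quadratic
  objectives, gap filling, flux sampling, elementary flux modes or
  minimal cut sets.
* Identity is by string id only — no namespace mapping or fuzzy matching
  between models from different reconstruction pipelines, and no rename
  detection in diffs (a renamed reaction appears as remove + add).
* No three-way merge of deltas; concurrent edits to the same design must
  be reconciled in version control.
* Programmatic designs execute arbitrary project code; they are trusted
  by design.
* The MILP uses a single uniform big-M; models with wildly heterogeneous
  bound magnitudes may solve faster with per-reaction coupling, which is
  not implemented.
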