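"""Validation analyses: diagnostics, flux minimization, essentiality,
product scans, the MILP minimal-reaction design and FVA-vs-data checks."""

import numpy as np
import pytest

from gemtest import (
    DiagnosticError,
    OptimizationError,
    ValidationError,
    compare_essentiality,
    energetic_consistency_check,
    essential_genes,
    fba,
    flux_minimization,
    fva_against_measurements,
    minimize_active_reactions,
    product_scan,
)
from gemtest.analysis import read_measured_fluxes
from gemtest.fixtures import LOOP_ATPASE, LOOP_ERROR_REACTION
from gemtest.model import Metabolite, Reaction

from conftest import oracle_fba_objective, oracle_min_active_count

TOL = 1e-5


class TestEnergeticConsistency:
    def test_erroneous_cycle_detected_with_unit_witness(self, toy_loop):
        diagnosis = energetic_consistency_check(toy_loop, LOOP_ATPASE)
        assert diagnosis.consistent is False
        assert diagnosis.witness is not None
        assert diagnosis.witness.status == "optimal"
        assert diagnosis.witness.fluxes[LOOP_ATPASE] == pytest.approx(1.0, abs=TOL)

    def test_consistent_after_cycle_removed(self, toy_loop):
        toy_loop.remove_reaction(LOOP_ERROR_REACTION)
        diagnosis = energetic_consistency_check(toy_loop, LOOP_ATPASE)
        assert diagnosis.consistent is True
        assert diagnosis.witness is None

    def test_uptake_driven_atpase_is_consistent(self, toy_parallel):
        # ATP only producible from substrate uptake: closing uptake makes
        # a forced ATPase flux infeasible.
        toy_parallel.add_metabolite(Metabolite("ATP"))
        toy_parallel.add_metabolite(Metabolite("ADP"))
        toy_parallel.add_reaction(
            Reaction("RGEN", {"A": -1.0, "ADP": -1.0, "ATP": 1.0})
        )
        toy_parallel.add_reaction(Reaction("ATPASE", {"ATP": -1.0, "ADP": 1.0}))
        diagnosis = energetic_consistency_check(toy_parallel, "ATPASE")
        assert diagnosis.consistent is True

    def test_atpase_bounds_contradiction_is_setup_failure(self, toy_loop):
        toy_loop.reactions[LOOP_ATPASE].lower_bound = 0.0
        toy_loop.reactions[LOOP_ATPASE].upper_bound = 0.0
        with pytest.raises(DiagnosticError, match="outside its bounds"):
            energetic_consistency_check(toy_loop, LOOP_ATPASE)

    def test_missing_atpase_rejected(self, toy_chain):
        with pytest.raises(DiagnosticError, match="NOPE"):
            energetic_consistency_check(toy_chain, "NOPE")


class TestFluxMinimization:
    def test_parallel_prefers_short_route(self, toy_parallel):
        total, solution = flux_minimization(toy_parallel, 1.0)
        assert total == pytest.approx(20.0, abs=TOL)
        assert solution.fluxes["R3"] == pytest.approx(10.0, abs=TOL)
        assert solution.fluxes["R1"] == pytest.approx(0.0, abs=TOL)

    def test_chain_has_no_choice(self, toy_chain):
        total, _ = flux_minimization(toy_chain, 1.0)
        assert total == pytest.approx(30.0, abs=TOL)

    def test_zero_fraction_allows_zero_flux(self, toy_parallel):
        total, _ = flux_minimization(toy_parallel, 0.0)
        assert total == pytest.approx(0.0, abs=TOL)

    def test_total_bounds_any_feasible_point(self, toy_parallel):
        """Minimality: no random feasible same-biomass solution has a
        smaller enzymatic flux total."""
        total, _ = flux_minimization(toy_parallel, 1.0)
        rng = np.random.default_rng(42)
        enzymatic = [
            rid for rid, r in toy_parallel.reactions.items() if not r.is_exchange
        ]
        for _ in range(100):
            # random split of the required 10 units between the two routes
            direct = rng.uniform(0.0, 10.0)
            chain = 10.0 - direct
            fluxes = {
                "EX_A": -10.0,
                "R3": direct,
                "R1": chain,
                "R2": chain,
                "BIOMASS": 10.0,
                "EX_C": 0.0,
            }
            candidate = sum(abs(fluxes[rid]) for rid in enzymatic)
            assert candidate >= total - TOL

    def test_infeasible_fixing_reported(self, toy_parallel):
        toy_parallel.reactions["BIOMASS"].lower_bound = 50.0
        with pytest.raises(OptimizationError):
            flux_minimization(toy_parallel, 1.0)


class TestEssentiality:
    def test_chain_genes_essential(self, toy_chain):
        result = essential_genes(toy_chain, threshold=1e-6)
        assert result.essential_genes == {"g1", "g2"}
        assert result.wild_type_objective == pytest.approx(10.0, abs=TOL)

    def test_parallel_routes_protect_all_genes(self, toy_parallel):
        result = essential_genes(toy_parallel, threshold=1e-6)
        assert result.essential_genes == set()
        assert set(result.growth_by_gene) == {"g1", "g2", "g3"}

    def test_gene_free_route_cannot_be_blocked(self, toy_chain):
        # add a spontaneous (gene-free) bypass: no knockout can stop growth
        toy_chain.add_reaction(Reaction("R_SPONT", {"A": -1.0, "C": 1.0}))
        result = essential_genes(toy_chain, threshold=1e-6)
        assert result.essential_genes == set()

    def test_threshold_invariant_holds(self, toy_chain):
        result = essential_genes(toy_chain, threshold=1e-6)
        for gene, growth in result.growth_by_gene.items():
            assert (gene in result.essential_genes) == (growth < result.threshold)

    def test_nongrowing_wild_type_rejected(self, toy_chain):
        toy_chain.reactions["EX_A"].lower_bound = 0.0
        with pytest.raises(OptimizationError, match="does not grow"):
            essential_genes(toy_chain)


class TestCompareEssentiality:
    def test_confusion_counts(self, toy_chain):
        result = essential_genes(toy_chain)
        counts = compare_essentiality(result, {"g1"}, {"g2"})
        assert counts == {"TP": 1, "FP": 1, "TN": 0, "FN": 0}

    def test_empty_observations_give_zero_counts(self, toy_chain):
        result = essential_genes(toy_chain)
        assert compare_essentiality(result, set(), set()) == {
            "TP": 0,
            "FP": 0,
            "TN": 0,
            "FN": 0,
        }

    def test_missed_essential_counts_as_false_negative(self, toy_parallel):
        result = essential_genes(toy_parallel)  # predicts none essential
        counts = compare_essentiality(result, {"g1"}, set())
        assert counts["FN"] == 1

    def test_overlapping_observations_rejected(self, toy_chain):
        result = essential_genes(toy_chain)
        with pytest.raises(ValidationError, match="both observed sets"):
            compare_essentiality(result, {"g1"}, {"g1"})


class TestProductScan:
    def test_all_carbon_routable_to_product(self, toy_parallel):
        scan = product_scan(toy_parallel, ["EX_C"])
        assert scan["EX_C"] == pytest.approx(10.0, abs=TOL)

    def test_no_uptake_no_product(self, toy_parallel):
        from gemtest import ConditionSet

        closed = ConditionSet(id="closed", exchange_bounds={"EX_A": (0.0, 1000.0)})
        scan = product_scan(toy_parallel, ["EX_C"], conditions=closed)
        assert scan["EX_C"] == 0.0

    def test_disconnected_product_yields_zero(self, toy_parallel):
        # close every route into C: the product cannot be synthesized
        for rid in ("R2", "R3"):
            toy_parallel.reactions[rid].upper_bound = 0.0
        scan = product_scan(toy_parallel, ["EX_C"])
        assert scan["EX_C"] == 0.0

    def test_unknown_exchange_rejected(self, toy_parallel):
        with pytest.raises(ValidationError, match="EX_NOPE"):
            product_scan(toy_parallel, ["EX_NOPE"])


class TestMinimizeActiveReactions:
    def test_parallel_minimal_set(self, toy_parallel):
        count, active = minimize_active_reactions(toy_parallel, 1.0)
        assert count == 3
        assert active == {"EX_A", "R3", "BIOMASS"}

    def test_chain_minimal_set(self, toy_chain):
        count, active = minimize_active_reactions(toy_chain, 1.0)
        assert count == 4
        assert active == {"EX_A", "R1", "R2", "BIOMASS"}

    def test_zero_fraction_needs_no_reactions(self, toy_parallel):
        count, active = minimize_active_reactions(toy_parallel, 0.0)
        assert count == 0
        assert active == set()

    @pytest.mark.parametrize("fixture", ["toy_parallel", "toy_chain", "toy_loop"])
    def test_matches_exhaustive_subset_oracle(self, fixture, request):
        model = request.getfixturevalue(fixture)
        count, _ = minimize_active_reactions(model, 1.0)
        assert count == oracle_min_active_count(model, 1.0)

    def test_infeasible_target_reported(self, toy_parallel):
        toy_parallel.reactions["BIOMASS"].lower_bound = 50.0
        with pytest.raises(OptimizationError):
            minimize_active_reactions(toy_parallel, 1.0)


class TestFVAAgainstMeasurements:
    def test_overlapping_interval_accepted(self, toy_parallel):
        report = fva_against_measurements(toy_parallel, {"R3": (2.0, 8.0)}, 1.0)
        assert report["R3"]["overlaps"] is True
        lo, hi = report["R3"]["model_range"]
        assert (lo, hi) == pytest.approx((0.0, 10.0), abs=TOL)

    def test_disjoint_interval_flagged(self, toy_parallel):
        report = fva_against_measurements(toy_parallel, {"R3": (11.0, 12.0)}, 1.0)
        assert report["R3"]["overlaps"] is False

    def test_touching_interval_counts_as_overlap(self, toy_parallel):
        report = fva_against_measurements(toy_parallel, {"R3": (10.0, 12.0)}, 1.0)
        assert report["R3"]["overlaps"] is True

    def test_unknown_measured_id_rejected(self, toy_parallel):
        with pytest.raises(ValidationError, match="R_NOPE"):
            fva_against_measurements(toy_parallel, {"R_NOPE": (0.0, 1.0)})

    def test_measured_flux_file_parsing(self, tmp_path, toy_parallel):
        path = tmp_path / "measured.tsv"
        path.write_text("# comment\nR3  2  8\n\nR1\t0\t10\n")
        measured = read_measured_fluxes(path)
        assert measured == {"R3": (2.0, 8.0), "R1": (0.0, 10.0)}
        report = fva_against_measurements(toy_parallel, measured, 1.0)
        assert report["R3"]["overlaps"] and report["R1"]["overlaps"]

    def test_malformed_measurement_line_rejected(self, tmp_path):
        path = tmp_path / "measured.tsv"
        path.write_text("R3 2\n")
        with pytest.raises(ValidationError, match="expected"):
            read_measured_fluxes(path)
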