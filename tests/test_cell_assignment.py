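"""VCB field extraction, mismatch-tolerant matching, UMI collapse and the
three cell-to-variant validity criteria."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mave_evidence as me
from mave_evidence.cell_assignment import AMBIGUOUS, BarcodeMatcher, VCBRead
from mave_evidence.config import SimulationConfig

from oracles import adjacency_cluster_count_bruteforce, assignment_bruteforce

FLANK = "GTCAGTCGGA"


class TestExtractFields:
    def test_well_formed_pair(self):
        r1 = "A" * 16 + "C" * 12 + "GGGG"
        r2 = "TT" + FLANK + "ACGTACGT" + "TTCGAGCGAT"
        read = me.extract_fields(r1, r2, FLANK)
        assert read == VCBRead("A" * 16, "C" * 12, "ACGTACGT")

    def test_short_read1_rejected(self):
        assert me.extract_fields("A" * 20, FLANK + "ACGTACGT", FLANK) == "read1_too_short"

    def test_flank_with_one_substitution_still_found(self):
        mutated = "A" + FLANK[1:]
        r2 = mutated + "ACGTACGT" + "TT"
        read = me.extract_fields("A" * 28, r2, FLANK)
        assert read.variant_barcode == "ACGTACGT"

    def test_missing_flank_rejected(self):
        assert me.extract_fields("A" * 28, "T" * 40, FLANK) == "flank_not_found"


class TestMatchBarcode:
    def test_exact_match_wins(self):
        assert me.match_barcode("AAAA", {"AAAA", "AAAT"}) == "AAAA"

    def test_single_mismatch_corrected(self):
        assert me.match_barcode("AAAG", {"AAAA", "CCCC"}) == "AAAA"

    def test_ambiguous_at_equal_distance(self):
        assert me.match_barcode("AAAT", {"AAAA", "AACT"}) == AMBIGUOUS

    def test_no_match_beyond_tolerance(self):
        assert me.match_barcode("GGGG", {"AAAA", "CCCC"}) is None

    def test_n_bases_count_as_mismatches(self):
        assert me.match_barcode("AAAN", {"AAAA"}) == "AAAA"
        assert me.match_barcode("AANN", {"AAAA"}) is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.sets(st.text(alphabet="ACGT", min_size=5, max_size=5), min_size=1, max_size=8),
        st.text(alphabet="ACGTN", min_size=5, max_size=5),
    )
    def test_indexed_matcher_equals_linear_scan(self, whitelist, observed):
        assert BarcodeMatcher(whitelist).match(observed) == me.match_barcode(
            observed, whitelist
        )


class TestCollapseUmis:
    def test_identical_umis_collapse_to_one(self):
        assert me.collapse_umis({"AAAAAAAAAAAA": 5}) == 1

    def test_error_satellite_absorbed(self):
        assert me.collapse_umis({"AAAAAAAAAAAA": 10, "AAAAAAAAAAAT": 1}) == 1

    def test_distant_umis_stay_distinct(self):
        assert me.collapse_umis({"AAAATTTT": 1, "CCCCTTTT": 1, "GGGGTTTT": 1}) == 3

    def test_empty_input(self):
        assert me.collapse_umis({}) == 0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.dictionaries(
            st.text(alphabet="ACGT", min_size=4, max_size=4),
            st.integers(min_value=1, max_value=50),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_adjacency_oracle(self, counts):
        assert me.collapse_umis(counts) == adjacency_cluster_count_bruteforce(counts)


class TestAssignCells:
    VARIANT_OF = {"AAAA": "V1", "CCCC": "V2", "GGGG": "V3"}

    def test_clear_winner_assigned(self):
        assignments, _ = me.assign_cells({"cell1": {"AAAA": 5, "CCCC": 1}}, self.VARIANT_OF)
        [a] = assignments
        assert a.variant_id == "V1" and a.n_umis == 6
        assert a.top_fraction == pytest.approx(5 / 6)
        assert a.second_fraction == pytest.approx(1 / 6)

    def test_too_few_umis_unassigned(self):
        assignments, unassigned = me.assign_cells({"c": {"AAAA": 2}}, self.VARIANT_OF)
        assert not assignments
        assert unassigned["failed_criterion"].tolist() == ["min_umis"]

    def test_strong_runner_up_unassigned(self):
        assignments, unassigned = me.assign_cells(
            {"c": {"AAAA": 4, "CCCC": 3}}, self.VARIANT_OF
        )
        assert not assignments
        assert unassigned["failed_criterion"].tolist() == ["runner_up"]

    def test_top_fraction_exactly_half_fails(self):
        # the majority criterion is strict: 3/6 is not > 0.5
        _, unassigned = me.assign_cells(
            {"c": {"AAAA": 3, "CCCC": 2, "GGGG": 1}}, self.VARIANT_OF
        )
        assert unassigned["failed_criterion"].tolist() == ["top_fraction"]

    def test_runner_up_exactly_quarter_passes(self):
        # "did not exceed 0.25" is non-strict: 2/8 passes
        assignments, _ = me.assign_cells(
            {"c": {"AAAA": 6, "CCCC": 2}}, self.VARIANT_OF
        )
        assert len(assignments) == 1

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.dictionaries(
            st.integers(min_value=0, max_value=19).map(lambda i: f"cell{i}"),
            st.dictionaries(
                st.sampled_from(["AAAA", "CCCC", "GGGG"]),
                st.integers(min_value=1, max_value=10),
                min_size=1,
                max_size=3,
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_matches_bruteforce_criteria(self, table):
        assignments, unassigned = me.assign_cells(table, self.VARIANT_OF)
        expected = assignment_bruteforce(table)
        got = {a.cell_barcode: a.variant_id for a in assignments}
        for cell, top_bc in expected.items():
            if top_bc is None:
                assert cell not in got
            else:
                assert got[cell] == self.VARIANT_OF[top_bc]
        # partition: every cell lands in exactly one of the two tables
        assert len(assignments) + len(unassigned) == len(table)


class TestRecovery:
    def test_clean_library_recovers_truth(self):
        cfg = SimulationConfig(
            n_variants=15,
            n_cells_per_variant=12,
            n_genes=60,
            n_module_genes=6,
            n_mito_genes=2,
            coding_length=300,
            ambient_rate=0.0,
            barcode_error_rate=0.01,
            seed=9,
        )
        manifest = me.generate_manifest(cfg)
        truth = me.generate_truth(manifest, cfg)
        r1, r2 = me.simulate_vcb_reads(truth, manifest, cfg)
        whitelist = dict(zip(manifest.entries["barcode"], manifest.entries["variant_id"]))
        assignments, _, summary = me.run_assignment(
            ((s1, s2) for (_, s1), (_, s2) in zip(r1, r2)),
            whitelist,
            truth.cells,
            manifest.flank_left,
        )
        assert len(assignments) <= len(truth.cells)
        # near-default error regime: almost every truth cell passes the
        # three validity criteria
        assert len(assignments) >= 0.95 * len(truth.cells)
        correct = np.mean(
            [
                truth.cell_to_variant[c] == v
                for c, v in zip(assignments["cell_barcode"], assignments["variant_id"])
            ]
        )
        assert correct >= 0.99

    def test_cells_outside_reference_list_never_assigned(self):
        cfg = SimulationConfig(
            n_variants=8,
            n_cells_per_variant=6,
            n_genes=40,
            n_module_genes=4,
            n_mito_genes=2,
            coding_length=300,
            ambient_rate=0.0,
            barcode_error_rate=0.0,
            seed=4,
        )
        manifest = me.generate_manifest(cfg)
        truth = me.generate_truth(manifest, cfg)
        r1, r2 = me.simulate_vcb_reads(truth, manifest, cfg)
        whitelist = dict(zip(manifest.entries["barcode"], manifest.entries["variant_id"]))
        allowed = truth.cells[:10]
        assignments, _, summary = me.run_assignment(
            ((s1, s2) for (_, s1), (_, s2) in zip(r1, r2)),
            whitelist,
            allowed,
            manifest.flank_left,
        )
        assert set(assignments["cell_barcode"]) <= set(allowed)
        assert summary["rejected_cell_barcode_unmatched"] > 0

    def test_heavy_ambient_breaks_runner_up_criterion(self):
        """With contamination concentrated on one competing variant the
        winner can keep its majority while the runner-up exceeds 0.25;
        at still higher ambient rates cells fail the majority criterion
        instead."""
        cfg = SimulationConfig(
            n_variants=2,
            n_cells_per_variant=20,
            n_genes=40,
            n_module_genes=4,
            n_mito_genes=2,
            coding_length=300,
            ambient_rate=0.35,
            barcode_error_rate=0.0,
            seed=6,
        )
        manifest = me.generate_manifest(cfg)
        truth = me.generate_truth(manifest, cfg)
        r1, r2 = me.simulate_vcb_reads(truth, manifest, cfg)
        whitelist = dict(zip(manifest.entries["barcode"], manifest.entries["variant_id"]))
        _, unassigned, _ = me.run_assignment(
            ((s1, s2) for (_, s1), (_, s2) in zip(r1, r2)),
            whitelist,
            truth.cells,
            manifest.flank_left,
        )
        assert (unassigned["failed_criterion"] == "runner_up").sum() > 0
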