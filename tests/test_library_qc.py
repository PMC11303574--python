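"""Barcode clustering, SNV concordance and truncation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mave_evidence as me
from mave_evidence.config import SimulationConfig
from mave_evidence.io import VariantManifest
from mave_evidence.library_qc import (
    BarcodeCluster,
    ReadObservation,
    parse_long_read,
)

from oracles import directional_clusters_bruteforce


def _manifest(reference="ACGTACGTACGTACGTACGT", rows=None):
    rows = rows or [("V1", 4, "A", "T", "AAAACCCC")]
    entries = pd.DataFrame(
        [
            {"variant_id": v, "gene": "G", "pos": p, "ref": r, "alt": a, "barcode": b}
            for v, p, r, a, b in rows
        ]
    )
    return VariantManifest(
        entries=entries,
        reference=reference,
        flank_left="GTCAGTCGGA",
        flank_right="TTCGAGCGAT",
    )


class TestClusterBarcodes:
    def test_satellite_absorbed_into_dominant_barcode(self):
        clusters = me.cluster_barcodes({"AAAA": 100, "AAAT": 3})
        assert len(clusters) == 1
        assert clusters[0].representative == "AAAA"
        assert set(clusters[0].members) == {"AAAA", "AAAT"}

    def test_distant_barcodes_stay_separate(self):
        clusters = me.cluster_barcodes({"AAAA": 10, "TTTT": 10})
        assert len(clusters) == 2

    def test_count_rule_blocks_equal_abundance_merge(self):
        # 10 >= 2*10 - 1 is false, so neighbours of equal depth stay apart
        clusters = me.cluster_barcodes({"AAAA": 10, "AAAT": 10})
        assert len(clusters) == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            me.cluster_barcodes({"AAAA": 5, "AAAAA": 5})

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.dictionaries(
            st.text(alphabet="ACGT", min_size=4, max_size=4),
            st.integers(min_value=1, max_value=200),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_bruteforce_oracle(self, counts):
        """Directional clustering equals explicit edge-enumeration on
        small instances, and partitions the input."""
        clusters = me.cluster_barcodes(counts)
        got = sorted(sorted(c.members) for c in clusters)
        expected = sorted(sorted(c) for c in directional_clusters_bruteforce(counts))
        assert got == expected
        all_members = [bc for c in clusters for bc in c.members]
        assert sorted(all_members) == sorted(counts)


class TestCallClusterVariant:
    def _cluster(self, read_snvs, span=20):
        reads = [
            ReadObservation(f"r{i}", "AAAACCCC", snvs, span)
            for i, snvs in enumerate(read_snvs)
        ]
        return BarcodeCluster("AAAACCCC", {"AAAACCCC": len(reads)}, reads)

    def test_modal_snv_and_fraction(self):
        cluster = self._cluster([((4, "T"),)] * 6 + [()] * 4)
        assert me.call_cluster_variant(cluster) == ("4:T", 0.6)

    def test_tie_broken_lexicographically(self):
        cluster = self._cluster([((4, "T"),)] * 5 + [((2, "G"),)] * 5)
        snv, fraction = me.call_cluster_variant(cluster)
        assert snv == "2:G" and fraction == 0.5

    def test_all_wild_type(self):
        cluster = self._cluster([()] * 8)
        assert me.call_cluster_variant(cluster) == ("no_snv", 1.0)

    def test_empty_cluster_fails(self):
        with pytest.raises(ValueError):
            me.call_cluster_variant(BarcodeCluster("AAAA", {"AAAA": 1}, []))


class TestValidatePair:
    def _cluster(self, n_match=6, n_wt=4, span=20, n_trunc=0, barcode="AAAACCCC"):
        reads = [
            ReadObservation(f"m{i}", barcode, ((4, "T"),), span) for i in range(n_match)
        ]
        reads += [ReadObservation(f"w{i}", barcode, (), span) for i in range(n_wt)]
        for i in range(n_trunc):
            reads[i] = ReadObservation(reads[i].read_id, barcode, reads[i].snvs, span - 60)
        return BarcodeCluster(barcode, {barcode: len(reads)}, reads)

    def test_concordant_untruncated_passes(self):
        # 250 bp reference so a 60 bp deficit counts as truncation
        manifest = _manifest(reference="ACGT" * 62 + "AC", rows=[("V1", 4, "A", "T", "AAAACCCC")])
        cluster = self._cluster(span=250)
        record = me.validate_pair(cluster, me.call_cluster_variant(cluster), manifest)
        assert record.verdict == "pass" and record.variant_id == "V1"

    def test_heavy_truncation_fails(self):
        manifest = _manifest(reference="ACGT" * 62 + "AC", rows=[("V1", 4, "A", "T", "AAAACCCC")])
        cluster = self._cluster(n_match=7, n_wt=1, span=250, n_trunc=2)  # 25% short
        record = me.validate_pair(cluster, me.call_cluster_variant(cluster), manifest)
        assert record.verdict == "fail_truncation"

    def test_low_concordance_fails(self):
        # modal mutation IS the designed SNV but at 9/20 = 0.45 support
        manifest = _manifest(reference="ACGT" * 62 + "AC", rows=[("V1", 4, "A", "T", "AAAACCCC")])
        reads = [
            ReadObservation(f"m{i}", "AAAACCCC", ((4, "T"),), 250) for i in range(9)
        ]
        reads += [ReadObservation(f"w{i}", "AAAACCCC", (), 250) for i in range(6)]
        reads += [
            ReadObservation(f"o{i}", "AAAACCCC", ((8, "G"),), 250) for i in range(5)
        ]
        cluster = BarcodeCluster("AAAACCCC", {"AAAACCCC": 20}, reads)
        record = me.validate_pair(cluster, me.call_cluster_variant(cluster), manifest)
        assert record.called_snv == "4:T"
        assert record.snv_fraction == 0.45
        assert record.verdict == "fail_concordance"

    def test_undesigned_representative_unmatched(self):
        manifest = _manifest(reference="ACGT" * 62 + "AC", rows=[("V1", 4, "A", "T", "AAAACCCC")])
        cluster = self._cluster(span=250, barcode="GGGGGGGG")
        record = me.validate_pair(cluster, me.call_cluster_variant(cluster), manifest)
        assert record.verdict == "fail_unmatched" and record.variant_id is None


class TestParseLongRead:
    def test_truncated_read_anchored_at_three_prime_end(self):
        manifest = _manifest(reference="AAAATAAAAGAAAACAAAAG", rows=[("V1", 4, "T", "C", "AAAACCCC")])
        coding = "AAAACAAAAGAAAACAAAAG"  # carries 4:C
        read = coding[8:] + manifest.flank_left + "AAAACCCC" + manifest.flank_right
        obs = parse_long_read("r", read, manifest)
        assert obs.span == 12
        # SNV at position 4 fell off with the 5' truncation
        assert obs.snvs == ()
        full = parse_long_read("f", coding + manifest.flank_left + "AAAACCCC", manifest)
        assert full.snvs == ((4, "C"),)


class TestEndToEnd:
    def test_default_error_rates_pass_most_variants(self):
        cfg = SimulationConfig(
            n_variants=30,
            n_cells_per_variant=5,
            n_genes=50,
            n_module_genes=5,
            n_mito_genes=2,
            coding_length=300,
            long_read_depth=60,
            seed=3,
        )
        manifest = me.generate_manifest(cfg)
        reads = me.simulate_long_reads(manifest, cfg)
        qc, whitelist = me.run_library_qc(reads, manifest)
        assert len(whitelist) >= 0.95 * len(manifest)
        # partition sanity: every passing barcode is a designed barcode
        assert set(whitelist["barcode"]) <= set(manifest.entries["barcode"])

    @pytest.mark.parametrize("error_rate", [0.0, 0.05, 0.15])
    def test_passing_barcodes_never_exceed_design(self, error_rate):
        cfg = SimulationConfig(
            n_variants=12,
            n_cells_per_variant=5,
            n_genes=50,
            n_module_genes=5,
            n_mito_genes=2,
            coding_length=300,
            long_read_depth=40,
            barcode_error_rate=error_rate,
            seed=5,
        )
        manifest = me.generate_manifest(cfg)
        qc, whitelist = me.run_library_qc(me.simulate_long_reads(manifest, cfg), manifest)
        assert len(whitelist) <= len(manifest)
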