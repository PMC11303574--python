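"""Validate the designed variant-to-barcode map from long-read consensus data.

Consensus reads of the cloned variant library are parsed for their 3'-UTR
barcode (located by the constant left flank), barcodes are collapsed with
directional network clustering to absorb sequencing-error satellites, and
each cluster's reads are examined for SNVs in the coding region. A
variant-to-barcode relationship passes quality control when

* the most common mutation accounts for at least 50% of the cluster's
  reads AND matches the designed SNV for that barcode, and
* fewer than 20% of the reads are shorter than the expected length of the
  target gene by 50 bp or more.

Clusters whose representative barcode is not a designed barcode are
reported as unmatched rather than rescued.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from mave_evidence.io import VariantManifest, read_fastq
from mave_evidence.network import TagCluster, cluster_tags, hamming

logger = logging.getLogger(__name__)

NO_SNV = "no_snv"


@dataclass
class ReadObservation:
    """Per-read evidence: observed barcode, coding SNVs, aligned span."""

    read_id: str
    barcode: str
    snvs: tuple[tuple[int, str], ...]
    span: int  # aligned coding-region length


@dataclass
class BarcodeCluster:
    """A barcode cluster and the long reads supporting it."""

    representative: str
    members: dict[str, int] = field(default_factory=dict)
    reads: list[ReadObservation] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class LibraryQCRecord:
    """QC verdict for one barcode cluster."""

    representative: str
    variant_id: str | None
    called_snv: str
    snv_fraction: float
    truncated_fraction: float
    verdict: str  # pass | fail_concordance | fail_truncation | fail_unmatched


def find_flank(seq: str, flank: str, max_mismatch: int = 1) -> int:
    """Leftmost start of ``flank`` in ``seq``: exact match first, then the
    best (fewest-mismatch) position within ``max_mismatch`` substitutions.
    Returns -1 when absent."""
    pos = seq.find(flank)
    if pos >= 0:
        return pos
    best_pos, best_d = -1, max_mismatch + 1
    for i in range(len(seq) - len(flank) + 1):
        d = hamming(seq[i : i + len(flank)], flank)
        if d < best_d:
            best_pos, best_d = i, d
    return best_pos if best_d <= max_mismatch else -1


def parse_long_read(
    read_id: str, seq: str, manifest: VariantManifest
) -> ReadObservation | None:
    """Extract the barcode and coding SNV observations from one read.

    The coding portion (everything left of the flank) is anchored to the
    reference by its 3' end: truncation removes 5' bases, so position i of
    the read maps to reference position i + (len(reference) - span).
    """
    flank_pos = find_flank(seq, manifest.flank_left)
    if flank_pos < 0:
        return None
    bc_start = flank_pos + len(manifest.flank_left)
    barcode = seq[bc_start : bc_start + manifest.barcode_length]
    if len(barcode) < manifest.barcode_length:
        return None
    coding = seq[:flank_pos]
    ref = manifest.reference
    if len(coding) > len(ref):
        coding = coding[-len(ref) :]
    offset = len(ref) - len(coding)
    snvs = tuple(
        (offset + i, base)
        for i, base in enumerate(coding)
        if base != ref[offset + i]
    )
    return ReadObservation(read_id=read_id, barcode=barcode, snvs=snvs, span=len(coding))


def cluster_barcodes(
    barcode_counts: Mapping[str, int],
    max_edit: int = 1,
    method: str = "directional",
) -> list[BarcodeCluster]:
    """Collapse observed barcodes into clusters (directional by default).

    Directional rule: an edge from A to B exists when Hamming(A, B) <=
    ``max_edit`` and count(A) >= 2 * count(B) - 1; clusters are the
    connected components reachable from count-descending seeds. Every
    input barcode lands in exactly one cluster.
    """
    return [
        BarcodeCluster(representative=c.representative, members=dict(c.members))
        for c in cluster_tags(barcode_counts, max_edit=max_edit, method=method)
    ]


def _attach_reads(
    clusters: Sequence[BarcodeCluster], observations: Iterable[ReadObservation]
) -> None:
    member_of: dict[str, BarcodeCluster] = {}
    for cluster in clusters:
        for bc in cluster.members:
            member_of[bc] = cluster
    for obs in observations:
        member_of[obs.barcode].reads.append(obs)


def call_cluster_variant(cluster: BarcodeCluster) -> tuple[str, float]:
    """Most common coding mutation across a cluster's reads.

    Returns the modal SNV as ``"pos:alt"`` (or ``"no_snv"`` when wild-type
    reads dominate) and its fraction of total cluster reads. Ties break
    deterministically by (position, alt base), with the wild-type category
    ordered last.
    """
    if not cluster.reads:
        raise ValueError("cluster has no parseable reads")
    tallies: dict[tuple[int, str] | None, int] = {}
    for obs in cluster.reads:
        if obs.snvs:
            for snv in obs.snvs:
                tallies[snv] = tallies.get(snv, 0) + 1
        else:
            tallies[None] = tallies.get(None, 0) + 1

    def sort_key(item: tuple[tuple[int, str] | None, int]):
        snv, count = item
        tie = (float("inf"), "") if snv is None else (float(snv[0]), snv[1])
        return (-count, tie)

    modal, count = min(tallies.items(), key=sort_key)
    name = NO_SNV if modal is None else f"{modal[0]}:{modal[1]}"
    return name, count / cluster.n_reads


def validate_pair(
    cluster: BarcodeCluster,
    called: tuple[str, float],
    manifest: VariantManifest,
    min_concordance: float = 0.5,
    max_truncated: float = 0.20,
    truncation_margin: int = 50,
) -> LibraryQCRecord:
    """Apply the concordance and truncation rules to one cluster.

    A read is truncated when its aligned span is at least
    ``truncation_margin`` bases short of the reference length. Verdict
    precedence: unmatched representative, then concordance, then
    truncation.
    """
    called_snv, fraction = called
    expected = len(manifest.reference)
    n_trunc = sum(obs.span <= expected - truncation_margin for obs in cluster.reads)
    trunc_fraction = n_trunc / cluster.n_reads if cluster.n_reads else 0.0

    snv_of = manifest.designed_snv()
    variant_of = manifest.barcode_to_variant()
    if cluster.representative not in snv_of:
        verdict, variant_id = "fail_unmatched", None
    else:
        variant_id = variant_of[cluster.representative]
        pos, alt = snv_of[cluster.representative]
        designed = f"{pos}:{alt}"
        if fraction < min_concordance or called_snv != designed:
            verdict = "fail_concordance"
        elif trunc_fraction >= max_truncated:
            verdict = "fail_truncation"
        else:
            verdict = "pass"
    return LibraryQCRecord(
        representative=cluster.representative,
        variant_id=variant_id,
        called_snv=called_snv,
        snv_fraction=fraction,
        truncated_fraction=trunc_fraction,
        verdict=verdict,
    )


def run_library_qc(
    reads: Iterable[tuple[str, str]],
    manifest: VariantManifest,
    max_edit: int = 1,
    method: str = "directional",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full library QC: parse reads, cluster barcodes, validate each pair.

    Returns the per-cluster QC table and the validated variant-to-barcode
    whitelist (variant_id, barcode) of passing clusters. Variants left
    with zero passing barcodes are logged.
    """
    observations = []
    n_unparseable = 0
    for read_id, seq in reads:
        obs = parse_long_read(read_id, seq, manifest)
        if obs is None:
            n_unparseable += 1
        else:
            observations.append(obs)
    if not observations:
        raise ValueError("no reads with a locatable barcode cassette")
    if n_unparseable:
        logger.info("library QC: %d reads without a locatable flank", n_unparseable)

    counts: dict[str, int] = {}
    for obs in observations:
        counts[obs.barcode] = counts.get(obs.barcode, 0) + 1
    clusters = cluster_barcodes(counts, max_edit=max_edit, method=method)
    _attach_reads(clusters, observations)

    records = []
    for cluster in clusters:
        if not cluster.reads:
            continue
        called = call_cluster_variant(cluster)
        records.append(validate_pair(cluster, called, manifest))
    qc = pd.DataFrame(
        [
            {
                "barcode": r.representative,
                "variant_id": r.variant_id,
                "called_snv": r.called_snv,
                "snv_fraction": r.snv_fraction,
                "truncated_fraction": r.truncated_fraction,
                "verdict": r.verdict,
            }
            for r in records
        ]
    )
    whitelist = (
        qc.loc[qc["verdict"] == "pass", ["variant_id", "barcode"]]
        .sort_values("variant_id")
        .reset_index(drop=True)
    )
    lost = set(manifest.entries["variant_id"]) - set(whitelist["variant_id"])
    if lost:
        logger.warning(
            "library QC: %d variants left with zero passing barcodes", len(lost)
        )
    return qc, whitelist


def run_library_qc_files(
    reads_path: str | os.PathLike,
    manifest_path: str | os.PathLike,
    outdir: str | os.PathLike,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """File-level wrapper: FASTQ/FASTA + manifest TSV in, TSVs out."""
    manifest = VariantManifest.from_tsv(manifest_path)
    qc, whitelist = run_library_qc(read_fastq(reads_path), manifest, **kwargs)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc.to_csv(outdir / "library_qc.tsv", sep="\t", index=False)
    whitelist.to_csv(outdir / "whitelist.tsv", sep="\t", index=False)
    return qc, whitelist
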