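"""Associate cells to variants from the variant-cell-barcode (VCB) library.

Read 1 carries the 16 bp cell barcode and 12 bp UMI; Read 2 carries the
8 bp variant barcode between constant flanks. Extracted barcodes are
matched against their reference sets (the library-QC whitelist for
variant barcodes; the expression matrix's barcode list for cell barcodes)
allowing one substitution; UMIs are collapsed with adjacency network
clustering. A cell-to-variant association is valid when

1. the number of unique transcript UMIs for the cell barcode is >= 3,
2. a single variant barcode achieves a > 0.5 fraction of those UMIs, and
3. the variant barcode with the second highest fraction does not
   exceed 0.25.

Ambiguous single-mismatch matches (two reference entries at the minimal
qualifying distance) drop the read: a false assignment is costlier than a
lost read, and designed barcodes sit at pairwise distance >= 3, so
ambiguity only arises from errors. N bases count as mismatches.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from mave_evidence.library_qc import find_flank
from mave_evidence.network import n_clusters

logger = logging.getLogger(__name__)

AMBIGUOUS = "__ambiguous__"


@dataclass(frozen=True)
class VCBRead:
    """One parsed VCB read pair."""

    cell_barcode: str
    umi: str
    variant_barcode: str


@dataclass(frozen=True)
class CellVariantAssignment:
    """A valid cell-to-variant association and the fractions behind it."""

    cell_barcode: str
    variant_id: str
    n_umis: int
    top_fraction: float
    second_fraction: float

    def __post_init__(self) -> None:
        if not (
            self.n_umis >= 3
            and self.top_fraction > 0.5
            and self.second_fraction <= 0.25
        ):
            raise ValueError("assignment violates the validity criteria")


def extract_fields(
    read1: str,
    read2: str,
    flank_left: str,
    cell_barcode_length: int = 16,
    umi_length: int = 12,
    variant_barcode_length: int = 8,
) -> VCBRead | str:
    """Slice the VCB fields from a read pair.

    The cell barcode and UMI sit at fixed offsets of Read 1; the variant
    barcode is located by an exact-then-1-mismatch search for the left
    flank in Read 2 (PCR constructs shift, so no fixed offset). Returns a
    rejection reason string when a field cannot be recovered.
    """
    if len(read1) < cell_barcode_length + umi_length:
        return "read1_too_short"
    flank_pos = find_flank(read2, flank_left)
    if flank_pos < 0:
        return "flank_not_found"
    start = flank_pos + len(flank_left)
    variant_barcode = read2[start : start + variant_barcode_length]
    if len(variant_barcode) < variant_barcode_length:
        return "read2_too_short"
    return VCBRead(
        cell_barcode=read1[:cell_barcode_length],
        umi=read1[cell_barcode_length : cell_barcode_length + umi_length],
        variant_barcode=variant_barcode,
    )


def match_barcode(
    observed: str, whitelist: Sequence[str] | set[str], max_mismatch: int = 1
) -> str | None:
    """Match an observed barcode against a reference set.

    Exact matches win immediately; otherwise the unique entry within
    ``max_mismatch`` substitutions. Returns ``AMBIGUOUS`` when two or
    more entries tie at the minimal qualifying distance, None when no
    entry qualifies. N (or any non-ACGT base) counts as a mismatch.
    """
    if observed in whitelist:
        return observed
    best: list[str] = []
    best_d = max_mismatch + 1
    for entry in whitelist:
        if len(entry) != len(observed):
            raise ValueError("whitelist entry length differs from observed barcode")
        d = sum(a != b for a, b in zip(observed, entry))
        if d < best_d:
            best, best_d = [entry], d
        elif d == best_d:
            best.append(entry)
    if best_d > max_mismatch:
        return None
    return best[0] if len(best) == 1 else AMBIGUOUS


class BarcodeMatcher:
    """Indexed single-mismatch barcode matcher.

    Precomputes, for every whitelist entry, its length masked patterns
    (one position wildcarded at a time), so a query resolves in O(length)
    dictionary lookups instead of a whitelist scan. Semantics are
    identical to :func:`match_barcode` with ``max_mismatch=1``.
    """

    def __init__(self, whitelist: Iterable[str]):
        self.whitelist = set(whitelist)
        lengths = {len(w) for w in self.whitelist}
        if len(lengths) > 1:
            raise ValueError("whitelist entries must have equal length")
        self.length = lengths.pop() if lengths else 0
        self._masked: dict[str, list[str]] = defaultdict(list)
        for entry in sorted(self.whitelist):
            for i in range(self.length):
                self._masked[entry[:i] + "*" + entry[i + 1 :]].append(entry)

    def match(self, observed: str) -> str | None:
        if observed in self.whitelist:
            return observed
        if len(observed) != self.length:
            raise ValueError("observed barcode length differs from whitelist")
        hits: set[str] = set()
        for i in range(self.length):
            key = observed[:i] + "*" + observed[i + 1 :]
            hits.update(self._masked.get(key, ()))
        if not hits:
            return None
        return hits.pop() if len(hits) == 1 else AMBIGUOUS


def collapse_umis(umi_counts: Mapping[str, int], max_edit: int = 1) -> int:
    """Number of unique UMIs after adjacency network collapse."""
    if not umi_counts:
        return 0
    return n_clusters(umi_counts, max_edit=max_edit, method="adjacency")


def assign_cells(
    table: Mapping[str, Mapping[str, int]],
    variant_of_barcode: Mapping[str, str],
    min_umis: int = 3,
    min_top_fraction: float = 0.5,
    max_second_fraction: float = 0.25,
) -> tuple[list[CellVariantAssignment], pd.DataFrame]:
    """Apply the three validity criteria to per-cell unique-UMI counts.

    ``table`` maps cell barcode -> variant barcode -> unique (collapsed)
    UMI count. The fractions in criteria 2-3 share the criterion-1
    denominator: total unique UMIs for the cell across variant barcodes.
    The top fraction must strictly exceed 0.5; the runner-up fraction may
    equal 0.25. Returns valid assignments plus a table of unassigned
    cells with the first failed criterion.
    """
    assignments: list[CellVariantAssignment] = []
    unassigned = []
    for cell in table:
        counts = table[cell]
        total = sum(counts.values())
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top_bc, top_n = ranked[0]
        second_n = ranked[1][1] if len(ranked) > 1 else 0
        top_frac = top_n / total
        second_frac = second_n / total
        if total < min_umis:
            reason = "min_umis"
        elif not top_frac > min_top_fraction:
            reason = "top_fraction"
        elif second_frac > max_second_fraction:
            reason = "runner_up"
        else:
            assignments.append(
                CellVariantAssignment(
                    cell_barcode=cell,
                    variant_id=variant_of_barcode[top_bc],
                    n_umis=total,
                    top_fraction=top_frac,
                    second_fraction=second_frac,
                )
            )
            continue
        unassigned.append(
            {
                "cell_barcode": cell,
                "n_umis": total,
                "top_fraction": top_frac,
                "second_fraction": second_frac,
                "failed_criterion": reason,
            }
        )
    unassigned_df = pd.DataFrame(
        unassigned,
        columns=["cell_barcode", "n_umis", "top_fraction", "second_fraction", "failed_criterion"],
    )
    return assignments, unassigned_df


def run_assignment(
    read_pairs: Iterable[tuple[str, str]],
    whitelist: Mapping[str, str] | pd.DataFrame,
    cell_barcodes: Iterable[str],
    flank_left: str,
    cell_barcode_length: int = 16,
    umi_length: int = 12,
    variant_barcode_length: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full assignment stage on an iterable of (read1, read2) sequences.

    ``whitelist`` maps validated variant barcode -> variant_id (or is the
    library-QC whitelist table). Cell barcodes outside the matrix-derived
    reference list contribute nothing. Returns the assignments table, the
    unassigned table, and a summary of reads seen/rejected by reason.
    """
    if isinstance(whitelist, pd.DataFrame):
        whitelist = dict(zip(whitelist["barcode"], whitelist["variant_id"]))
    vbc_matcher = BarcodeMatcher(whitelist)
    cell_matcher = BarcodeMatcher(cell_barcodes)

    summary: Counter[str] = Counter()
    # cell -> variant barcode -> raw UMI counts (collapsed later)
    raw: dict[str, dict[str, Counter]] = defaultdict(lambda: defaultdict(Counter))
    for read1, read2 in read_pairs:
        summary["reads_seen"] += 1
        parsed = extract_fields(
            read1,
            read2,
            flank_left,
            cell_barcode_length=cell_barcode_length,
            umi_length=umi_length,
            variant_barcode_length=variant_barcode_length,
        )
        if isinstance(parsed, str):
            summary[f"rejected_{parsed}"] += 1
            continue
        cell = cell_matcher.match(parsed.cell_barcode)
        if cell is None:
            summary["rejected_cell_barcode_unmatched"] += 1
            continue
        if cell == AMBIGUOUS:
            summary["rejected_cell_barcode_ambiguous"] += 1
            continue
        vbc = vbc_matcher.match(parsed.variant_barcode)
        if vbc is None:
            summary["rejected_variant_barcode_unmatched"] += 1
            continue
        if vbc == AMBIGUOUS:
            summary["rejected_variant_barcode_ambiguous"] += 1
            continue
        raw[cell][vbc][parsed.umi] += 1
        summary["reads_used"] += 1

    table = {
        cell: {vbc: collapse_umis(umis) for vbc, umis in by_vbc.items()}
        for cell, by_vbc in raw.items()
    }
    assignments, unassigned = assign_cells(table, whitelist)
    assignments_df = pd.DataFrame(
        [
            {
                "cell_barcode": a.cell_barcode,
                "variant_id": a.variant_id,
                "n_umis": a.n_umis,
                "top_fraction": a.top_fraction,
                "second_fraction": a.second_fraction,
            }
            for a in assignments
        ],
        columns=["cell_barcode", "variant_id", "n_umis", "top_fraction", "second_fraction"],
    ).sort_values("cell_barcode").reset_index(drop=True)
    summary["cells_assigned"] = len(assignments_df)
    summary["cells_unassigned"] = len(unassigned)
    logger.info(
        "assignment: %d reads, %d cells assigned, %d unassigned",
        summary["reads_seen"],
        summary["cells_assigned"],
        summary["cells_unassigned"],
    )
    return assignments_df, unassigned, dict(summary)


def run_assignment_files(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike,
    whitelist_path: str | os.PathLike,
    cells_path: str | os.PathLike,
    manifest_flank_left: str,
    outdir: str | os.PathLike,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """File-level wrapper over :func:`run_assignment`."""
    from mave_evidence.io import read_fastq

    whitelist = pd.read_csv(whitelist_path, sep="\t", dtype=str)
    cells = pd.read_csv(cells_path, header=None)[0].astype(str)
    pairs = (
        (s1, s2)
        for (_, s1), (_, s2) in zip(read_fastq(r1_path), read_fastq(r2_path))
    )
    assignments, unassigned, summary = run_assignment(
        pairs, whitelist, cells, manifest_flank_left, **kwargs
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    unassigned.to_csv(outdir / "unassigned.tsv", sep="\t", index=False)
    with open(outdir / "assignment_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return assignments, unassigned, summary
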