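"""Seeded generator of every input the MAVE evidence pipeline consumes.

Emulates a pooled single-cell variant-effect experiment: a designed
variant manifest with unique 3'-UTR barcodes, long-read consensus
sequencing of the cloned library, the targeted variant-cell-barcode (VCB)
library pairing 10x cell barcodes with variant barcodes, the single-cell
expression count matrix, known pathogenic/benign labels, and baseline
evidence points. Pathogenic variants shift the expression of a module of
genes by a configurable fold-change; unlabeled (VUS) variants are drawn
from a mixture of the pathogenic and benign expression regimes; ambient
contamination, barcode substitution errors, read truncations and
low-quality cells are injected at configurable rates.

All randomness derives from ``SimulationConfig.seed``; identical configs
give bit-identical outputs. Each generator draws from an independent
stream (seed plus a fixed stage offset) so outputs do not depend on the
order in which generators are invoked.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
import scipy.sparse as sp

from mave_evidence.config import SimulationConfig
from mave_evidence.io import VariantManifest, write_fastq, write_mtx_triple
from mave_evidence.network import hamming

BASES = np.array(list("ACGT"))

# Constant 10 bp anchors flanking the variant barcode in the 3'-UTR
# construct; recorded in the manifest header for downstream stages.
FLANK_LEFT = "GTCAGTCGGA"
FLANK_RIGHT = "TTCGAGCGAT"

# independent substream offsets per generator
_STREAM_MANIFEST = 1
_STREAM_TRUTH = 2
_STREAM_LONG_READS = 3
_STREAM_VCB = 4
_STREAM_EXPRESSION = 5
_STREAM_BASELINE = 6


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-base substitution at the given rate (never to the same base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[rng.integers(0, len(choices))].encode()
    return arr.tobytes().decode()


@dataclass
class GroundTruth:
    """Hidden state of a simulated experiment, kept for recovery tests.

    ``pathogenic_like`` records which variants were drawn from the shifted
    expression regime: all pathogenic variants, plus the half of unlabeled
    (VUS) variants sampled from the pathogenic mixture component.
    """

    variant_labels: dict[str, str]
    cell_to_variant: dict[str, str]
    gene_names: list[str]
    gene_ids: list[str]
    gene_baseline: list[float]
    module_genes: list[str]
    mito_genes: list[str]
    pathogenic_like: dict[str, bool]
    low_quality_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        variants = set(self.variant_labels)
        if not set(self.cell_to_variant.values()) <= variants:
            raise ValueError("every truth cell must map to a manifest variant")
        if not set(self.module_genes) <= set(self.gene_names):
            raise ValueError("module gene set must lie within the gene universe")

    @property
    def cells(self) -> list[str]:
        return list(self.cell_to_variant)

    def labels_table(self) -> pd.DataFrame:
        """Known pathogenic/benign label table (unlabeled variants absent)."""
        rows = [
            {"variant_id": v, "label": lab}
            for v, lab in self.variant_labels.items()
            if lab in ("pathogenic", "benign")
        ]
        return pd.DataFrame(rows, columns=["variant_id", "label"])

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_manifest(config: SimulationConfig) -> VariantManifest:
    """Design ``n_variants`` SNVs, each tagged with a unique barcode.

    Barcodes are drawn by rejection sampling under a pairwise Hamming
    distance >= 3 constraint, which makes downstream single-mismatch
    barcode correction provably unambiguous. Each variant receives a
    distinct (position, ref, alt) SNV on a simulated coding sequence.
    """
    rng = _rng(config, _STREAM_MANIFEST)
    n = config.n_variants
    if 4**config.barcode_length < n:
        raise ValueError(
            f"barcode space 4^{config.barcode_length} cannot hold {n} variants"
        )
    if 3 * config.coding_length < n:
        raise ValueError("coding sequence too short for distinct SNVs")

    reference = _random_seq(rng, config.coding_length)

    barcodes: list[str] = []
    attempts = 0
    max_attempts = 2000 * n + 10000
    while len(barcodes) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} barcodes of length "
                f"{config.barcode_length} at pairwise Hamming distance >= 3"
            )
        candidate = _random_seq(rng, config.barcode_length)
        if all(hamming(candidate, b) >= 3 for b in barcodes):
            barcodes.append(candidate)

    # distinct (pos, alt-offset) pairs; alt = ref shifted by 1..3 in base order
    combos = rng.choice(3 * config.coding_length, size=n, replace=False)
    rows = []
    base_index = {b: i for i, b in enumerate("ACGT")}
    for i in range(n):
        pos = int(combos[i]) // 3
        shift = int(combos[i]) % 3 + 1
        ref = reference[pos]
        alt = "ACGT"[(base_index[ref] + shift) % 4]
        rows.append(
            {
                "variant_id": f"V{i:04d}",
                "gene": config.gene_symbol,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "barcode": barcodes[i],
            }
        )
    entries = pd.DataFrame(rows, columns=["variant_id", "gene", "pos", "ref", "alt", "barcode"])
    return VariantManifest(
        entries=entries,
        reference=reference,
        flank_left=FLANK_LEFT,
        flank_right=FLANK_RIGHT,
    )


def generate_truth(manifest: VariantManifest, config: SimulationConfig) -> GroundTruth:
    """Assign labels, cells, gene baselines and the perturbed gene module."""
    rng = _rng(config, _STREAM_TRUTH)
    variants = list(manifest.entries["variant_id"])
    n = len(variants)
    n_path = int(round(config.frac_pathogenic * n))
    n_benign = int(round(config.frac_benign * n))
    n_benign = min(n_benign, n - n_path)
    labels = (
        ["pathogenic"] * n_path
        + ["benign"] * n_benign
        + ["vus"] * (n - n_path - n_benign)
    )
    perm = rng.permutation(n)
    variant_labels = {variants[perm[i]]: labels[i] for i in range(n)}
    variant_labels = {v: variant_labels[v] for v in variants}

    pathogenic_like = {
        v: (lab == "pathogenic") or (lab == "vus" and rng.random() < 0.5)
        for v, lab in variant_labels.items()
    }

    # unique cell barcodes
    cells: list[str] = []
    seen: set[str] = set()
    total_cells = n * config.n_cells_per_variant
    while len(cells) < total_cells:
        bc = _random_seq(rng, config.cell_barcode_length)
        if bc not in seen:
            seen.add(bc)
            cells.append(bc)
    cell_to_variant = {
        cells[i]: variants[i // config.n_cells_per_variant] for i in range(total_cells)
    }
    n_lowq = int(round(config.low_quality_fraction * total_cells))
    low_quality = [cells[i] for i in rng.choice(total_cells, size=n_lowq, replace=False)]

    # gene universe: mito genes first, then nuclear genes
    gene_names = [f"MT-G{i}" for i in range(config.n_mito_genes)] + [
        f"G{i:04d}" for i in range(config.n_genes - config.n_mito_genes)
    ]
    gene_ids = [f"ENSG{i:08d}" for i in range(config.n_genes)]
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    mito = np.zeros(config.n_genes, dtype=bool)
    mito[: config.n_mito_genes] = True
    baseline = np.empty(config.n_genes)
    if config.n_mito_genes:
        baseline[mito] = weights[mito] / weights[mito].sum() * config.mito_fraction_mean
        baseline[~mito] = (
            weights[~mito] / weights[~mito].sum() * (1 - config.mito_fraction_mean)
        )
    else:
        baseline = weights / weights.sum()
    nuclear_idx = np.nonzero(~mito)[0]
    module_idx = rng.choice(nuclear_idx, size=config.n_module_genes, replace=False)
    module_genes = [gene_names[i] for i in sorted(module_idx)]

    return GroundTruth(
        variant_labels=variant_labels,
        cell_to_variant=cell_to_variant,
        gene_names=gene_names,
        gene_ids=gene_ids,
        gene_baseline=baseline.tolist(),
        module_genes=module_genes,
        mito_genes=gene_names[: config.n_mito_genes],
        pathogenic_like=pathogenic_like,
        low_quality_cells=low_quality,
    )


def simulate_long_reads(
    manifest: VariantManifest, config: SimulationConfig
) -> list[tuple[str, str]]:
    """Consensus long reads of the cloned variant library.

    Each read spans the full coding sequence (carrying the designed SNV)
    followed by the 3'-UTR barcode cassette. A configured fraction of
    reads is truncated by 50-150 bp at the 5' (coding) end — the barcode
    cassette sits at the 3' end, so truncated reads remain identifiable
    and countable against the 20% truncation rule. Barcode bases are
    substituted at ``barcode_error_rate``.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    rng = _rng(config, _STREAM_LONG_READS)
    reads: list[tuple[str, str]] = []
    for row in manifest.entries.itertuples():
        coding = (
            manifest.reference[: row.pos] + row.alt + manifest.reference[row.pos + 1 :]
        )
        for j in range(config.long_read_depth):
            barcode = _mutate(rng, row.barcode, config.barcode_error_rate)
            seq = coding
            if rng.random() < config.truncation_rate:
                cut = int(rng.integers(50, 151))
                seq = seq[cut:]
            seq = seq + manifest.flank_left + barcode + manifest.flank_right
            reads.append((f"{row.variant_id}_r{j}", seq))
    return reads


def simulate_vcb_reads(
    truth: GroundTruth, manifest: VariantManifest, config: SimulationConfig
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Paired VCB reads linking cell barcodes to variant barcodes.

    Read 1 = 16 bp cell barcode + 12 bp UMI; Read 2 = 0-3 random bases,
    the left flank, the 8 bp variant barcode, the right flank. Each cell
    emits at least 3 unique UMIs for its true variant; ``ambient_rate``
    of reads instead carry a random other variant's barcode under a
    fresh UMI. Substitution errors hit the cell barcode, UMI and variant
    barcode at ``barcode_error_rate`` per base.
    """
    rng = _rng(config, _STREAM_VCB)
    bc_of = dict(zip(manifest.entries["variant_id"], manifest.entries["barcode"]))
    all_barcodes = list(manifest.entries["barcode"])
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    idx = 0
    for cell, variant in truth.cell_to_variant.items():
        true_bc = bc_of[variant]
        n_umis = 3 + int(rng.poisson(max(config.mean_umis_per_cell - 3, 0)))
        for _ in range(n_umis):
            umi = _random_seq(rng, config.umi_length)
            n_dup = 1 + int(rng.poisson(1.0))
            for _ in range(n_dup):
                vbc, read_umi = true_bc, umi
                if len(all_barcodes) > 1 and rng.random() < config.ambient_rate:
                    vbc = all_barcodes[int(rng.integers(0, len(all_barcodes)))]
                    while vbc == true_bc:
                        vbc = all_barcodes[int(rng.integers(0, len(all_barcodes)))]
                    read_umi = _random_seq(rng, config.umi_length)
                cb = _mutate(rng, cell, config.barcode_error_rate)
                read_umi = _mutate(rng, read_umi, config.barcode_error_rate)
                vbc = _mutate(rng, vbc, config.barcode_error_rate)
                prefix = _random_seq(rng, int(rng.integers(0, 4)))
                r1.append((f"vcb_{idx}", cb + read_umi))
                r2.append(
                    (f"vcb_{idx}", prefix + manifest.flank_left + vbc + manifest.flank_right)
                )
                idx += 1
    return r1, r2


def simulate_expression(truth: GroundTruth, config: SimulationConfig) -> AnnData:
    """Negative-binomial single-cell counts with a variant-dependent shift.

    Cells of pathogenic-regime variants have module-gene relative
    expression multiplied by ``effect_size`` (renormalized, so the shift
    is compositional, as seen by row-sum normalization downstream).
    Low-quality cells get totals below 5000 UMIs and a tripled
    mitochondrial fraction.
    """
    rng = _rng(config, _STREAM_EXPRESSION)
    n_genes = len(truth.gene_names)
    p0 = np.asarray(truth.gene_baseline, dtype=float)
    name_to_idx = {g: i for i, g in enumerate(truth.gene_names)}
    module = np.array([name_to_idx[g] for g in truth.module_genes], dtype=int)
    mito = np.array([name_to_idx[g] for g in truth.mito_genes], dtype=int)

    p1 = p0.copy()
    if module.size:
        p1[module] *= config.effect_size
    p1 /= p1.sum()

    def lowq(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        if mito.size:
            q[mito] *= 3.0
        return q / q.sum()

    profiles = np.vstack([p0, p1, lowq(p0), lowq(p1)])

    cells = truth.cells
    lowq_set = set(truth.low_quality_cells)
    shifted = np.array(
        [truth.pathogenic_like[truth.cell_to_variant[c]] for c in cells], dtype=int
    )
    is_lowq = np.array([c in lowq_set for c in cells], dtype=int)
    regime = shifted + 2 * is_lowq

    totals = rng.lognormal(
        mean=np.log(config.mean_cell_total_umi), sigma=0.25, size=len(cells)
    )
    totals[is_lowq == 1] = rng.uniform(500, 4000, size=int(is_lowq.sum()))

    mu = totals[:, None] * profiles[regime]
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int32)

    adata = AnnData(
        X=sp.csr_matrix(counts),
        var=pd.DataFrame(
            {"gene_id": truth.gene_ids},
            index=pd.Index(truth.gene_names, name="gene_name"),
        ),
    )
    adata.obs_names = cells
    return adata


def generate_baseline_evidence(
    manifest: VariantManifest, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Baseline benign/pathogenic evidence points per variant.

    Stands in for the non-functional evidence a clinical laboratory holds
    before the assay. Unlabeled (VUS) variants draw points strictly below
    every classification threshold; labeled variants may sit near their
    axis's threshold, so assay evidence can complete a likely-pathogenic /
    likely-benign / upgraded classification.
    """
    rng = _rng(config, _STREAM_BASELINE)
    rows = []
    for variant in manifest.entries["variant_id"]:
        label = truth.variant_labels[variant]
        if label == "pathogenic":
            b = 0.0
            p = float(rng.choice([3.0, 3.5, 4.0, 5.0], p=[0.4, 0.2, 0.3, 0.1]))
        elif label == "benign":
            b = float(rng.choice([2.0, 3.0, 4.0], p=[0.3, 0.4, 0.3]))
            p = 0.0
        else:
            b = float(rng.choice([0.0, 1.0, 2.0], p=[0.6, 0.3, 0.1]))
            p = float(rng.choice([0.0, 1.0, 2.0, 3.0], p=[0.5, 0.25, 0.15, 0.1]))
        rows.append(
            {"variant_id": variant, "benign_points": b, "pathogenic_points": p}
        )
    return pd.DataFrame(rows, columns=["variant_id", "benign_points", "pathogenic_points"])


def simulate_all(config: SimulationConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Generate and write every pipeline input; returns artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = generate_manifest(config)
    truth = generate_truth(manifest, config)

    manifest.to_tsv(outdir / "manifest.tsv")
    write_fastq(outdir / "long_reads.fastq", simulate_long_reads(manifest, config))
    r1, r2 = simulate_vcb_reads(truth, manifest, config)
    write_fastq(outdir / "vcb_R1.fastq", r1)
    write_fastq(outdir / "vcb_R2.fastq", r2)
    adata = simulate_expression(truth, config)
    write_mtx_triple(adata, outdir / "matrix")
    truth.labels_table().to_csv(outdir / "labels.tsv", sep="\t", index=False)
    generate_baseline_evidence(manifest, truth, config).to_csv(
        outdir / "baseline.tsv", sep="\t", index=False
    )
    truth.to_json(outdir / "truth.json")
    return {
        "manifest": str(outdir / "manifest.tsv"),
        "long_reads": str(outdir / "long_reads.fastq"),
        "vcb_r1": str(outdir / "vcb_R1.fastq"),
        "vcb_r2": str(outdir / "vcb_R2.fastq"),
        "matrix": str(outdir / "matrix"),
        "labels": str(outdir / "labels.tsv"),
        "baseline": str(outdir / "baseline.tsv"),
        "truth": str(outdir / "truth.json"),
    }
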