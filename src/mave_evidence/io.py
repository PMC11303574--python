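"""File formats: variant manifest TSV, FASTQ, CellRanger-style MTX triple.

The manifest TSV carries the designed variants (variant_id, gene, pos,
ref, alt, barcode) plus header comment lines recording the reference
coding sequence and the constant flanks surrounding the variant barcode,
which downstream stages need as anchors.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from Bio import SeqIO
from scipy.io import mmread, mmwrite

MANIFEST_COLUMNS = ["variant_id", "gene", "pos", "ref", "alt", "barcode"]


@dataclass
class VariantManifest:
    """Designed variants, their barcodes, and the shared reference context.

    Attributes
    ----------
    entries
        One row per designed variant: variant_id, gene, pos (0-based on
        ``reference``), ref, alt, barcode.
    reference
        Reference coding sequence of the target gene.
    flank_left, flank_right
        Constant sequences immediately flanking the variant barcode in the
        transcript 3'-UTR; used to locate barcodes in reads.
    """

    entries: pd.DataFrame
    reference: str
    flank_left: str
    flank_right: str

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        barcodes = self.entries["barcode"]
        if barcodes.duplicated().any():
            raise ValueError("manifest barcodes must be unique")
        if barcodes.str.len().nunique() > 1:
            raise ValueError("manifest barcodes must have uniform length")
        for _, row in self.entries.iterrows():
            if self.reference[int(row.pos)] != row.ref:
                raise ValueError(
                    f"{row.variant_id}: ref base {row.ref} does not match "
                    f"reference at position {row.pos}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def barcode_length(self) -> int:
        return int(self.entries["barcode"].str.len().iloc[0])

    @property
    def barcodes(self) -> set[str]:
        return set(self.entries["barcode"])

    def barcode_to_variant(self) -> dict[str, str]:
        return dict(zip(self.entries["barcode"], self.entries["variant_id"]))

    def designed_snv(self) -> dict[str, tuple[int, str]]:
        """Map barcode -> (position, alt base) of its designed SNV."""
        return {
            row.barcode: (int(row.pos), row.alt)
            for row in self.entries.itertuples()
        }

    def to_tsv(self, path: str | os.PathLike) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"#reference={self.reference}\n")
            fh.write(f"#flank_left={self.flank_left}\n")
            fh.write(f"#flank_right={self.flank_right}\n")
            self.entries.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "VariantManifest":
        header: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].rstrip("\n").partition("=")
                header[key] = value
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            entries = pd.read_csv(fh, sep="\t", dtype={"barcode": str, "ref": str, "alt": str})
        for key in ("reference", "flank_left", "flank_right"):
            if key not in header:
                raise ValueError(f"manifest header missing #{key}=")
        return cls(
            entries=entries,
            reference=header["reference"],
            flank_left=header["flank_left"],
            flank_right=header["flank_right"],
        )


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs as standard 4-line FASTQ with
    constant 'I' qualities (consensus reads carry no per-base model)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ or FASTA file."""
    fmt = "fasta" if str(path).endswith((".fa", ".fasta")) else "fastq"
    for record in SeqIO.parse(str(path), fmt):
        yield record.id, str(record.seq)


def write_mtx_triple(adata: AnnData, outdir: str | os.PathLike) -> None:
    """Write a cells-by-genes AnnData as a CellRanger-dialect MTX triple
    (matrix.mtx genes-by-cells, barcodes.tsv, features.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = sp.csc_matrix(adata.X.T)
    mmwrite(str(outdir / "matrix.mtx"), matrix, field="integer")
    with open(outdir / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{bc}\n" for bc in adata.obs_names)
    features = pd.DataFrame(
        {
            "gene_id": adata.var["gene_id"]
            if "gene_id" in adata.var
            else adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    features.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)


def read_mtx_triple(indir: str | os.PathLike) -> AnnData:
    """Read a CellRanger-dialect MTX triple into a cells-by-genes AnnData."""
    indir = Path(indir)
    matrix = sp.csr_matrix(mmread(str(indir / "matrix.mtx")).T)
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].astype(str)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    var = pd.DataFrame(
        {"gene_id": features[0].astype(str).values},
        index=pd.Index(features[1].astype(str).values, name="gene_name"),
    )
    adata = AnnData(X=matrix, var=var)
    adata.obs_names = barcodes.values
    return adata
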