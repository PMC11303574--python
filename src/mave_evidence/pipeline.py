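"""End-to-end orchestration: simulate -> library QC -> assignment ->
cell QC -> modeling -> calibration -> classification -> report.

Every stage writes plain-text artifacts plus a provenance block (output
hashes, config echo, library versions, seed) into the run manifest, so a
run is inspectable and reproducible from its output directory alone.
Stage failures halt the pipeline with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path
from typing import Any

from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd
import scipy
import sklearn

import mave_evidence
from mave_evidence import synthetic
from mave_evidence.cell_assignment import run_assignment
from mave_evidence.cell_qc import run_cell_qc
from mave_evidence.classification import (
    apply_evidence,
    summarize,
    tier_count_table,
)
from mave_evidence.calibration import run_calibration
from mave_evidence.config import PipelineConfig
from mave_evidence.io import (
    VariantManifest,
    read_fastq,
    read_mtx_triple,
    write_fastq,
    write_mtx_triple,
)
from mave_evidence.library_qc import run_library_qc
from mave_evidence.modeling import build_profiles, filter_genes, train_and_score

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _provenance(stage: str, outputs: list[Path], config_echo: Any, seed: int) -> dict:
    return {
        "stage": stage,
        "outputs": {p.name: _sha256(p) for p in outputs if p.is_file()},
        "config": config_echo,
        "seed": seed,
        "versions": {
            "mave_evidence": mave_evidence.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "anndata": _pkg_version("anndata"),
        },
    }


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | os.PathLike = "mave_run",
) -> dict:
    """Execute the configured stages; returns the run manifest.

    With the ``simulate`` stage enabled (default) all inputs are
    generated under ``outdir/inputs``; otherwise they must already exist
    there (standard formats: manifest TSV, FASTQs, MTX triple, labels and
    baseline TSVs).
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = outdir / "inputs"
    manifest_blocks: list[dict] = []
    stage = "setup"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            paths = synthetic.simulate_all(config.simulation, inputs)
            manifest_blocks.append(
                _provenance(
                    stage,
                    [Path(p) for p in paths.values()],
                    dataclasses.asdict(config.simulation),
                    config.seed,
                )
            )
        vmanifest = VariantManifest.from_tsv(inputs / "manifest.tsv")
        adata = read_mtx_triple(inputs / "matrix")

        stage = "libqc"
        qc, whitelist = run_library_qc(read_fastq(inputs / "long_reads.fastq"), vmanifest)
        qc.to_csv(outdir / "library_qc.tsv", sep="\t", index=False)
        whitelist.to_csv(outdir / "whitelist.tsv", sep="\t", index=False)
        manifest_blocks.append(
            _provenance(stage, [outdir / "library_qc.tsv", outdir / "whitelist.tsv"], {}, config.seed)
        )

        stage = "assign"
        pairs = (
            (s1, s2)
            for (_, s1), (_, s2) in zip(
                read_fastq(inputs / "vcb_R1.fastq"), read_fastq(inputs / "vcb_R2.fastq")
            )
        )
        assignments, unassigned, summary = run_assignment(
            pairs,
            whitelist,
            adata.obs_names,
            vmanifest.flank_left,
            cell_barcode_length=config.simulation.cell_barcode_length,
            umi_length=config.simulation.umi_length,
            variant_barcode_length=vmanifest.barcode_length,
        )
        assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        unassigned.to_csv(outdir / "unassigned.tsv", sep="\t", index=False)
        with open(outdir / "assignment_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        manifest_blocks.append(
            _provenance(stage, [outdir / "assignments.tsv"], {}, config.seed)
        )

        stage = "cellqc"
        kept_cells, per_cell, per_cluster = run_cell_qc(
            adata,
            mito_prefix=config.mito_prefix,
            top_k=config.qc_top_k,
            min_cluster_size=config.qc_min_cluster_size,
            direction=config.qc_direction,
        )
        pd.Series(kept_cells).to_csv(
            outdir / "kept_cells.tsv", sep="\t", index=False, header=False
        )
        per_cell.to_csv(outdir / "cell_qc.tsv", sep="\t", index_label="cell_barcode")
        per_cluster.to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
        manifest_blocks.append(
            _provenance(stage, [outdir / "kept_cells.tsv"], {"direction": config.qc_direction}, config.seed)
        )

        stage = "model"
        kept_assignments = assignments[assignments["cell_barcode"].isin(kept_cells)]
        genes = filter_genes(adata, kept_assignments, config.modeling.gene_filter_fraction)
        profiles, n_cells = build_profiles(
            adata, kept_assignments, genes, config.modeling.min_cells_per_variant
        )
        labels_df = pd.read_csv(inputs / "labels.tsv", sep="\t")
        labels = pd.Series(labels_df["label"].values, index=labels_df["variant_id"])
        scores, model_out = train_and_score(profiles, labels, config.modeling)
        scores = scores.merge(
            n_cells.rename_axis("variant_id").reset_index(), on="variant_id", how="left"
        )
        profiles.to_csv(outdir / "profiles.tsv", sep="\t", index_label="variant_id")
        scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        with open(outdir / "model_report.json", "w") as fh:
            json.dump(model_out["report"], fh, indent=1)
        manifest_blocks.append(
            _provenance(
                stage,
                [outdir / "scores.tsv"],
                dataclasses.asdict(config.modeling),
                config.seed,
            )
        )

        stage = "calibrate"
        tiers, calib_report = run_calibration(scores, labels, multi_assay=config.multi_assay)
        tiers.to_csv(outdir / "tiers.tsv", sep="\t", index=False)
        with open(outdir / "calibration.json", "w") as fh:
            json.dump(calib_report, fh, indent=1)
        manifest_blocks.append(
            _provenance(stage, [outdir / "tiers.tsv"], {"multi_assay": config.multi_assay}, config.seed)
        )

        stage = "classify"
        baseline = pd.read_csv(inputs / "baseline.tsv", sep="\t")
        records = apply_evidence(baseline, tiers)
        matrix = summarize(records)
        records.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        matrix.to_frame().to_csv(outdir / "transitions.tsv", sep="\t", index=False)
        tier_count_table(tiers).to_csv(outdir / "tier_counts.tsv", sep="\t", index=False)
        with open(outdir / "classification_summary.json", "w") as fh:
            json.dump(matrix.summary(), fh, indent=1)
        manifest_blocks.append(
            _provenance(stage, [outdir / "classification.tsv"], {}, config.seed)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline halted at stage '{stage}': {exc}") from exc

    run_manifest = {"seed": config.seed, "stages": manifest_blocks}
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1)
    logger.info("pipeline complete: %s", outdir)
    return run_manifest
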