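"""Run the whole pipeline end to end on synthetic data.

simulate -> library QC -> cell assignment -> cell QC -> modeling ->
calibration -> classification, with every intermediate written as a
plain-text artifact plus provenance hashes.
"""

import json
from pathlib import Path

from mave_evidence import ModelingConfig, PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulation=SimulationConfig(
        n_variants=16,
        n_cells_per_variant=30,
        n_genes=300,
        n_module_genes=30,
        coding_length=300,
        long_read_depth=40,
    ),
    modeling=ModelingConfig(n_features=100, n_pcs=8),
    qc_min_cluster_size=20,
    seed=11,
)
outdir = Path("example_output/full_run")
run_pipeline(config, outdir)

with open(outdir / "calibration.json") as fh:
    calib = json.load(fh)
with open(outdir / "classification_summary.json") as fh:
    summary = json.load(fh)

print(f"artifacts in {outdir}/")
print(f"model AUROC {calib['auroc']:.3f} (gate {calib['gate']}) -> tiers {calib['tier_counts']}")
print(
    f"VUS reclassification rate {summary['reclassification_rate_percent']}% "
    f"({summary['n_vus_reclassified']}/{summary['n_vus_total']})"
)
print("Re-running with the same seed reproduces every table byte for byte.")
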