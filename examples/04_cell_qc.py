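"""Remove low-quality cells with density clustering on five QC features.

Cells are clustered (HDBSCAN) on total UMIs, mitochondrial UMIs, percent
mitochondrial, detected genes and UMIs in the top-expressed genes;
clusters in which >= 20% of cells have under 5000 UMIs are dropped.
"""

import mave_evidence as me

config = me.SimulationConfig(
    n_variants=16, n_cells_per_variant=40, n_genes=300, n_module_genes=30,
    coding_length=300, seed=1,
)
manifest = me.generate_manifest(config)
truth = me.generate_truth(manifest, config)
adata = me.simulate_expression(truth, config)

kept, per_cell, per_cluster = me.run_cell_qc(adata, min_cluster_size=20)
print(per_cluster.to_string(index=False))
print(f"\nkept {len(kept)}/{adata.n_obs} cells")
lowq = set(truth.low_quality_cells)
print(
    f"of {len(lowq)} simulated low-quality cells, "
    f"{sum(c in lowq for c in kept)} slipped through"
)
print(
    "Each row is one density cluster; low_umi_proportion is its share of "
    "sub-5000-UMI cells, the quantity the keep/remove rule acts on."
)
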