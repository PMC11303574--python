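"""Configuration objects for simulation, modeling and pipeline orchestration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1]; got {value}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic single-cell MAVE experiment.

    Defaults follow the experimental design the generator emulates: pooled
    variant libraries with unique 8 bp barcodes in the transcript 3'-UTR,
    10x-style 16 bp cell barcodes and 12 bp UMIs, and a target of 100 cells
    per variant.

    Parameters
    ----------
    n_variants
        Number of designed single-nucleotide variants.
    frac_pathogenic, frac_benign
        Fractions of variants with known pathogenic / benign labels; the
        remainder are unlabeled (VUS). Must sum to at most 1.
    barcode_length, cell_barcode_length, umi_length
        Lengths (bases) of the variant barcode, cell barcode and UMI.
    n_cells_per_variant
        Cells recovered per variant.
    n_genes
        Genes in the expression readout (including mitochondrial genes).
    n_module_genes
        Genes whose expression shifts in cells carrying pathogenic variants.
    effect_size
        Multiplicative fold-change applied to module-gene expression in the
        pathogenic regime; 1.0 is the null (no signal).
    nb_dispersion
        Negative-binomial dispersion d, with variance mu + d * mu**2.
    mito_fraction_mean
        Expected fraction of a healthy cell's UMIs in mitochondrial genes.
    barcode_error_rate
        Per-base substitution probability applied to sequenced barcodes.
    truncation_rate
        Fraction of long reads truncated by >= 50 bp.
    ambient_rate
        Fraction of VCB reads carrying a random wrong variant barcode
        (ambient / template-switching contamination).
    low_quality_fraction
        Fraction of cells simulated as low quality (total UMI < 5000 with
        elevated mitochondrial fraction).
    long_read_depth
        Consensus long reads generated per designed barcode.
    mean_umis_per_cell
        Mean unique VCB UMIs per cell (at least 3 in the default regime).
    coding_length
        Length of the simulated reference coding sequence.
    n_mito_genes
        Number of genes given an "MT-" name prefix.
    seed
        Base seed; identical configs with identical seeds produce
        bit-identical outputs.
    """

    n_variants: int = 50
    frac_pathogenic: float = 0.4
    frac_benign: float = 0.4
    barcode_length: int = 8
    cell_barcode_length: int = 16
    umi_length: int = 12
    n_cells_per_variant: int = 100
    n_genes: int = 2000
    n_module_genes: int = 50
    effect_size: float = 4.0
    nb_dispersion: float = 0.5
    mito_fraction_mean: float = 0.05
    barcode_error_rate: float = 0.01
    truncation_rate: float = 0.05
    ambient_rate: float = 0.05
    low_quality_fraction: float = 0.08
    long_read_depth: int = 100
    mean_umis_per_cell: float = 8.0
    mean_cell_total_umi: float = 12000.0
    coding_length: int = 400
    n_mito_genes: int = 10
    gene_symbol: str = "GENE1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_pathogenic",
            "frac_benign",
            "nb_dispersion",
            "mito_fraction_mean",
            "barcode_error_rate",
            "truncation_rate",
            "ambient_rate",
            "low_quality_fraction",
        ):
            _check_fraction(name, getattr(self, name))
        if self.frac_pathogenic + self.frac_benign > 1.0 + 1e-12:
            raise ValueError("frac_pathogenic + frac_benign must not exceed 1")
        for name in (
            "n_variants",
            "barcode_length",
            "cell_barcode_length",
            "umi_length",
            "n_cells_per_variant",
            "n_genes",
            "long_read_depth",
            "coding_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_module_genes < 0 or self.n_mito_genes < 0:
            raise ValueError("gene subset sizes must be >= 0")
        if self.n_module_genes + self.n_mito_genes > self.n_genes:
            raise ValueError("module and mito gene sets exceed the gene universe")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.mean_umis_per_cell < 3:
            raise ValueError("mean_umis_per_cell below the 3-UMI validity floor")

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ModelingConfig:
    """Settings for pathogenicity-score modeling.

    The modeling stage builds per-variant mean normalized expression
    profiles, selects variable genes by binned index of dispersion, reduces
    dimensions with PCA, picks a model family by 3x5-fold cross-validated
    AUROC, calibrates probabilities (Platt sigmoid) and produces final
    scores by leave-one-out cross-validation repeated ``loocv_repeats``
    times with seeds ``seed + 0 .. seed + loocv_repeats - 1``.
    """

    min_cells_per_variant: int = 5
    gene_filter_fraction: float = 0.10
    n_features: int = 500
    n_bins: int = 20
    n_pcs: int = 10
    cv_repeats: int = 3
    cv_folds: int = 5
    loocv_repeats: int = 10
    calibration: str = "sigmoid"  # or "isotonic"
    families: tuple[str, ...] = ("logistic", "svm", "random_forest")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1 or self.loocv_repeats < 1:
            raise ValueError("repeat counts must be >= 1")
        _check_fraction("gene_filter_fraction", self.gene_filter_fraction)
        if self.calibration not in ("sigmoid", "isotonic"):
            raise ValueError("calibration must be 'sigmoid' or 'isotonic'")
        unknown = set(self.families) - {"logistic", "svm", "random_forest"}
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")

    def replace(self, **kwargs: Any) -> "ModelingConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Stage toggles allow re-running downstream stages on existing artifacts.
    The global seed is propagated to stages with fixed offsets so a single
    integer reproduces a whole run.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)
    mito_prefix: str = "MT-"
    qc_top_k: int = 50
    qc_min_cluster_size: int = 25
    qc_direction: str = "quality-intent"
    multi_assay: bool = False
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate",
        "libqc",
        "assign",
        "cellqc",
        "model",
        "calibrate",
        "classify",
    )

    def __post_init__(self) -> None:
        if self.qc_direction not in ("quality-intent", "as-printed"):
            raise ValueError("qc_direction must be 'quality-intent' or 'as-printed'")
        # one global seed drives every stage deterministically
        self.simulation = self.simulation.replace(seed=self.seed)
        self.modeling = self.modeling.replace(seed=self.seed + 1000)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim = SimulationConfig(**data.pop("simulation", {}))
        model = ModelingConfig(**data.pop("modeling", {}))
        return cls(simulation=sim, modeling=model, **data)
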