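# Methods

This note records the models, parameter choices and numerical
conventions behind `mave_evidence`, and what the synthetic data do and
do not establish about real experiments.

## The experiment being modeled

A pooled library of designed single-nucleotide variants is integrated
into cells one-variant-per-cell (landing-pad recombination), each
transcript tagged with a unique 8 bp barcode in the 3′-UTR. Three
sequencing readouts feed the analysis: long-read consensus sequencing of
the cloned library (library QC), a targeted variant-cell-barcode (VCB)
library pairing 10x cell barcodes with variant barcodes (cell
assignment), and the single-cell expression matrix (the functional
readout). Known pathogenic and benign variants act as training labels;
the scientific output is a calibrated pathogenicity score per variant
and its conversion into classification evidence points.

## Barcode and UMI network collapse

Sequencing errors scatter a true tag into low-count satellites at
Hamming distance 1. Two collapse strategies are implemented in
`network.py`:

* **directional** (library barcodes, default): edge A→B iff
  Hamming(A,B) ≤ 1 and count(A) ≥ 2·count(B) − 1; clusters are nodes
  reachable from count-descending seeds. The asymmetric count rule
  absorbs error satellites without merging two genuinely distinct,
  similarly abundant barcodes.
* **adjacency** (UMIs): count-descending seeds absorb unclaimed
  neighbours at distance ≤ 1, single hop.

Both are deterministic (ties in seed order break lexicographically) and
are tested against independent brute-force edge-enumeration oracles.
Designed barcodes are generated at pairwise Hamming distance ≥ 3 by
rejection sampling, which makes single-mismatch correction provably
unambiguous for designed sequences; observed ambiguity can then only
come from errors, and ambiguous matches are dropped rather than
guessed (a lost read is cheaper than a wrong cell-variant link).

## Library QC conventions

* The "expected length of the target gene" is the manifest reference
  length; a read is truncated when its aligned span is ≥ 50 bp shorter.
* Reads are anchored to the reference by their 3′ end (the barcode
  cassette sits there), so 5′ truncation shifts the alignment offset
  rather than corrupting it. The synthetic generator truncates at the
  5′ end for the same reason: a 3′-truncated read would lose its
  barcode and silently vanish from clustering instead of exercising the
  20% truncation rule.
* Modal-SNV ties break lexicographically by (position, alt); the
  wild-type category orders last.
* Clusters whose representative is not a designed barcode are reported
  `fail_unmatched`, never rescued; a failing barcode removes only
  itself, and variants left with zero passing barcodes are logged.

## Cell assignment conventions

* Criterion 1's UMI total is the denominator of the fractions in
  criteria 2–3: unique (collapsed) UMIs per cell across all variant
  barcodes.
* Boundary semantics: top fraction exactly 0.5 fails (strict >);
  runner-up exactly 0.25 passes (non-strict ≤).
* The variant barcode is located in Read 2 by an exact-then-1-mismatch
  search for the 10 bp left flank (declared in the manifest header),
  not by fixed offset — PCR constructs shift.
* N bases count as mismatches. Cell barcodes are matched against the
  expression matrix's barcode list with the same 1-mismatch rule, via a
  masked-pattern index (O(length) lookups per read).

## Cell QC

Five features per cell: total UMIs, mitochondrial UMIs (feature-name
prefix `MT-`), percent mitochondrial, genes with nonzero counts, UMIs
in the top-50 genes by overall count ("highly expressed" is not defined
upstream; top-50 is this package's choice). Features are standardized
before HDBSCAN (they span orders of magnitude). HDBSCAN runs with
`min_cluster_size=25`, `min_samples=5`,
`cluster_selection_epsilon=0.5` (standardized units) and
`allow_single_cluster=True`: QC feature space is typically one diffuse
blob of healthy cells plus a compact low-quality island, and default
excess-of-mass selection dissolves a unimodal blob entirely into noise;
with these settings well-separated populations still emerge as distinct
clusters (verified by a two-blob test).

The printed removal rule ("removed if the proportion of < 5000 UMI
cells in the cluster was < 0.2") contradicts its stated purpose of
removing low-quality cells. The default here is the quality-intent
reading — clusters with ≥ 20% sub-5000-UMI cells are removed — with the
literal reading available as `direction="as-printed"`. Noise-labeled
cells are removed under both, as the cluster-proportion rule does not
model them.

## Modeling

* **Order of operations**: cells are row-sum normalized first, then
  averaged per variant (normalize-then-average); variants need ≥ 5
  eligible cells (target recovery is 100 cells/variant; 5 is the floor
  below which a mean profile is judged unreliable).
* **Feature selection**: index of dispersion σ²/μ per gene across
  variant profiles (0 for zero-mean genes), z-scored within 20
  equal-occupancy mean-expression bins; top 500 genes by normalized
  dispersion, ties broken by raw dispersion then gene index so constant
  genes never precede varying ones.
* **PCA**: centered, full SVD, 10 components (clipped to
  min(features, variants − 1)), with a deterministic sign convention
  (largest-magnitude loading positive).
* **Model selection**: mean AUROC over 3 repetitions of stratified
  5-fold CV (folds reduced with a warning when a class is smaller than
  the fold count). Grids: logistic C ∈ {0.01, 0.1, 1, 10}; SVM
  C ∈ {0.1, 1, 10} × γ ∈ {scale, 0.1, 0.01}; random forest
  trees ∈ {10, 25} × depth ∈ {None, 5}. Tree counts are sized to the
  tens-of-variants panels this stage sees — at ~60 training points more
  trees add runtime, not accuracy. Exact ties resolve to the simpler
  family (logistic < SVM < random forest) and earlier grid entry.
* **Calibration and scoring**: the winner is wrapped in
  `CalibratedClassifierCV` (Platt sigmoid by default — isotonic
  overfits small label sets — internal stratified 3-fold). Labeled
  variants are scored by LOOCV repeated 10 times with seeds
  s+0 … s+9; the reported score is the mean calibrated pathogenic-class
  probability. Feature selection, PCA and calibration are all refit
  inside every LOOCV training split, so the held-out variant cannot
  influence its own score; a poisoned-feature test asserts this.
  Unlabeled variants are scored by full-label models averaged over the
  same seeds.

## Evidence calibration

NPV(t) is the benign fraction among labeled variants scoring ≤ t,
PPV(t) the pathogenic fraction among those scoring ≥ t; candidate
thresholds are the midpoints between adjacent distinct labeled scores
plus the extremes. Labeled variants contribute their LOOCV scores, so
the predictive values are leakage-free. Cuts are the outermost
thresholds attaining each bound (largest for NPV, smallest for PPV),
maximizing tier occupancy subject to it; empirical curves are used
as-is, without isotonic smoothing. Bound semantics: "≥ 80–95%" is
[0.80, 0.95]; "> 95%" and "> 97.5%" are strict; under the multi-assay
flag the (0.95, 0.975] region still earns 2 points. Point estimates are
used, matching the tier definitions; a Wilson-interval conservative
mode exists behind a flag. The multi-assay flag is caller-declared
metadata (a model built from several distinct functional readouts); the
package does not infer it. In pathological curves a score can qualify
for both directions at once (the cumulative definitions overlap between
the class modes); such conflicts are reported indeterminate rather than
resolved arbitrarily. The AUROC ≥ 0.8 gate is non-strict and uses the
rank-based estimator with half-credit ties.

## Classification

Point thresholds: likely benign 3, benign 5, likely pathogenic 4,
pathogenic 5, on 0.5-point granularity. Assay points feed exactly one
axis (benign tiers → benign points, pathogenic tiers → pathogenic
points). A variant qualifying on both axes carries conflicting evidence
and is reported VUS; full conflict-resolution hierarchies are out of
scope, and real classifications additionally involve human review —
this output is the mechanical point arithmetic only. The VUS
reclassification rate is (VUS→B + VUS→LB + VUS→LP + VUS→P) divided by
those plus VUS→VUS.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline
assumes: unique-barcode manifests, long reads with barcode substitution
errors (1%/base) and 5′ truncations (5%), VCB reads with ambient
contamination (5% of reads carry a random wrong variant barcode under a
fresh UMI), negative-binomial expression (dispersion 0.5, ~12k
UMIs/cell) in which pathogenic-regime cells have 50 module genes
shifted 4-fold (compositionally, i.e. visible after row-sum
normalization), a mitochondrial gene set at 5% of counts, and 8% of
cells downscaled below 5000 UMIs with tripled mitochondrial fraction.
Default panel: 50 variants × 100 cells (the experimental target), 40%
pathogenic / 40% benign labels, unlabeled variants drawn from a
50/50 mixture of the two expression regimes so their scores populate
the region between the tiers. The magnitude and breadth of real
pathogenic expression shifts are unknown — effect size and module size
are calibration choices, not measurements.

Consequently, passing tests show the machinery is correct and
well-calibrated under its own assumptions: they do not show that real
variants of any particular gene produce separable expression profiles,
and the null/recovery AUROC bands say nothing about assay quality in
the wet lab. Realistic transcriptome structure (co-expression, isoform
use, batch effects, doublets, ambient RNA in the expression matrix) is
deliberately absent.

## Problem sizes and determinism

Statistical acceptance checks run at: null calibration, 80 variants ×
100 cells × 2000 genes over 10 seeds (expression + modeling stages —
read-level stages add nothing to a null check of the model and are
exercised by the recovery, determinism and smoke runs); signal
recovery and the end-to-end smoke run at the 50 × 100 × 2000 default;
tier-purity calibration on 4000 labeled scores drawn from Beta(8,2) /
Beta(2,8). All randomness flows from a single integer seed through
per-stage independent streams; identical configs yield byte-identical
artifacts, including the Matrix Market file.

## Known limitations

* Single gene per run; multi-gene joint modeling is out of scope.
* No doublet detection or ambient-RNA decontamination in cell QC.
* The score→evidence conversion uses predictive-value bins, not
  odds-of-pathogenicity; both are reasonable, only the former is
  implemented.
* External MAVE feature tables can enter at the modeling stage (any
  numeric variant × feature table), but no curation of published
  datasets is included.
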