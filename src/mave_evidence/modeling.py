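"""Supervised pathogenicity-score modeling from per-variant expression.

The feature space is the per-variant mean of row-sum-normalized
expression over QC-passing assigned cells, restricted to genes expressed
in at least 10% of cells for at least one variant. Variable genes are
selected by a binned index of dispersion (variance/mean z-scored within
20 equal-occupancy mean-expression bins), dimensions are reduced with
PCA, a model family (logistic regression, SVM, random forest) is chosen
by mean AUROC over 3 repetitions of stratified 5-fold cross-validation,
and the winner is wrapped in a probability-calibration layer (Platt
sigmoid, internal 3-fold).

Final scores for labeled variants come from leave-one-out
cross-validation repeated ``loocv_repeats`` times with distinct seeds;
the reported score is the mean calibrated pathogenic-class probability
over repeats. Feature selection and PCA are refit inside every LOOCV
training split, so the held-out variant never influences its own score.
Unlabeled variants are scored by models fit on all labeled variants,
averaged over the same seeds.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC

from mave_evidence.config import ModelingConfig

logger = logging.getLogger(__name__)

# simpler families first: cross-validation ties resolve to the left
FAMILY_ORDER = ("logistic", "svm", "random_forest")

GRIDS: dict[str, list[dict]] = {
    "logistic": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "svm": [
        {"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 0.1, 0.01)
    ],
    # tree counts sized to the tens-of-variants panels this stage sees;
    # more trees add cost, not accuracy, at that sample size
    "random_forest": [
        {"n_estimators": n, "max_depth": d} for n in (10, 25) for d in (None, 5)
    ],
}


def filter_genes(
    adata: AnnData, assignments: pd.DataFrame, fraction: float = 0.10
) -> list[str]:
    """Genes expressed in >= ``fraction`` of cells for at least one variant.

    ``assignments`` holds cell_barcode and variant_id columns; cells
    absent from the matrix are ignored.
    """
    cells = assignments[assignments["cell_barcode"].isin(adata.obs_names)]
    if cells.empty:
        raise ValueError("no assigned cells present in the matrix")
    X = sp.csr_matrix(adata[cells["cell_barcode"].to_numpy()].X)
    keep = np.zeros(adata.n_vars, dtype=bool)
    variant_codes, variant_index = pd.factorize(cells["variant_id"], sort=True)
    for code in range(len(variant_index)):
        rows = np.nonzero(variant_codes == code)[0]
        nonzero_frac = (X[rows] > 0).sum(axis=0).A.ravel() / len(rows)
        keep |= nonzero_frac >= fraction
    retained = list(adata.var_names[keep])
    if not retained:
        raise ValueError(
            f"no genes expressed in >= {fraction:.0%} of cells for any variant"
        )
    return retained


def build_profiles(
    adata: AnnData,
    assignments: pd.DataFrame,
    genes: list[str],
    min_cells: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-variant mean of row-sum-normalized expression.

    Each cell's counts are divided by the cell's total count over all
    genes (zero-total cells are excluded), then averaged per variant and
    restricted to ``genes``. Variants contributing fewer than
    ``min_cells`` cells are excluded and logged. Returns the variant x
    gene profile table and the contributing-cell counts.
    """
    cells = assignments[assignments["cell_barcode"].isin(adata.obs_names)]
    sub = adata[cells["cell_barcode"].to_numpy()]
    X = sp.csr_matrix(sub.X).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    eligible = totals > 0
    X = X.multiply(np.where(eligible, 1.0 / np.maximum(totals, 1.0), 0.0)[:, None]).tocsr()

    gene_idx = [sub.var_names.get_loc(g) for g in genes]
    variant_ids = cells["variant_id"].to_numpy()
    profiles = {}
    n_cells = {}
    for variant in pd.unique(variant_ids):
        rows = np.nonzero((variant_ids == variant) & eligible)[0]
        if len(rows) < min_cells:
            logger.info(
                "profile for %s excluded: %d eligible cells < %d",
                variant,
                len(rows),
                min_cells,
            )
            continue
        mean = np.asarray(X[rows].mean(axis=0)).ravel()[gene_idx]
        profiles[variant] = mean
        n_cells[variant] = len(rows)
    if not profiles:
        raise ValueError("no variant reached the minimum cell count")
    table = pd.DataFrame.from_dict(profiles, orient="index", columns=genes).sort_index()
    return table, pd.Series(n_cells).sort_index().rename("n_cells")


def select_features(
    profiles: np.ndarray | pd.DataFrame, n_top: int, n_bins: int = 20
) -> np.ndarray:
    """Top genes by binned, z-scored index of dispersion.

    Per gene, dispersion = variance / mean across variant profiles (0 for
    zero-mean genes). Genes are placed in ``n_bins`` equal-occupancy bins
    by mean expression and the dispersion is z-scored within each bin;
    the ``n_top`` genes with the highest normalized dispersion win, ties
    broken by raw dispersion then gene index (so zero-dispersion genes
    never precede varying ones). Returns column indices in selection
    order.
    """
    X = np.asarray(profiles, dtype=float)
    n_genes = X.shape[1]
    if n_top >= n_genes:
        return np.arange(n_genes)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)

    # equal-occupancy binning by mean (stable rank, ties by index)
    order = np.argsort(mean, kind="stable")
    rank = np.empty(n_genes, dtype=int)
    rank[order] = np.arange(n_genes)
    bins = rank * min(n_bins, n_genes) // n_genes

    z = np.zeros(n_genes)
    for b in np.unique(bins):
        members = bins == b
        mu, sigma = dispersion[members].mean(), dispersion[members].std()
        if sigma > 0:
            z[members] = (dispersion[members] - mu) / sigma
    selected = np.lexsort((np.arange(n_genes), -dispersion, -z))[:n_top]
    return selected


def reduce_dimensions(X: np.ndarray, n_pcs: int) -> np.ndarray:
    """Centered PCA scores with a deterministic sign convention (the
    largest-magnitude loading of each component is made positive)."""
    X = np.asarray(X, dtype=float)
    limit = min(X.shape[1], X.shape[0] - 1)
    if n_pcs > limit:
        warnings.warn(f"n_pcs clipped from {n_pcs} to {limit}", stacklevel=2)
        n_pcs = limit
    pca = _fit_pca(X, n_pcs)
    return pca.transform(X)


def _fit_pca(X: np.ndarray, n_pcs: int) -> PCA:
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pca.fit(X)
    flip = np.sign(
        pca.components_[np.arange(n_pcs), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    pca.components_ *= flip[:, None]
    return pca


class _FeaturePipeline:
    """Dispersion-based gene selection followed by PCA, fit on a training
    split only so held-out variants never leak into their own features."""

    def __init__(self, n_features: int, n_bins: int, n_pcs: int):
        self.n_features = n_features
        self.n_bins = n_bins
        self.n_pcs = n_pcs

    def fit(self, X: np.ndarray) -> "_FeaturePipeline":
        self.idx_ = select_features(X, self.n_features, self.n_bins)
        limit = min(len(self.idx_), X.shape[0] - 1)
        self.pca_ = _fit_pca(X[:, self.idx_], min(self.n_pcs, limit))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca_.transform(X[:, self.idx_])

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def _make_estimator(family: str, params: dict, seed: int):
    if family == "logistic":
        return LogisticRegression(max_iter=2000, **params)
    if family == "svm":
        return SVC(random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}")


def _decision_scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


def _select_model(
    X: np.ndarray, y: np.ndarray, config: ModelingConfig
) -> tuple[str, dict, list[dict]]:
    """Pick (family, params) by mean AUROC over repeated stratified CV."""
    min_class = int(np.bincount(y).min())
    folds = min(config.cv_folds, min_class)
    if folds < config.cv_folds:
        warnings.warn(
            f"cv folds reduced from {config.cv_folds} to {folds} "
            "(fewer labeled variants than folds)",
            stacklevel=2,
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=config.cv_repeats, random_state=config.seed
    )
    configs = [
        (family, params)
        for family in FAMILY_ORDER
        if family in config.families
        for params in GRIDS[family]
    ]
    aurocs: list[list[float]] = [[] for _ in configs]
    for train, test in splitter.split(X, y):
        pipe = _FeaturePipeline(config.n_features, config.n_bins, config.n_pcs)
        Xtr = pipe.fit_transform(X[train])
        Xte = pipe.transform(X[test])
        for k, (family, params) in enumerate(configs):
            est = _make_estimator(family, params, config.seed)
            est.fit(Xtr, y[train])
            aurocs[k].append(roc_auc_score(y[test], _decision_scores(est, Xte)))
    results = [
        {"family": fam, "params": par, "mean_auroc": float(np.mean(a))}
        for (fam, par), a in zip(configs, aurocs)
    ]
    best = max(range(len(results)), key=lambda k: results[k]["mean_auroc"])
    # strict max with left-to-right iteration order already prefers the
    # simpler family on exact ties
    for k in range(len(results)):
        if results[k]["mean_auroc"] >= results[best]["mean_auroc"]:
            best = k
            break
    return results[best]["family"], results[best]["params"], results


def _calibrated(
    family: str, params: dict, config: ModelingConfig, repeat_seed: int, y: np.ndarray
):
    n_folds = min(3, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(n_folds, 2), shuffle=True, random_state=repeat_seed)
    return CalibratedClassifierCV(
        _make_estimator(family, params, repeat_seed),
        method=config.calibration,
        cv=cv,
    )


def train_and_score(
    profiles: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    config: ModelingConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Model selection, calibration and repeated-LOOCV scoring.

    ``profiles`` is the variant x feature table (any numeric table works,
    so externally published MAVE feature tables can replace the
    expression profile stage); ``labels`` maps a subset of its index to
    'pathogenic' or 'benign'. Returns a score table (variant_id, score in
    [0, 1] with 1 = pathogenic, n_repeats, provenance) and a model
    report.
    """
    config = config or ModelingConfig()
    labels = pd.Series(dict(labels))
    labels = labels[labels.index.isin(profiles.index)]
    classes = set(labels.unique())
    if not {"pathogenic", "benign"} <= classes or len(classes) != 2:
        raise ValueError(
            "training requires both 'pathogenic' and 'benign' labels; "
            f"got {sorted(classes)}"
        )
    if (labels == "pathogenic").sum() < 2 or (labels == "benign").sum() < 2:
        raise ValueError("need at least 2 labeled variants per class")

    X_all = profiles.to_numpy(dtype=float)
    labeled_ids = [v for v in profiles.index if v in labels.index]
    labeled_pos = np.array([profiles.index.get_loc(v) for v in labeled_ids])
    y = np.array([1 if labels[v] == "pathogenic" else 0 for v in labeled_ids])
    X = X_all[labeled_pos]

    family, params, cv_results = _select_model(X, y, config)
    logger.info("selected model: %s %s", family, params)

    repeat_seeds = [config.seed + r for r in range(config.loocv_repeats)]

    # leave-one-out scores for labeled variants; the feature pipeline and
    # the calibrated model are refit for every held-out variant
    loocv = np.zeros((len(labeled_ids), config.loocv_repeats))
    for i in range(len(labeled_ids)):
        train = np.delete(np.arange(len(labeled_ids)), i)
        pipe = _FeaturePipeline(config.n_features, config.n_bins, config.n_pcs)
        Xtr = pipe.fit_transform(X[train])
        Xte = pipe.transform(X[i : i + 1])
        for r, rs in enumerate(repeat_seeds):
            model = _calibrated(family, params, config, rs, y[train])
            model.fit(Xtr, y[train])
            loocv[i, r] = model.predict_proba(Xte)[0, 1]

    # full-model scores for unlabeled variants, averaged over the same seeds
    unlabeled_ids = [v for v in profiles.index if v not in labels.index]
    full = np.zeros((len(unlabeled_ids), config.loocv_repeats))
    if unlabeled_ids:
        unlabeled_pos = np.array([profiles.index.get_loc(v) for v in unlabeled_ids])
        pipe = _FeaturePipeline(config.n_features, config.n_bins, config.n_pcs)
        Xtr = pipe.fit_transform(X)
        Xun = pipe.transform(X_all[unlabeled_pos])
        for r, rs in enumerate(repeat_seeds):
            model = _calibrated(family, params, config, rs, y)
            model.fit(Xtr, y)
            full[:, r] = model.predict_proba(Xun)[:, 1]

    rows = [
        {
            "variant_id": v,
            "score": float(loocv[i].mean()),
            "provenance": "loocv-mean",
        }
        for i, v in enumerate(labeled_ids)
    ] + [
        {
            "variant_id": v,
            "score": float(full[i].mean()),
            "provenance": "full-model",
        }
        for i, v in enumerate(unlabeled_ids)
    ]
    scores = pd.DataFrame(rows, columns=["variant_id", "score", "provenance"])
    scores = scores.sort_values("variant_id").reset_index(drop=True)

    per_repeat = pd.DataFrame(
        np.vstack([loocv, full]) if unlabeled_ids else loocv,
        index=labeled_ids + unlabeled_ids,
        columns=[f"repeat_{r}" for r in range(config.loocv_repeats)],
    )
    report = {
        "family": family,
        "params": params,
        "cv_results": cv_results,
        "n_labeled": len(labeled_ids),
        "n_unlabeled": len(unlabeled_ids),
        "loocv_repeats": config.loocv_repeats,
        "calibration": config.calibration,
    }
    return scores, {"report": report, "per_repeat": per_repeat}
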