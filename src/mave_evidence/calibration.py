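"""AUROC gating and NPV/PPV-binned evidence weighting.

A model is valid for clinical use when its AUROC against known
pathogenic and benign variants is at least 0.8. Valid models have their
scores converted to tiered evidence points via predictive-value
thresholds computed from the labeled variants:

=============================  ==================  ======
tier                           bound               points
=============================  ==================  ======
very highly predictive benign  NPV > 97.5%         2.5 B
highly predictive benign       NPV > 95%           2   B
moderately predictive benign   NPV >= 80-95%       1   B
indeterminate                  below both 80%      0
moderately predictive path.    PPV >= 80-95%       1   P
highly predictive path.        PPV > 95%           2   P
very highly predictive path.   PPV > 97.5%         2.5 P
=============================  ==================  ======

The 2.5-point tiers apply only to models flagged as built from multiple
distinct functional readouts (``multi_assay``). PPV(t) is the fraction
pathogenic among labeled variants scoring >= t; NPV(t) the fraction
benign among those scoring <= t. Cuts are the outermost thresholds
attaining each bound, maximizing tier occupancy subject to it. Labeled
variants contribute their leave-one-out scores, keeping the predictive
values leakage-free.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

AUROC_GATE = 0.8

TIER_POINTS = {
    "very highly predictive benign": (2.5, "B"),
    "highly predictive benign": (2.0, "B"),
    "moderately predictive benign": (1.0, "B"),
    "indeterminate": (0.0, ""),
    "moderately predictive pathogenic": (1.0, "P"),
    "highly predictive pathogenic": (2.0, "P"),
    "very highly predictive pathogenic": (2.5, "P"),
}


def _to_series(scores, labels) -> tuple[pd.Series, pd.Series]:
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    common = scores.index.intersection(labels.index)
    scores, labels = scores[common], labels[common]
    if not (labels == "pathogenic").any() or not (labels == "benign").any():
        raise ValueError("both pathogenic and benign labeled variants are required")
    return scores.astype(float), labels


def compute_auroc(
    scores: Mapping[str, float] | pd.Series,
    labels: Mapping[str, str] | pd.Series,
    gate: float = AUROC_GATE,
) -> tuple[float, bool]:
    """Rank-based AUROC (ties get half credit) and the validity verdict.

    AUROC is the probability a random pathogenic variant outscores a
    random benign one; the model is valid when AUROC >= ``gate``
    (non-strict).
    """
    scores, labels = _to_series(scores, labels)
    y = (labels == "pathogenic").to_numpy()
    ranks = rankdata(scores.to_numpy())
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    auroc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auroc), bool(auroc >= gate)


@dataclass
class PredictiveValueCurve:
    """NPV/PPV point estimates over candidate score thresholds.

    Thresholds are the distinct labeled scores' midpoints plus the two
    extremes. At each threshold t, ``ppv`` is the pathogenic fraction
    among scores >= t (NaN when nothing scores >= t) with ``n_ge``
    variants behind it; ``npv`` symmetrically for scores <= t.
    """

    thresholds: np.ndarray
    ppv: np.ndarray
    npv: np.ndarray
    n_ge: np.ndarray
    n_le: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "ppv": self.ppv,
                "npv": self.npv,
                "n_ge": self.n_ge,
                "n_le": self.n_le,
            }
        )


def _wilson_lower(successes: int, n: int, z: float = 1.959963984540054) -> float:
    """Lower bound of the 95% Wilson score interval for a proportion."""
    if n == 0:
        return float("nan")
    p = successes / n
    denom = 1 + z**2 / n
    centre = p + z**2 / (2 * n)
    margin = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return (centre - margin) / denom


def compute_predictive_values(
    scores: Mapping[str, float] | pd.Series,
    labels: Mapping[str, str] | pd.Series,
    conservative: bool = False,
) -> PredictiveValueCurve:
    """Empirical NPV/PPV curve from labeled variants only.

    With ``conservative=True`` the curve carries the lower bound of the
    95% Wilson score interval instead of the point estimate, so tier
    cuts demand statistical rather than nominal attainment of each
    predictive-value bound. The tier definitions themselves are point
    estimates; this mode is an optional stricter variant.
    """
    scores, labels = _to_series(scores, labels)
    s = scores.to_numpy()
    y = (labels == "pathogenic").to_numpy()
    distinct = np.unique(s)
    thresholds = np.concatenate(
        [[distinct[0]], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1]]]
    )
    thresholds = np.unique(thresholds)
    ppv = np.full(len(thresholds), np.nan)
    npv = np.full(len(thresholds), np.nan)
    n_ge = np.zeros(len(thresholds), dtype=int)
    n_le = np.zeros(len(thresholds), dtype=int)
    for k, t in enumerate(thresholds):
        ge = s >= t
        le = s <= t
        n_ge[k], n_le[k] = int(ge.sum()), int(le.sum())
        if n_ge[k]:
            ppv[k] = (
                _wilson_lower(int(y[ge].sum()), n_ge[k])
                if conservative
                else y[ge].mean()
            )
        if n_le[k]:
            npv[k] = (
                _wilson_lower(int((~y[le]).sum()), n_le[k])
                if conservative
                else (~y[le]).mean()
            )
    return PredictiveValueCurve(thresholds, ppv, npv, n_ge, n_le)


def _cuts(curve: PredictiveValueCurve, multi_assay: bool) -> dict[str, float | None]:
    """Outermost thresholds attaining each predictive-value bound."""

    def largest_npv(bound: float, strict: bool) -> float | None:
        ok = np.where(
            (curve.npv > bound) if strict else (curve.npv >= bound - 1e-12)
        )[0]
        return float(curve.thresholds[ok.max()]) if ok.size else None

    def smallest_ppv(bound: float, strict: bool) -> float | None:
        ok = np.where(
            (curve.ppv > bound) if strict else (curve.ppv >= bound - 1e-12)
        )[0]
        return float(curve.thresholds[ok.min()]) if ok.size else None

    cuts = {
        "b1": largest_npv(0.80, strict=False),
        "b2": largest_npv(0.95, strict=True),
        "p1": smallest_ppv(0.80, strict=False),
        "p2": smallest_ppv(0.95, strict=True),
        "b2.5": largest_npv(0.975, strict=True) if multi_assay else None,
        "p2.5": smallest_ppv(0.975, strict=True) if multi_assay else None,
    }
    return cuts


def assign_tiers(
    scores: Mapping[str, float] | pd.Series | pd.DataFrame,
    curve: PredictiveValueCurve,
    multi_assay: bool = False,
) -> pd.DataFrame:
    """Assign every scored variant its evidence tier and points.

    The strongest applicable tier wins: a score at or below the 97.5%
    NPV cut earns 2.5 benign points (multi-assay models only), else the
    95% cut earns 2, else the 80% cut earns 1; symmetrically on the
    pathogenic side at or above the PPV cuts. Scores qualifying for no
    bin — or for both directions at once, which only degenerate curves
    produce — are indeterminate with 0 points.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores.set_index("variant_id")["score"]
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    cuts = _cuts(curve, multi_assay)

    rows = []
    for variant, score in scores.items():
        benign_tier = pathogenic_tier = None
        if cuts["b2.5"] is not None and score <= cuts["b2.5"]:
            benign_tier = "very highly predictive benign"
        elif cuts["b2"] is not None and score <= cuts["b2"]:
            benign_tier = "highly predictive benign"
        elif cuts["b1"] is not None and score <= cuts["b1"]:
            benign_tier = "moderately predictive benign"
        if cuts["p2.5"] is not None and score >= cuts["p2.5"]:
            pathogenic_tier = "very highly predictive pathogenic"
        elif cuts["p2"] is not None and score >= cuts["p2"]:
            pathogenic_tier = "highly predictive pathogenic"
        elif cuts["p1"] is not None and score >= cuts["p1"]:
            pathogenic_tier = "moderately predictive pathogenic"
        if benign_tier and pathogenic_tier:
            tier = "indeterminate"  # conflicting directions: no points
        else:
            tier = benign_tier or pathogenic_tier or "indeterminate"
        points, direction = TIER_POINTS[tier]
        rows.append(
            {
                "variant_id": variant,
                "score": float(score),
                "tier": tier,
                "points": points,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "score", "tier", "points", "direction"])


def run_calibration(
    scores: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    multi_assay: bool = False,
    gate: float = AUROC_GATE,
    conservative: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Gate the model by AUROC, then tier all scores.

    ``scores`` is the modeling stage's table (variant_id, score, ...).
    Raises ValueError when the model fails the AUROC gate — an invalid
    model contributes no evidence.
    """
    score_series = scores.set_index("variant_id")["score"]
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    auroc, valid = compute_auroc(score_series, labels, gate=gate)
    if not valid:
        raise ValueError(
            f"model AUROC {auroc:.3f} below the validity gate {gate}; "
            "scores cannot be used as classification evidence"
        )
    curve = compute_predictive_values(score_series, labels, conservative=conservative)
    tiers = assign_tiers(score_series, curve, multi_assay=multi_assay)
    cuts = _cuts(curve, multi_assay)
    report = {
        "auroc": auroc,
        "valid": valid,
        "gate": gate,
        "multi_assay": multi_assay,
        "cuts": cuts,
        "tier_counts": tiers["tier"].value_counts().to_dict(),
    }
    return tiers, report


def run_calibration_files(
    scores_path: str | os.PathLike,
    labels_path: str | os.PathLike,
    outdir: str | os.PathLike,
    multi_assay: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """File-level wrapper: scores + labels TSVs in, tier TSV + JSON out."""
    scores = pd.read_csv(scores_path, sep="\t")
    labels_df = pd.read_csv(labels_path, sep="\t")
    labels = pd.Series(labels_df["label"].values, index=labels_df["variant_id"])
    tiers, report = run_calibration(scores, labels, multi_assay=multi_assay)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tiers.to_csv(outdir / "tiers.tsv", sep="\t", index=False)
    with open(outdir / "calibration.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return tiers, report
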