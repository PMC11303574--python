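"""Point-based variant classification and reclassification accounting.

Classification follows a semiquantitative point rubric: likely benign
and benign require 3 and 5 benign points; likely pathogenic and
pathogenic require 4 and 5 pathogenic points. Assay evidence points from
the calibration stage are added to exactly one axis (benign tiers to
benign points, pathogenic tiers to pathogenic points; 0.5-point
granularity accommodates the 2.5-point tiers). Variants qualifying on
both axes carry conflicting evidence and stay VUS. The summary stage
tallies before/after transitions and the VUS reclassification rate.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

LIKELY_BENIGN_POINTS = 3.0
BENIGN_POINTS = 5.0
LIKELY_PATHOGENIC_POINTS = 4.0
PATHOGENIC_POINTS = 5.0

CLASSES = ("B", "LB", "VUS", "LP", "P")

#: Transition-table column order (reclassifications of interest)
TABLE_TRANSITIONS = ("VUS>B", "VUS>LB", "VUS>LP", "VUS>P", "VUS>VUS", "LP>P", "LB>B")

#: Tier-count table column order and the tiers feeding each column
TIER_COLUMNS = {
    "NPV80": ("moderately predictive benign", 1.0),
    "NPV95": ("highly predictive benign", 2.0),
    "NPV97.5": ("very highly predictive benign", 2.5),
    "PPV80": ("moderately predictive pathogenic", 1.0),
    "PPV95": ("highly predictive pathogenic", 2.0),
    "PPV97.5": ("very highly predictive pathogenic", 2.5),
}


def classify(benign_points: float, pathogenic_points: float) -> str:
    """Class from accumulated benign and pathogenic points.

    Pathogenic axis: >= 5 points gives P, >= 4 gives LP; benign axis:
    >= 5 gives B, >= 3 gives LB; neither gives VUS. A variant qualifying
    on both axes carries internally conflicting evidence and is reported
    VUS.
    """
    if benign_points < 0 or pathogenic_points < 0:
        raise ValueError("evidence points must be non-negative")
    benign_class = (
        "B"
        if benign_points >= BENIGN_POINTS
        else "LB"
        if benign_points >= LIKELY_BENIGN_POINTS
        else None
    )
    pathogenic_class = (
        "P"
        if pathogenic_points >= PATHOGENIC_POINTS
        else "LP"
        if pathogenic_points >= LIKELY_PATHOGENIC_POINTS
        else None
    )
    if benign_class and pathogenic_class:
        return "VUS"
    return benign_class or pathogenic_class or "VUS"


def apply_evidence(
    baseline: pd.DataFrame, tiers: pd.DataFrame
) -> pd.DataFrame:
    """Add tiered assay points to baseline evidence and classify.

    ``baseline`` has variant_id, benign_points, pathogenic_points (and
    optionally gene); ``tiers`` is the calibration stage's table. Tier
    variants missing from the baseline are skipped and reported in the
    returned frame's ``attrs['skipped']``.
    """
    base = baseline.set_index("variant_id")
    records = []
    skipped = []
    for row in tiers.itertuples():
        if row.variant_id not in base.index:
            skipped.append(row.variant_id)
            continue
        b0 = float(base.loc[row.variant_id, "benign_points"])
        p0 = float(base.loc[row.variant_id, "pathogenic_points"])
        b1, p1 = b0, p0
        if row.direction == "B":
            b1 += float(row.points)
        elif row.direction == "P":
            p1 += float(row.points)
        before = classify(b0, p0)
        after = classify(b1, p1)
        record = {
            "variant_id": row.variant_id,
            "baseline_benign_points": b0,
            "baseline_pathogenic_points": p0,
            "mave_points": float(row.points),
            "direction": row.direction,
            "benign_points": b1,
            "pathogenic_points": p1,
            "before": before,
            "after": after,
            "transition": f"{before}>{after}",
        }
        if "gene" in base.columns:
            record["gene"] = base.loc[row.variant_id, "gene"]
        records.append(record)
    out = pd.DataFrame(records)
    out.attrs["skipped"] = skipped
    return out


@dataclass
class TransitionMatrix:
    """Counts of classification transitions plus reclassification rates.

    ``counts`` covers every observed ``before>after`` label. The VUS
    reclassification rate is the fraction of evidence-receiving VUS that
    left VUS: (VUS>B + VUS>LB + VUS>LP + VUS>P) / (those + VUS>VUS).
    """

    counts: dict[str, int] = field(default_factory=dict)
    per_gene: pd.DataFrame | None = None

    def _get(self, label: str) -> int:
        return int(self.counts.get(label, 0))

    @property
    def n_vus_reclassified(self) -> int:
        return sum(self._get(t) for t in ("VUS>B", "VUS>LB", "VUS>LP", "VUS>P"))

    @property
    def n_vus_total(self) -> int:
        return self.n_vus_reclassified + self._get("VUS>VUS")

    @property
    def reclassification_rate(self) -> float:
        return self.n_vus_reclassified / self.n_vus_total if self.n_vus_total else 0.0

    @property
    def reclassification_rate_percent(self) -> float:
        """Rate on the percent scale rounded to one decimal (e.g. 12.6)."""
        return round(100 * self.reclassification_rate, 1)

    @property
    def upgrades(self) -> int:
        """VUS upgraded to likely pathogenic / pathogenic."""
        return self._get("VUS>LP") + self._get("VUS>P")

    @property
    def downgrades(self) -> int:
        """VUS downgraded to likely benign / benign."""
        return self._get("VUS>B") + self._get("VUS>LB")

    @property
    def lp_to_p(self) -> int:
        return self._get("LP>P")

    @property
    def lb_to_b(self) -> int:
        return self._get("LB>B")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_counts(cls, counts: Mapping[str, int] | Iterable[int]) -> "TransitionMatrix":
        """Build directly from transition counts — either a mapping of
        ``before>after`` labels or a sequence in ``TABLE_TRANSITIONS``
        order (VUS>B, VUS>LB, VUS>LP, VUS>P, VUS>VUS, LP>P, LB>B)."""
        if not isinstance(counts, Mapping):
            values = list(counts)
            if len(values) != len(TABLE_TRANSITIONS):
                raise ValueError(
                    f"expected {len(TABLE_TRANSITIONS)} counts in order "
                    f"{TABLE_TRANSITIONS}"
                )
            counts = dict(zip(TABLE_TRANSITIONS, values))
        return cls(counts={k: int(v) for k, v in counts.items()})

    def to_frame(self) -> pd.DataFrame:
        row = {t: self._get(t) for t in TABLE_TRANSITIONS}
        other = self.total - sum(row.values())
        row["other"] = other
        row["total"] = self.total
        return pd.DataFrame([row])

    def summary(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_vus_total": self.n_vus_total,
            "n_vus_reclassified": self.n_vus_reclassified,
            "reclassification_rate": self.reclassification_rate,
            "reclassification_rate_percent": self.reclassification_rate_percent,
            "upgrades": self.upgrades,
            "downgrades": self.downgrades,
            "lp_to_p": self.lp_to_p,
            "lb_to_b": self.lb_to_b,
            "total_records": self.total,
        }


def summarize(records: pd.DataFrame, per_gene: bool = False) -> TransitionMatrix:
    """Tally classification transitions from an ``apply_evidence`` table."""
    if records.empty:
        raise ValueError("no classification records to summarize")
    counts = records["transition"].value_counts().to_dict()
    gene_table = None
    if per_gene and "gene" in records.columns:
        gene_table = (
            records.groupby("gene")["transition"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=sorted(set(records["transition"])), fill_value=0)
        )
    return TransitionMatrix(counts={k: int(v) for k, v in counts.items()}, per_gene=gene_table)


def tier_count_table(tiers: pd.DataFrame) -> pd.DataFrame:
    """Tier-occupancy row: variants per predictive-value bin plus the
    total with actionable (non-indeterminate) predictions."""
    row = {}
    total = 0
    tier_counts = tiers["tier"].value_counts()
    for column, (tier_name, _points) in TIER_COLUMNS.items():
        n = int(tier_counts.get(tier_name, 0))
        row[column] = n
        total += n
    row["Total"] = total
    return pd.DataFrame([row])


def run_classification_files(
    baseline_path: str | os.PathLike,
    tiers_path: str | os.PathLike,
    outdir: str | os.PathLike,
) -> tuple[pd.DataFrame, TransitionMatrix]:
    """File-level wrapper: baseline + tier TSVs in, report TSVs out."""
    baseline = pd.read_csv(baseline_path, sep="\t")
    tiers = pd.read_csv(tiers_path, sep="\t", keep_default_na=False)
    records = apply_evidence(baseline, tiers)
    matrix = summarize(records, per_gene="gene" in records.columns)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    matrix.to_frame().to_csv(outdir / "transitions.tsv", sep="\t", index=False)
    tier_count_table(tiers).to_csv(outdir / "tier_counts.tsv", sep="\t", index=False)
    with open(outdir / "classification_summary.json", "w") as fh:
        json.dump(matrix.summary(), fh, indent=1)
    return records, matrix
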