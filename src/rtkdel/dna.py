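"""DNA-level inference of the exon 2-7 intragenic deletion.

Three independent DNA readouts are supported: exome read-count ratios between
the deleted region (exons 2-7) and a control region (exons 8-22), aCGH probe
partitions compared by t test, and segmented SNP-array values looked up at
exon 6 versus exon 19. High-level amplification is a strict log2 ratio > 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, roc_curve

from ._stats import trimmed_proportional_fit
from .genemodel import GeneModel

AMPLIFICATION_LOG2_CUTOFF = 2.0


@dataclass(frozen=True)
class RegionDef:
    name: str
    gene: str
    intervals: tuple[tuple[str, int, int], ...]  # (chrom, start, end), 0-based half-open

    def __post_init__(self):
        ivs = sorted(self.intervals, key=lambda iv: (iv[0], iv[1]))
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError(f"overlapping intervals in region {self.name}")

    def overlaps(self, other: "RegionDef") -> bool:
        for c1, s1, e1 in self.intervals:
            for c2, s2, e2 in other.intervals:
                if c1 == c2 and s1 < e2 and s2 < e1:
                    return True
        return False


def egfr_regions(model: GeneModel) -> tuple[RegionDef, RegionDef]:
    """Deleted (exons 2-7) and control (exons 8-22) regions from a gene model."""
    a = RegionDef(
        "exons_2_7", model.gene,
        tuple((e.chrom, e.start, e.end) for e in model.exons if 2 <= e.number <= 7),
    )
    b = RegionDef(
        "exons_8_22", model.gene,
        tuple((e.chrom, e.start, e.end) for e in model.exons if 8 <= e.number <= 22),
    )
    return a, b


@dataclass
class CoverageModel:
    slope: float  # expected counts_A per counts_B in copy-neutral samples
    n_fit: int


def fit_coverage_model(table: pd.DataFrame, trim: float = 0.05) -> CoverageModel:
    """Cohort-level normal ratio of deleted-region to control-region counts.

    Samples are ranked by counts_A/counts_B; the middle 90% of ratios are
    retained and a zero-intercept least-squares line of counts_A on counts_B
    is fitted over that band.
    """
    if len(table) < 10:
        raise ValueError("need >=10 samples")
    b = table["counts_B"].to_numpy(dtype=float)
    a = table["counts_A"].to_numpy(dtype=float)
    if np.all(b <= 0):
        raise ValueError("all control-region counts are zero")
    ok = b > 0
    slope, kept = trimmed_proportional_fit(b[ok], a[ok], trim=trim)
    return CoverageModel(slope=slope, n_fit=int(kept.sum()))


def deletion_scores(
    table: pd.DataFrame, model: CoverageModel, cutoff: float = 0.8
) -> pd.DataFrame:
    """Normalized exon 2-7 copy ratio per sample: counts_A / (slope * counts_B).

    1.0 means no relative loss; ``deleted`` flags normalized ratios below the
    configurable ``cutoff`` (the underlying score is continuous and feeds the
    ROC analysis).
    """
    a = table["counts_A"].to_numpy(dtype=float)
    b = table["counts_B"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = a / b
        norm = raw / model.slope
    return pd.DataFrame(
        {
            "sample_id": table["sample_id"],
            "raw_ratio": raw,
            "normalized_ratio": norm,
            "deleted": norm < cutoff,
        }
    ).set_index("sample_id", drop=False)


def roc_dna_vs_rna(
    scores: pd.DataFrame, rna_positive: pd.Series, target_specificity: float = 0.95
) -> dict:
    """ROC of the deletion score (1 - normalized ratio) against RNA-level
    variant positivity; reports AUC and sensitivity at the target specificity
    (largest TPR with FPR <= 1 - specificity)."""
    labels = rna_positive.reindex(scores["sample_id"]).to_numpy(dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both classes to compute a ROC curve")
    score = 1.0 - scores["normalized_ratio"].to_numpy()
    fpr, tpr, thresholds = roc_curve(labels, score)
    mask = fpr <= (1.0 - target_specificity) + 1e-12
    sens = float(tpr[mask].max()) if mask.any() else 0.0
    return {
        "auc": float(auc(fpr, tpr)),
        "sensitivity_at_specificity": sens,
        "target_specificity": target_specificity,
        "curve": pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
    }


def acgh_partition_test(
    probes: pd.DataFrame,
    deleted_span: tuple[float, float],
    control_span: tuple[float, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-sample comparison of aCGH probe log2 ratios between the candidate
    deleted span (midpoint of intron 1 to end of exon 7) and the control span
    (start of exon 8 through exon 21).

    Classic two-sample equal-variance t test, two-sided, uncorrected.
    ``rejected`` is the plain p < alpha outcome; ``significant`` additionally
    requires the deleted-span mean to lie below the control-span mean (a
    deletion, not a gain).
    """
    rows = []
    for sid, grp in probes.groupby("sample_id", sort=False):
        pos = grp["position"].to_numpy(dtype=float)
        l2 = grp["log2ratio"].to_numpy(dtype=float)
        in_del = (pos >= deleted_span[0]) & (pos < deleted_span[1])
        in_ctl = (pos >= control_span[0]) & (pos < control_span[1])
        if in_del.sum() < 2 or in_ctl.sum() < 2:
            raise ValueError(f"sample {sid}: need >=2 probes in each span")
        t, p = stats.ttest_ind(l2[in_del], l2[in_ctl], equal_var=True)
        lower = l2[in_del].mean() < l2[in_ctl].mean()
        rows.append((sid, float(t), float(p), bool(p < alpha), bool(p < alpha and lower)))
    return pd.DataFrame(
        rows, columns=["sample_id", "t_statistic", "p_value", "rejected", "significant"]
    ).set_index("sample_id", drop=False)


def snp6_exon_comparison(
    segments: pd.DataFrame,
    exon6_pos: float,
    exon19_pos: float,
    chrom: str | None = None,
    margin: float = 0.2,
) -> pd.DataFrame:
    """Relative-deletion flag from segmented copy-number tables.

    Looks up the segment value overlapping each exon position and flags
    relative deletion when the exon-6 value sits below the exon-19 value by
    more than ``margin`` (log2 units).
    """
    rows = []
    for sid, grp in segments.groupby("sample_id", sort=False):
        if chrom is not None:
            grp = grp[grp["chrom"] == chrom]
        v6 = _segment_value(grp, exon6_pos)
        v19 = _segment_value(grp, exon19_pos)
        rows.append((sid, v6, v19, bool(v19 - v6 > margin)))
    return pd.DataFrame(
        rows, columns=["sample_id", "exon6_value", "exon19_value", "relative_deletion"]
    ).set_index("sample_id", drop=False)


def _segment_value(segments: pd.DataFrame, pos: float) -> float:
    hit = segments[(segments["start"] <= pos) & (pos < segments["end"])]
    if hit.empty:
        raise ValueError(f"position {pos} outside all segments")
    return float(hit["value"].iloc[0])


def call_amplification(log2_ratio) -> pd.Series:
    """High-level amplification: locus log2 ratio strictly above 2.

    Accepts a scalar or a per-sample Series; missing values yield <NA>
    (undetermined), and the boundary value 2.0 is negative.
    """
    s = pd.Series(log2_ratio, dtype=float)
    out = pd.Series(pd.NA, index=s.index, dtype="boolean")
    out[s.notna()] = s[s.notna()] > AMPLIFICATION_LOG2_CUTOFF
    if np.isscalar(log2_ratio):
        return out.iloc[0]
    return out
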