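"""nCounter normalization, QC, and deletion-variant calling.

Normalization follows the control-gene scheme: each housekeeping gene's count
is divided by its cross-sample mean, and the per-sample median of these ratios
is the sample's normalization factor. The same factor is applied to the
negative-control probes, whose normalized mean (x5) sets the per-sample
detection threshold.

Variant calls compare a mutant-junction probe against a reference probe in the
region shared by mutant and wild-type transcripts (the kinase domain), giving
a transcribed allelic fraction (TAF). C-terminal truncation is called from
under-representation of the 3'-terminal exon probe versus a kinase-domain
anchor probe relative to a trimmed proportional fit across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import trimmed_proportional_fit
from .probes import HOUSEKEEPING_GENES, ProbeCountMatrix

CALL_CLASSES = ("negative", "marginal", "intermediate", "high")
CTERM_STRATA = ("wild_type", "intermediate", "high")

#: detection threshold multiple over the mean normalized negative-control count
DETECTION_FOLD = 5.0


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # samples x probes, counts / norm_factor
    norm_factor: pd.Series  # per sample
    detection_threshold: pd.Series  # per sample
    matrix: ProbeCountMatrix  # the raw input (probe annotation lives here)

    def probe_values(self, probe_id: str) -> pd.Series:
        return self.values[probe_id]


def _housekeeping_columns(matrix: ProbeCountMatrix, housekeeping_genes) -> dict[str, str]:
    """gene -> probe id for the housekeeping panel."""
    out = {}
    for gene in housekeeping_genes:
        ids = [
            p.probe_id
            for p in matrix.probes
            if p.probe_class == "housekeeping" and p.gene == gene
        ]
        if not ids:
            raise ValueError(f"housekeeping gene {gene!r} missing from probeset")
        out[gene] = ids[0]
    return out


def normalize(
    matrix: ProbeCountMatrix,
    housekeeping_genes=HOUSEKEEPING_GENES,
    exclude: list[str] | None = None,
) -> NormalizedMatrix:
    """Control-gene ratio normalization.

    norm_factor[s] = median over housekeeping genes g of
    (count[s,g] / mean over samples of count[.,g]); all probe counts,
    including negative controls, are divided by it. The detection threshold is
    5x the mean normalized negative-control count per sample.

    Samples listed in ``exclude`` (from :func:`qc_samples`) are dropped first.
    A zero housekeeping count in a retained sample is an error: such samples
    belong in QC exclusion, not in the denominator.
    """
    counts = matrix.counts.drop(index=list(exclude or []))
    if counts.empty:
        raise ValueError("no samples left after exclusion")
    hk = _housekeeping_columns(matrix, housekeeping_genes)
    hk_counts = counts[list(hk.values())].astype(float)
    if (hk_counts <= 0).any().any():
        bad = list(hk_counts.index[(hk_counts <= 0).any(axis=1)])
        raise ValueError(
            f"zero housekeeping counts in samples {bad}; exclude them via qc_samples"
        )
    ratios = hk_counts / hk_counts.mean(axis=0)
    factor = ratios.median(axis=1)
    values = counts.astype(float).div(factor, axis=0)
    neg_ids = matrix.probe_ids(probe_class="negative_control")
    if not neg_ids:
        raise ValueError("probeset has no negative-control probes")
    threshold = DETECTION_FOLD * values[neg_ids].mean(axis=1)
    return NormalizedMatrix(values=values, norm_factor=factor,
                            detection_threshold=threshold, matrix=matrix)


def qc_samples(
    matrix: ProbeCountMatrix,
    housekeeping_genes=HOUSEKEEPING_GENES,
    min_rel_level: float = 0.25,
) -> pd.DataFrame:
    """Flag under-loaded / poorly hybridized samples.

    A sample is excluded when the geometric mean of its housekeeping counts
    falls below ``min_rel_level`` times the cohort median of that summary.
    Returns one row per sample: sample_id, housekeeping_summary, excluded,
    reason.
    """
    if len(matrix.samples) < 3:
        raise ValueError("sample QC needs at least 3 samples")
    hk = _housekeeping_columns(matrix, housekeeping_genes)
    hk_counts = matrix.counts[list(hk.values())].astype(float).clip(lower=0.5)
    summary = np.exp(np.log(hk_counts).mean(axis=1))
    cutoff = min_rel_level * summary.median()
    excluded = summary < cutoff
    return pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "housekeeping_summary": summary,
            "excluded": excluded,
            "reason": np.where(excluded, "low control-gene expression", ""),
        }
    ).set_index("sample_id", drop=False)


def qc_negative_drift(matrix: ProbeCountMatrix, alpha: float = 0.05) -> dict:
    """Check that negative-control background does not rise with sample totals.

    Reports the rank correlation between per-sample mean negative-control
    count and per-sample total count; the cohort fails when the correlation is
    significantly positive (one-sided test at ``alpha``).
    """
    neg_ids = matrix.probe_ids(probe_class="negative_control")
    if not neg_ids:
        raise ValueError("no negative-control probes")
    if len(matrix.samples) < 3:
        raise ValueError("need at least 3 samples")
    neg_mean = matrix.counts[neg_ids].mean(axis=1)
    # totals over endogenous probes only: including the negatives themselves
    # would build a spurious positive correlation into the diagnostic
    totals = matrix.counts.drop(columns=neg_ids).sum(axis=1)
    if neg_mean.nunique() == 1 or totals.nunique() == 1:
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(totals, neg_mean, alternative="greater")
    return {"rho": float(rho), "p_value": float(p), "passed": bool(p >= alpha)}


def classify_taf(taf: float, detected: bool) -> str:
    """TAF stratum: negative (below detection), marginal (<1%), intermediate
    (1-10%, right-open), high (>=10%)."""
    if not detected:
        return "negative"
    if taf < 0.01:
        return "marginal"
    if taf < 0.10:
        return "intermediate"
    return "high"


def call_junction_variant(
    norm: NormalizedMatrix,
    variant: str,
    mutant_probe: str,
    reference_probe: str,
    vii_threshold: float = 0.02,
) -> pd.DataFrame:
    """Per-sample deletion calls for a junction-probe variant.

    TAF = mutant/reference, clipped to [0,1] for classification (the raw
    ratio is retained: mutant transcripts also carry the reference region, so
    ratios above 1 are noise). ``detected`` requires the mutant probe to reach
    the sample's detection threshold. For vII, positivity additionally
    requires the raw ratio to exceed ``vii_threshold`` (default 2% of total
    gene counts); for the other junction variants positivity means detected
    with TAF >= 1%.
    """
    for probe in (mutant_probe, reference_probe):
        if probe not in norm.values.columns:
            raise ValueError(f"probe {probe!r} missing; refusing to call {variant}")
    mut = norm.values[mutant_probe]
    ref = norm.values[reference_probe]
    thr = norm.detection_threshold
    detected = mut >= thr

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (mut / ref).to_numpy()
    flags = np.full(len(mut), "", dtype=object)
    both_zero = (ref == 0) & (mut == 0)
    ref_zero = (ref == 0) & (mut > 0)
    raw = np.where(both_zero, 0.0, raw)
    raw = np.where(ref_zero, 1.0, raw)
    flags[ref_zero.to_numpy()] = "reference_zero"
    flags[both_zero.to_numpy()] = "no_counts"
    det = detected & ~both_zero
    taf = np.clip(raw, 0.0, 1.0)
    call_class = [classify_taf(t, d) for t, d in zip(taf, det)]
    if variant == "vII":
        positive = det.to_numpy() & (raw > vii_threshold)
    else:
        positive = det.to_numpy() & (taf >= 0.01)
    return pd.DataFrame(
        {
            "sample_id": mut.index,
            "variant": variant,
            "mutant_counts": mut.to_numpy(),
            "reference_counts": ref.to_numpy(),
            "taf_raw": raw,
            "taf": taf,
            "call_class": call_class,
            "detected": det.to_numpy(),
            "positive": positive,
            "flag": flags,
        }
    ).set_index("sample_id", drop=False)


@dataclass
class CTermModel:
    slope: float
    anchor_probe: str
    cterm_probe: str
    n_fit: int
    r_squared: float


def fit_cterm_model(
    norm: NormalizedMatrix,
    anchor_probe: str = "EGFR_E19",
    cterm_probe: str = "EGFR_E28",
    trim: float = 0.05,
) -> CTermModel:
    """Wild-type proportionality between the 3'-terminal exon probe and the
    kinase-domain anchor, fitted on the central 90% of the cterm/anchor ratio
    distribution with zero intercept (probe counts of co-transcribed exons are
    proportional; a free intercept would let background dominate
    low-expression samples)."""
    anchor = norm.values[anchor_probe]
    cterm = norm.values[cterm_probe]
    usable = anchor >= norm.detection_threshold
    if usable.sum() < 10:
        raise ValueError("need >=10 samples with anchor counts above detection")
    x = anchor[usable].to_numpy()
    y = cterm[usable].to_numpy()
    slope, kept = trimmed_proportional_fit(x, y, trim=trim)
    resid = y[kept] - slope * x[kept]
    ss_tot = float(np.sum(y[kept] ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CTermModel(slope=slope, anchor_probe=anchor_probe, cterm_probe=cterm_probe,
                      n_fit=int(kept.sum()), r_squared=r2)


def call_cterm(norm: NormalizedMatrix, model: CTermModel) -> pd.DataFrame:
    """Apply the wild-type model to the whole cohort: expected cterm counts =
    slope x anchor; strata: high (<10% of expected), intermediate (<60%),
    else wild_type. The summary ``positive`` flag covers both truncation
    strata; ``high_only`` mirrors the stricter tally."""
    anchor = norm.values[model.anchor_probe]
    observed = norm.values[model.cterm_probe]
    expected = model.slope * anchor
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (observed / expected).to_numpy()
    undefined = expected.to_numpy() <= 0
    frac = np.where(undefined, np.nan, frac)
    strata = np.where(frac < 0.10, "high", np.where(frac < 0.60, "intermediate", "wild_type"))
    strata = np.where(undefined, "undefined", strata)
    return pd.DataFrame(
        {
            "sample_id": anchor.index,
            "observed_cterm": observed.to_numpy(),
            "expected_cterm": expected.to_numpy(),
            "fraction_of_expected": frac,
            "stratum": strata,
            "positive": np.isin(strata, ("intermediate", "high")),
            "high_only": strata == "high",
            "flag": np.where(undefined, "expected_zero", ""),
        }
    ).set_index("sample_id", drop=False)
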