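"""qRT-PCR standard curves, efficiency, relative quantification and QC.

Efficiency comes from the dilution-series slope: E = 10^(-1/slope) - 1 with
slope fitted by OLS of CT on log10(concentration). Relative quantity uses
Quantity = (1 + E)^(ct_ref - CT), where ct_ref is the smallest CT on the
standard curve (the highest-concentration point; historically labelled
"CT_max" — a misnomer kept only in docs). Quantities of the target assays are
normalized to TBP and the deletion transcript is reported as a fraction of
total gene transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_TBP_CT = 36.0
TBP_MAD_LIMIT = 0.25


@dataclass
class StandardCurve:
    assay: str
    slope: float  # cycles per log10(ng), negative
    intercept: float
    efficiency: float  # 1.0 = perfect doubling
    ct_ref: float  # smallest CT on the curve
    r_squared: float


def fit_standard_curve(points, assay: str = "") -> StandardCurve:
    """OLS fit of CT on log10(concentration) over a dilution series.

    ``points`` is an iterable of (concentration ng, CT) pairs with at least 3
    distinct positive concentrations. A non-negative fitted slope signals
    broken input (more template must mean lower CT) and raises.
    """
    pts = [(float(c), float(ct)) for c, ct in points]
    conc = np.array([c for c, _ in pts])
    ct = np.array([c for _, c in pts])
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < 3:
        raise ValueError("need >=3 distinct concentrations")
    slope, intercept = np.polyfit(np.log10(conc), ct, 1)
    if slope >= 0:
        raise ValueError(f"non-negative slope {slope:.3f}: CT must fall with concentration")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    resid = ct - (slope * np.log10(conc) + intercept)
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(
        assay=assay,
        slope=float(slope),
        intercept=float(intercept),
        efficiency=float(efficiency),
        ct_ref=float(np.min(ct)),
        r_squared=r2,
    )


def quantify(replicate_cts, curve: StandardCurve, average: str = "ct") -> float:
    """Relative quantity of a sample from its replicate CTs.

    Quantity = (1 + E)^(ct_ref - CT). With ``average="ct"`` (default) the
    called replicate CTs are averaged before conversion; ``average="quantity"``
    converts each replicate and averages the quantities.
    """
    cts = np.array([c for c in replicate_cts if c is not None and np.isfinite(c)], dtype=float)
    if cts.size == 0:
        raise ValueError("no called replicates")
    if average == "ct":
        return float((1.0 + curve.efficiency) ** (curve.ct_ref - cts.mean()))
    if average == "quantity":
        return float(np.mean((1.0 + curve.efficiency) ** (curve.ct_ref - cts)))
    raise ValueError(f"unknown averaging mode {average!r}")


def reject_samples(
    tbp_records: pd.DataFrame,
    tbp_curve: StandardCurve,
    max_ct: float = MAX_TBP_CT,
    min_failed: int = 2,
    mad_limit: float = TBP_MAD_LIMIT,
) -> pd.DataFrame:
    """Replicate QC on the TBP reference assay.

    A sample is rejected when ``min_failed`` or more TBP replicates failed to
    cross threshold below ``max_ct`` cycles (or never crossed), or when the
    median absolute deviation of the quantified TBP replicates exceeds
    ``mad_limit`` of their median (unscaled MAD, no consistency constant).

    ``tbp_records``: long table with columns sample_id, ct (NaN = no-call).
    """
    rows = []
    for sid, grp in tbp_records.groupby("sample_id", sort=False):
        cts = grp["ct"].to_numpy(dtype=float)
        n_failed = int(np.sum(~np.isfinite(cts) | (cts >= max_ct)))
        if n_failed >= min_failed:
            rows.append((sid, True, f"{n_failed} TBP replicates failed (<{max_ct:g} cycles)"))
            continue
        called = cts[np.isfinite(cts)]
        if called.size == 0:
            rows.append((sid, True, "no called TBP replicates"))
            continue
        q = (1.0 + tbp_curve.efficiency) ** (tbp_curve.ct_ref - called)
        med = np.median(q)
        mad = np.median(np.abs(q - med))
        if med <= 0 or mad / med > mad_limit:
            rows.append((sid, True, f"TBP replicate MAD {mad / med:.1%} > {mad_limit:.0%}"))
        else:
            rows.append((sid, False, ""))
    return pd.DataFrame(rows, columns=["sample_id", "rejected", "reject_reason"]).set_index(
        "sample_id", drop=False
    )


def quantify_samples(
    ct_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    average: str = "ct",
) -> pd.DataFrame:
    """Relative quantities per sample x assay from a long CT table
    (sample_id, assay, ct). Assays without any called replicate yield NaN."""
    rows = []
    for (sid, assay), grp in ct_table.groupby(["sample_id", "assay"], sort=False):
        cts = grp["ct"].to_numpy(dtype=float)
        cts = cts[np.isfinite(cts)]
        if assay not in curves:
            raise ValueError(f"no standard curve for assay {assay!r}")
        q = quantify(cts, curves[assay], average=average) if cts.size else np.nan
        rows.append((sid, assay, q))
    wide = (
        pd.DataFrame(rows, columns=["sample_id", "assay", "quantity"])
        .pivot(index="sample_id", columns="assay", values="quantity")
    )
    return wide


def normalize_and_fraction(
    quantities: pd.DataFrame,
    rejection: pd.DataFrame | None = None,
    viii_assay: str = "EGFRvIII",
    egfr_assay: str = "EGFR_total",
    tbp_assay: str = "TBP",
) -> pd.DataFrame:
    """TBP-normalized quantities and the vIII fraction of total EGFR.

    viii_fraction = (vIII/TBP) / (EGFR/TBP), clipped to [0,1] for reporting
    with the raw ratio retained. Rejected samples (and samples with zero TBP)
    carry NaN quantities.
    """
    out = pd.DataFrame(index=quantities.index)
    out["sample_id"] = quantities.index
    tbp = quantities[tbp_assay]
    rejected = pd.Series(False, index=quantities.index)
    reason = pd.Series("", index=quantities.index)
    if rejection is not None:
        rejected = rejection["rejected"].reindex(quantities.index).fillna(False)
        reason = rejection["reject_reason"].reindex(quantities.index).fillna("")
    zero_tbp = ~(tbp > 0)
    reason = reason.mask(~rejected & zero_tbp, "zero TBP quantity")
    rejected = rejected | zero_tbp

    with np.errstate(divide="ignore", invalid="ignore"):
        egfr_norm = quantities[egfr_assay] / tbp
        viii_norm = quantities[viii_assay].fillna(0.0) / tbp
        raw_frac = viii_norm / egfr_norm
    out["egfr_norm"] = egfr_norm.where(~rejected)
    out["viii_norm"] = viii_norm.where(~rejected)
    out["viii_fraction_raw"] = raw_frac.where(~rejected)
    out["viii_fraction"] = out["viii_fraction_raw"].clip(0.0, 1.0)
    out["rejected"] = rejected
    out["reject_reason"] = reason
    return out
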