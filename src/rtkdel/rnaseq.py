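"""Exon-junction tabulation from spliced alignments and variant fractions.

A split read supports junction (i, j) when one of its gap (N) operations joins
the end of exon i exactly to the start of exon j. Mutant junctions are
compared against the wild-type junction sharing the same acceptor exon, which
cancels 3' coverage bias; detection limits use exact two-sided binomial
(Clopper-Pearson) intervals.

Only reads with perfect alignments are counted: CIGAR restricted to aligned
matches and gaps (no clips, insertions or deletions) and, when present, an
edit-distance tag of 0. A config flag relaxes the edit-distance requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from ._stats import clopper_pearson
from .genemodel import GeneModel

#: default variant junction definitions: mutant (donor, acceptor) vs the
#: wild-type junction at the same acceptor exon
DEFAULT_VARIANT_JUNCTIONS = {
    "vIII": ("EGFR", (1, 8), (7, 8)),
    "vII": ("EGFR", (13, 16), (15, 16)),
    "pdgfra_d89": ("PDGFRA", (7, 10), (9, 10)),
}


@dataclass(frozen=True)
class VariantJunctionDef:
    variant: str
    gene: str
    mutant_junction: tuple[int, int]
    wildtype_junction: tuple[int, int]

    def __post_init__(self):
        if self.mutant_junction[1] != self.wildtype_junction[1]:
            raise ValueError(
                "mutant and wild-type junctions must share the acceptor exon "
                "(3'-bias matching)"
            )


def default_variant_defs(variants=("vIII", "vII", "pdgfra_d89")) -> list[VariantJunctionDef]:
    return [
        VariantJunctionDef(v, *DEFAULT_VARIANT_JUNCTIONS[v][:1], *DEFAULT_VARIANT_JUNCTIONS[v][1:])
        for v in variants
    ]


_ALLOWED_OPS = {0, 3}  # M, N


def _perfect(read: pysam.AlignedSegment, require_nm_zero: bool = True) -> bool:
    if read.cigartuples is None:
        return False
    if any(op not in _ALLOWED_OPS for op, _ in read.cigartuples):
        return False
    if require_nm_zero and read.has_tag("NM") and read.get_tag("NM") != 0:
        return False
    return True


def _read_junctions(read: pysam.AlignedSegment, ends: dict[int, int], starts: dict[int, int]):
    """Junctions (donor exon, acceptor exon) implied by the read's gap ops."""
    out = []
    pos = read.reference_start
    for op, length in read.cigartuples:
        if op == 0:
            pos += length
        elif op == 3:
            donor = ends.get(pos)
            acceptor = starts.get(pos + length)
            if donor is not None and acceptor is not None and acceptor > donor:
                out.append((donor, acceptor))
            pos += length
    return out


def extract_junctions(
    alignments: str | Path | pysam.AlignmentFile,
    model: GeneModel,
    mode: str = "split_only",
    require_nm_zero: bool = True,
    frag_bounds: tuple[int, int] = (50, 600),
    min_support: int = 2,
) -> pd.DataFrame:
    """Tabulate exon-junction support from SAM/BAM records for one sample.

    Returns one row per observed junction: gene, donor_exon, acceptor_exon,
    split_reads, gapped_pairs, confirmed (total support >= ``min_support``;
    a junction counts as real only when seen in more than one read).

    In ``split_plus_pairs`` mode, a properly paired fragment whose mates lie
    wholly inside exons i and j with at least one intervening exon absent
    supports (i, j) when the implied fragment length on the corresponding
    skipped transcript lies within ``frag_bounds``.
    """
    if mode not in ("split_only", "split_plus_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    ends = model.exon_ends()
    starts = model.exon_starts()
    split_counts: dict[tuple[int, int], int] = {}
    pair_counts: dict[tuple[int, int], int] = {}
    pending: dict[str, pysam.AlignedSegment] = {}
    n_used = 0
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != model.chrom:
                continue
            if not _perfect(read, require_nm_zero):
                continue
            n_used += 1
            for junc in _read_junctions(read, ends, starts):
                split_counts[junc] = split_counts.get(junc, 0) + 1
            if mode == "split_plus_pairs" and read.is_paired:
                mate = pending.pop(read.query_name, None)
                if mate is None:
                    pending[read.query_name] = read
                else:
                    junc = _pair_junction(read, mate, model, frag_bounds)
                    if junc is not None:
                        pair_counts[junc] = pair_counts.get(junc, 0) + 1
    finally:
        if own:
            alignments.close()
    juncs = sorted(set(split_counts) | set(pair_counts))
    df = pd.DataFrame(
        {
            "gene": model.gene,
            "donor_exon": [j[0] for j in juncs],
            "acceptor_exon": [j[1] for j in juncs],
            "split_reads": [split_counts.get(j, 0) for j in juncs],
            "gapped_pairs": [pair_counts.get(j, 0) for j in juncs],
        }
    )
    df["confirmed"] = (df["split_reads"] + df["gapped_pairs"]) >= min_support
    df.attrs["n_reads_used"] = n_used
    return df


def _pair_junction(r1, r2, model: GeneModel, frag_bounds) -> tuple[int, int] | None:
    """Pair evidence: mates wholly inside exons i < j with j > i + 1, no gap
    ops in either mate, and a plausible fragment length on the transcript that
    splices exon i directly to exon j."""
    if any(op == 3 for op, _ in r1.cigartuples) or any(op == 3 for op, _ in r2.cigartuples):
        return None
    a, b = sorted((r1, r2), key=lambda r: r.reference_start)
    ei = model.exon_containing(a.reference_start)
    ej = model.exon_containing(b.reference_start)
    if ei is None or ej is None or ej <= ei + 1:
        return None
    exon_i, exon_j = model.exon(ei), model.exon(ej)
    if a.reference_end > exon_i.end or b.reference_end > exon_j.end:
        return None
    # fragment length if exon i is joined directly to exon j
    frag = (exon_i.end - a.reference_start) + (b.reference_end - exon_j.start)
    if frag_bounds[0] <= frag <= frag_bounds[1]:
        return (ei, ej)
    return None


def junction_support(
    table: pd.DataFrame, junction: tuple[int, int], evidence: str = "split_reads"
) -> int:
    row = table[(table["donor_exon"] == junction[0]) & (table["acceptor_exon"] == junction[1])]
    if row.empty:
        return 0
    if evidence == "both":
        return int(row["split_reads"].iloc[0] + row["gapped_pairs"].iloc[0])
    return int(row[evidence].iloc[0])


def variant_fraction(
    table: pd.DataFrame,
    defs: list[VariantJunctionDef],
    min_support: int = 2,
    evidence: str = "split_reads",
    sample_id: str = "",
) -> pd.DataFrame:
    """Per-variant mutant junction fraction with exact 95% binomial CI.

    fraction = mutant / (mutant + matched wild-type junction reads); mutant
    junctions with support below ``min_support`` are reported as not detected
    with fraction 0. When neither junction has coverage the fraction is
    undefined and flagged.
    """
    rows = []
    for d in defs:
        mut = junction_support(table, d.mutant_junction, evidence)
        wt = junction_support(table, d.wildtype_junction, evidence)
        flag = ""
        detected = mut >= min_support
        if mut + wt == 0:
            frac, lo, hi = np.nan, np.nan, np.nan
            flag = "no coverage"
        else:
            eff_mut = mut if detected else 0
            frac = eff_mut / (eff_mut + wt)
            lo, hi = clopper_pearson(eff_mut, eff_mut + wt)
        rows.append((sample_id, d.variant, mut, wt, detected, frac, lo, hi, flag))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "variant",
            "mutant_reads",
            "wildtype_reads",
            "detected",
            "fraction",
            "ci95_low",
            "ci95_high",
            "flag",
        ],
    )


def pooled_detection_limit(
    tables: list[pd.DataFrame],
    vdef: VariantJunctionDef,
    sample_filter=None,
    evidence: str = "split_reads",
) -> dict:
    """Pooled mutant fraction across samples with an exact two-sided 95% CI.

    Sums mutant and wild-type junction reads over the samples passing
    ``sample_filter`` (raw sums; no per-sample support threshold) and inverts
    the binomial tails. With zero mutant reads the upper bound is the exact
    detection limit 1 - 0.025^(1/n).
    """
    kept = [t for i, t in enumerate(tables) if sample_filter is None or sample_filter(i, t)]
    if not kept:
        raise ValueError("no samples pass the filter")
    mut = sum(junction_support(t, vdef.mutant_junction, evidence) for t in kept)
    wt = sum(junction_support(t, vdef.wildtype_junction, evidence) for t in kept)
    total = mut + wt
    if total == 0:
        raise ValueError("zero pooled junction reads")
    lo, hi = clopper_pearson(mut, total)
    return {
        "variant": vdef.variant,
        "n_samples": len(kept),
        "mutant_reads": mut,
        "wildtype_reads": wt,
        "total_reads": total,
        "fraction": mut / total,
        "ci95_low": lo,
        "ci95_high": hi,
    }


def bin_fraction(frac: float, detected: bool) -> str:
    if not detected or not np.isfinite(frac):
        return "none_detected"
    if frac < 0.01:
        return "<1%"
    if frac <= 0.10:
        return "1-10%"
    return ">10%"


def concordance_with_nanostring(
    ns_calls: pd.DataFrame,
    rnaseq: pd.DataFrame,
    coverage: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate digital-counting classes against RNA-seq fraction bins.

    Returns (crosstab, per-sample detail). Samples called positive by the
    counting platform but with zero junction reads are annotated
    "within sampling error" when the binomial probability of observing zero
    mutant reads at the platform TAF and the sample's junction coverage
    exceeds 5% — low coverage, not discordance.
    """
    ns = ns_calls.set_index("sample_id") if "sample_id" in ns_calls.columns else ns_calls
    rs = rnaseq.set_index("sample_id") if "sample_id" in rnaseq.columns else rnaseq
    common = ns.index.intersection(rs.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples")
    detail = pd.DataFrame(index=common)
    detail["ns_class"] = ns.loc[common, "call_class"]
    detail["rnaseq_bin"] = [
        bin_fraction(rs.loc[s, "fraction"], bool(rs.loc[s, "detected"])) for s in common
    ]
    notes = []
    for s in common:
        note = ""
        if ns.loc[s, "positive"] and rs.loc[s, "mutant_reads"] == 0:
            n = int(rs.loc[s, "mutant_reads"] + rs.loc[s, "wildtype_reads"])
            if coverage is not None and s in coverage.index:
                n = int(coverage.loc[s])
            p0 = float(stats.binom.pmf(0, n, ns.loc[s, "taf"])) if n > 0 else 1.0
            if p0 > 0.05:
                note = "within sampling error"
            else:
                note = "discordant"
        notes.append(note)
    detail["note"] = notes
    tab = pd.crosstab(detail["ns_class"], detail["rnaseq_bin"])
    return tab, detail
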