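"""Synthetic multi-platform cohort generator with known per-sample truth.

Emulates the statistical structure the downstream analyses assume:

* amplification-dependent expression scale (deletion variants arise almost
  exclusively on amplified alleles, so mutant-positive samples are drawn from
  the amplified stratum);
* per-sample mutant transcribed allelic fractions (TAF) spanning orders of
  magnitude;
* Poisson / negative-binomial count noise on digital counts and sequencing
  coverage;
* 3' coverage bias in RNA-seq read placement;
* DNA-level loss of EGFR exons 2-7 coupled to vIII transcript expression
  (every vIII-expressing sample has relative copy < 1 for the deleted region).

All simulators derive the same per-sample truth from ``CohortSpec.seed`` via
independent named streams, so the four modalities are jointly consistent and
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genemodel import GeneModel
from .probes import HOUSEKEEPING_GENES, ProbeCountMatrix, ProbeDef, default_probeset

VARIANTS = ("vIII", "vII", "vV", "pdgfra_d89")

#: deletion isoforms as (gene, (first deleted exon, last deleted exon));
#: vV is a C-terminal truncation, not a junction isoform, so it has no entry
VARIANT_SKIPS = {
    "vIII": ("EGFR", (2, 7)),
    "vII": ("EGFR", (14, 15)),
    "pdgfra_d89": ("PDGFRA", (8, 9)),
}

#: optical/hybridization background expectation per probe (counts), flat
#: across samples — negative controls show no drift with sample totals
NEG_BACKGROUND = 5.0

_HK_BASE = {
    "B2M": 8000.0,
    "B4GALT1": 1200.0,
    "CLTC": 2500.0,
    "E2F4": 600.0,
    "GAPDH": 12000.0,
    "POLR2A": 900.0,
    "SDHA": 1500.0,
    "TBP": 700.0,
}

_STREAMS = {
    "truth": 0,
    "nanostring": 1,
    "qpcr": 2,
    "alignments": 3,
    "dna": 4,
    "dilution": 5,
    "snp6": 6,
    "ffpe": 7,
}


@dataclass(frozen=True)
class VariantMix:
    """Mixture spec for one variant: probability of positivity given
    amplification of its gene, and a uniform TAF range for positives."""

    prob_given_amplified: float
    taf_low: float
    taf_high: float

    def __post_init__(self):
        if not 0 <= self.prob_given_amplified <= 1:
            raise ValueError("prob_given_amplified must be in [0,1]")
        if not 0 < self.taf_low <= self.taf_high <= 1:
            raise ValueError("TAF range must satisfy 0 < low <= high <= 1")


def default_taf_distribution() -> dict[str, VariantMix]:
    return {
        "vIII": VariantMix(0.5, 0.01, 0.9),
        "vII": VariantMix(0.04, 0.03, 0.3),
        "vV": VariantMix(0.10, 0.5, 0.99),
        "pdgfra_d89": VariantMix(0.4, 0.05, 0.9),
    }


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int = 200
    frac_amplified: float = 0.45  # EGFR high-level amplification prevalence
    frac_amplified_pdgfra: float = 0.10
    amplified_expression_scale: float = 20.0
    taf_distribution: dict[str, VariantMix] = field(default_factory=default_taf_distribution)
    noise_model: str = "poisson"  # "poisson" | "negative_binomial" | "none"
    dispersion: float = 0.1  # NB only; var = mu + dispersion * mu^2
    coverage_3prime_bias: tuple[float, float] = (1.0, 2.0)  # linear 5'->3' depth ramp
    # median/log-sd of the shared low-level cross-hybridization fraction for
    # the vIII junction target: hybridization assays see a small nonspecific
    # signal proportional to total gene expression even in mutant-negative
    # samples, common across probe- and primer-based platforms; 0 disables
    cross_hyb_median: float = 1e-3
    cross_hyb_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        for name, v in (("frac_amplified", self.frac_amplified),
                        ("frac_amplified_pdgfra", self.frac_amplified_pdgfra)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.amplified_expression_scale <= 0:
            raise ValueError("amplified_expression_scale must be positive")
        if self.noise_model not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model == "negative_binomial" and self.dispersion <= 0:
            raise ValueError("dispersion must be strictly positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _draw_counts(rng: np.random.Generator, expectation: np.ndarray, noise_model: str,
                 dispersion: float) -> np.ndarray:
    expectation = np.asarray(expectation, dtype=float)
    if noise_model == "none":
        return expectation  # exact expectations, possibly non-integer
    if noise_model == "poisson":
        return rng.poisson(expectation).astype(float)
    n = 1.0 / dispersion
    p = n / (n + np.maximum(expectation, 1e-12))
    return rng.negative_binomial(n, p).astype(float)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def simulate_truth(spec: CohortSpec) -> pd.DataFrame:
    """Per-sample ground truth shared by all simulators for a given spec.

    DNA coupling: exon 2-7 relative copy is 1.0 exactly when vIII TAF is 0 and
    strictly below 1 otherwise (loss deepens with TAF), mirroring the tight
    RNA/DNA association of the deletion.
    """
    rng = spec.rng("truth")
    n = spec.n_samples
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    amp_egfr = rng.random(n) < spec.frac_amplified
    amp_pdgfra = rng.random(n) < spec.frac_amplified_pdgfra

    loading = rng.lognormal(0.0, 0.15, n)
    egfr_base = rng.lognormal(np.log(1000.0), 0.5, n)
    pdgfra_base = rng.lognormal(np.log(800.0), 0.5, n)
    egfr_expr = egfr_base * np.where(amp_egfr, spec.amplified_expression_scale, 1.0)
    pdgfra_expr = pdgfra_base * np.where(amp_pdgfra, spec.amplified_expression_scale, 1.0)

    taf = {}
    for variant in VARIANTS:
        mix = spec.taf_distribution[variant]
        amp = amp_pdgfra if variant == "pdgfra_d89" else amp_egfr
        pos = amp & (rng.random(n) < mix.prob_given_amplified)
        vals = rng.uniform(mix.taf_low, mix.taf_high, n)
        taf[variant] = np.where(pos, vals, 0.0)

    rel_copy = np.where(taf["vIII"] > 0, np.clip(1.0 - 0.9 * taf["vIII"], 0.05, 0.995), 1.0)
    locus_log2 = np.where(amp_egfr, rng.uniform(2.2, 3.8, n), rng.normal(0.0, 0.08, n))

    if spec.cross_hyb_median > 0:
        viii_bg = rng.lognormal(np.log(spec.cross_hyb_median), spec.cross_hyb_sigma, n)
        vii_bg_ns = rng.lognormal(np.log(spec.cross_hyb_median), spec.cross_hyb_sigma, n)
    else:
        viii_bg = np.zeros(n)
        vii_bg_ns = np.zeros(n)

    return pd.DataFrame(
        {
            "sample_id": ids,
            "amplified_egfr": amp_egfr,
            "amplified_pdgfra": amp_pdgfra,
            "taf_vIII": taf["vIII"],
            "taf_vII": taf["vII"],
            "taf_vV": taf["vV"],
            "taf_pdgfra_d89": taf["pdgfra_d89"],
            "exon2_7_relative_copy": rel_copy,
            "viii_cross_hyb": viii_bg,
            "vii_cross_hyb_ns": vii_bg_ns,
            "egfr_locus_log2": locus_log2,
            "egfr_expression": egfr_expr,
            "pdgfra_expression": pdgfra_expr,
            "loading": loading,
        }
    ).set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# Nanostring
# ---------------------------------------------------------------------------

def _nanostring_expectations(truth: pd.DataFrame, probes: list[ProbeDef]) -> pd.DataFrame:
    """Expected counts per sample x probe.

    Target probes sit at max(signal, background): probes whose target is
    absent read out at the optical background level of the negative controls.
    """
    n = len(truth)
    e = truth["egfr_expression"].to_numpy() * truth["loading"].to_numpy()
    p = truth["pdgfra_expression"].to_numpy() * truth["loading"].to_numpy()
    load = truth["loading"].to_numpy()
    cols = {}
    for probe in probes:
        pid = probe.probe_id
        if probe.probe_class == "negative_control":
            cols[pid] = np.full(n, NEG_BACKGROUND)
        elif probe.probe_class == "housekeeping":
            cols[pid] = _HK_BASE[probe.gene] * load
        elif pid == "EGFR_KD" or pid == "EGFR_E19":
            cols[pid] = e
        elif pid == "EGFR_E1_8":
            sig = truth["taf_vIII"].to_numpy() + truth["viii_cross_hyb"].to_numpy()
            cols[pid] = np.maximum(sig * e, NEG_BACKGROUND)
        elif pid == "EGFR_E13_16":
            sig = truth["taf_vII"].to_numpy() + truth["vii_cross_hyb_ns"].to_numpy()
            cols[pid] = np.maximum(sig * e, NEG_BACKGROUND)
        elif pid == "EGFR_E28":
            cols[pid] = np.maximum((1.0 - truth["taf_vV"].to_numpy()) * e, NEG_BACKGROUND)
        elif pid == "PDGFRA_KD":
            cols[pid] = p
        elif pid == "PDGFRA_E7_10":
            cols[pid] = np.maximum(truth["taf_pdgfra_d89"].to_numpy() * p, NEG_BACKGROUND)
        else:
            raise ValueError(f"no expectation rule for probe {pid!r}")
    return pd.DataFrame(cols, index=truth.index)


def simulate_nanostring(
    spec: CohortSpec,
    probeset: list[ProbeDef] | None = None,
    n_low_control_outliers: int = 0,
) -> tuple[ProbeCountMatrix, pd.DataFrame]:
    """Raw nCounter count matrix plus truth.

    ``n_low_control_outliers`` implants under-loaded samples (all non-negative
    probe expectations scaled to 1%) to exercise sample QC.
    """
    probeset = default_probeset() if probeset is None else probeset
    if not any(p.probe_class == "housekeeping" for p in probeset):
        raise ValueError("probeset needs at least one housekeeping probe")
    if not any(p.probe_class == "negative_control" for p in probeset):
        raise ValueError("probeset needs at least one negative-control probe")
    truth = simulate_truth(spec)
    rng = spec.rng("nanostring")
    exp = _nanostring_expectations(truth, probeset)

    outliers = np.zeros(len(truth), dtype=bool)
    if n_low_control_outliers:
        idx = rng.choice(len(truth), size=n_low_control_outliers, replace=False)
        outliers[idx] = True
        neg_ids = [p.probe_id for p in probeset if p.probe_class == "negative_control"]
        scale = pd.Series(1.0, index=exp.index)
        scale[outliers] = 0.01
        exp = exp.mul(scale, axis=0)
        exp[neg_ids] = NEG_BACKGROUND
    truth = truth.assign(low_control_outlier=outliers)

    counts = pd.DataFrame(
        _draw_counts(rng, exp.to_numpy(), spec.noise_model, spec.dispersion),
        index=exp.index,
        columns=exp.columns,
    )
    return ProbeCountMatrix(counts=counts, probes=probeset), truth


def make_dilution_series(
    high_sample_counts: pd.Series,
    neg_sample_counts: pd.Series,
    fractions: list[float],
    noise_model: str = "poisson",
    dispersion: float = 0.1,
    probes: list[ProbeDef] | None = None,
    seed: int = 0,
) -> ProbeCountMatrix:
    """In-silico serial dilution of a variant-high sample into a variant-negative
    sample at constant total RNA: expected counts are the fraction-weighted mean
    of the two input expectation vectors, one output sample per fraction."""
    if len(fractions) == 0:
        raise ValueError("fractions must be non-empty")
    fr = np.asarray(fractions, dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("fractions must lie in [0,1]")
    high = high_sample_counts.astype(float)
    neg = neg_sample_counts.reindex(high.index).astype(float)
    if neg.isna().any():
        raise ValueError("high and negative samples must share probe ids")
    exp = np.outer(fr, high.to_numpy()) + np.outer(1 - fr, neg.to_numpy())
    rng = np.random.default_rng([seed, _STREAMS["dilution"]])
    counts = _draw_counts(rng, exp, noise_model, dispersion)
    if probes is None:
        probes = [ProbeDef(pid, "target", gene="", role="none") for pid in high.index]
    df = pd.DataFrame(counts, columns=list(high.index),
                      index=[f"dil_{f:g}" for f in fr])
    return ProbeCountMatrix(counts=df, probes=probes)


# ---------------------------------------------------------------------------
# qRT-PCR
# ---------------------------------------------------------------------------

STANDARD_CONC_NG = (5.0, 1.7, 0.56, 0.19, 0.062, 0.021)

_ASSAY_EFFICIENCY = {"EGFRvIII": 0.93, "EGFR_total": 0.97, "TBP": 0.95}
_ASSAY_CT_TOP = {"EGFRvIII": 24.0, "EGFR_total": 20.0, "TBP": 26.0}
MAX_CYCLES = 40.0


@dataclass
class CtTableSet:
    """Replicate CT values per sample/assay plus the standard dilution series."""

    samples: pd.DataFrame  # sample_id, assay, replicate, ct (NaN = no-call)
    standards: pd.DataFrame  # assay, conc_ng, ct
    truth: pd.DataFrame


def simulate_qpcr(
    spec: CohortSpec,
    standard_conc: tuple[float, ...] = STANDARD_CONC_NG,
    ct_noise_sd: float = 0.1,
    n_replicates: int = 3,
    efficiencies: dict[str, float] | None = None,
) -> CtTableSet:
    """Triplicate CTs from CT = CT_top - log10(q)/log10(1+E) with Gaussian
    replicate noise; the standard curve is generated from the same model at
    the dilution-series concentrations. Set ``ct_noise_sd=0`` (or
    spec.noise_model="none") for the exact noiseless limit."""
    conc = np.asarray(standard_conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be positive")
    if np.any(np.diff(conc) >= 0):
        raise ValueError("standard concentrations must be strictly decreasing")
    eff = dict(_ASSAY_EFFICIENCY, **(efficiencies or {}))
    if spec.noise_model == "none":
        ct_noise_sd = 0.0
    truth = simulate_truth(spec)
    rng = spec.rng("qpcr")

    # relative quantities, scaled so the top standard of each assay is 1.0
    e = truth["egfr_expression"].to_numpy() * truth["loading"].to_numpy()
    viii_sig = truth["taf_vIII"].to_numpy() + truth["viii_cross_hyb"].to_numpy()
    rel = {
        "EGFR_total": e / 50_000.0,
        "EGFRvIII": viii_sig * e / 50_000.0,
        "TBP": 0.1 * truth["loading"].to_numpy(),
    }

    rows = []
    for assay, q in rel.items():
        slope_ct = -1.0 / np.log10(1.0 + eff[assay])
        with np.errstate(divide="ignore"):
            ct_true = _ASSAY_CT_TOP[assay] + slope_ct * np.log10(q)
        for rep in range(1, n_replicates + 1):
            ct = ct_true + (rng.normal(0.0, ct_noise_sd, len(q)) if ct_noise_sd > 0 else 0.0)
            ct = np.where(np.isfinite(ct) & (ct <= MAX_CYCLES), ct, np.nan)
            rows.append(pd.DataFrame({
                "sample_id": truth["sample_id"],
                "assay": assay,
                "replicate": rep,
                "ct": ct,
            }))
    samples = pd.concat(rows, ignore_index=True)

    std_rows = []
    for assay in rel:
        slope_ct = -1.0 / np.log10(1.0 + eff[assay])
        ct = _ASSAY_CT_TOP[assay] + slope_ct * np.log10(conc / conc[0])
        if ct_noise_sd > 0:
            ct = ct + rng.normal(0.0, ct_noise_sd, len(conc))
        std_rows.append(pd.DataFrame({"assay": assay, "conc_ng": conc, "ct": ct}))
    standards = pd.concat(std_rows, ignore_index=True)
    return CtTableSet(samples=samples, standards=standards, truth=truth)


# ---------------------------------------------------------------------------
# spliced alignments
# ---------------------------------------------------------------------------

def _exon_bias(model: GeneModel, bias_range: tuple[float, float]) -> dict[int, float]:
    lo, hi = bias_range
    n = len(model.exons)
    return {e.number: lo + (hi - lo) * (e.number - 1) / max(n - 1, 1) for e in model.exons}


def _transcript_blocks(exons) -> tuple[np.ndarray, np.ndarray, int]:
    lens = np.array([len(e) for e in exons])
    offsets = np.concatenate([[0], np.cumsum(lens)])
    return lens, offsets, int(offsets[-1])


def _interval_to_cigar(exons, offsets, t_start: int, t_end: int):
    """Map a transcript interval to (genomic start, cigar tuples) with M/N ops."""
    cigar = []
    gstart = None
    prev_gend = None
    for i, e in enumerate(exons):
        lo = max(t_start, offsets[i])
        hi = min(t_end, offsets[i + 1])
        if lo >= hi:
            continue
        g_lo = e.start + (lo - offsets[i])
        g_hi = e.start + (hi - offsets[i])
        if gstart is None:
            gstart = g_lo
        else:
            gap = g_lo - prev_gend
            if gap > 0:
                cigar.append((3, gap))  # N: intron skip
        cigar.append((0, g_hi - g_lo))  # M
        prev_gend = g_hi
    return gstart, cigar


def _sam_header(model: GeneModel) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": model.chrom, "LN": model.span[1] + 10_000}],
        }
    )


def simulate_sample_sam(
    model: GeneModel,
    taf: dict[str, float],
    depth: int,
    path: str | Path,
    read_length: int = 50,
    frag_mean: int = 250,
    frag_sd: int = 30,
    bias_range: tuple[float, float] = (1.0, 2.0),
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
) -> Path:
    """Paired-end spliced alignments for one sample over a wild-type/variant
    isoform mixture; writes a valid SAM file (1-based, with header).

    ``taf`` maps variant name -> transcribed allelic fraction; remaining mass
    is the wild-type isoform. ``depth`` is the number of fragments. Fragment
    start positions are weighted by the 5'->3' bias ramp of the exon they
    fall in.
    """
    if len(model.exons) < 2:
        raise ValueError("degenerate gene model")
    rng = np.random.default_rng(0) if rng is None else rng
    variants = [v for v, f in taf.items() if f > 0]
    for v in variants:
        gene, _ = VARIANT_SKIPS[v]
        if gene != model.gene:
            raise ValueError(f"variant {v} is not defined on gene {model.gene}")
    mix = np.array([taf[v] for v in variants] + [1.0 - sum(taf[v] for v in variants)])
    if mix[-1] < -1e-9:
        raise ValueError("TAF values sum above 1")
    mix = np.clip(mix, 0, None)

    isoforms = []
    bias = _exon_bias(model, bias_range)
    for v in variants + [None]:
        exons = model.transcript_exons(VARIANT_SKIPS[v][1] if v else None)
        lens, offsets, tlen = _transcript_blocks(exons)
        if read_length >= tlen:
            raise ValueError("read_length must be shorter than the transcript")
        w = np.concatenate([np.full(len(e), bias[e.number]) for e in exons])
        isoforms.append((exons, offsets, tlen, w))

    # fragments per isoform scale with molar fraction x transcript length,
    # so per-position (and per-junction) coverage tracks the molar fraction
    weights = mix * np.array([iso[2] for iso in isoforms], dtype=float)
    weights = weights / weights.sum()

    path = Path(path)
    n_iso = rng.multinomial(depth, weights)
    with pysam.AlignmentFile(str(path), "w", header=_sam_header(model)) as out:
        read_idx = 0
        for (exons, offsets, tlen, w), n_frag in zip(isoforms, n_iso):
            if n_frag == 0:
                continue
            frag_lens = rng.normal(frag_mean, frag_sd, n_frag)
            frag_lens = np.clip(np.rint(frag_lens), read_length, tlen).astype(int)
            # inverse-CDF sampling of bias-weighted start positions, grouped
            # by fragment length so the cumulative weights are reused
            cumw = np.cumsum(w)
            starts = np.empty(n_frag, dtype=int)
            order = np.argsort(frag_lens, kind="stable")
            frag_lens = frag_lens[order]
            for L in np.unique(frag_lens):
                idx = np.nonzero(frag_lens == L)[0]
                limit = cumw[tlen - L]
                u = rng.random(len(idx)) * limit
                starts[idx] = np.searchsorted(cumw, u, side="right")
            for L, start in zip(frag_lens, starts):
                L = int(L)
                start = int(start)
                read_idx += 1
                name = f"{sample_id}_frag{read_idx}"
                m1 = (start, start + read_length)
                m2 = (start + L - read_length, start + L)
                g1, c1 = _interval_to_cigar(exons, offsets, *m1)
                g2, c2 = _interval_to_cigar(exons, offsets, *m2)
                for which, (gpos, cig), (mpos, _), rev in (
                    (64, (g1, c1), (g2, c2), False),
                    (128, (g2, c2), (g1, c1), True),
                ):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = name
                    a.flag = 1 | 2 | which | (16 if rev else 32)
                    a.reference_id = 0
                    a.reference_start = gpos
                    a.mapping_quality = 60
                    a.cigartuples = cig
                    a.query_sequence = "A" * read_length
                    a.next_reference_id = 0
                    a.next_reference_start = mpos if mpos is not None else gpos
                    a.template_length = L if not rev else -L
                    a.set_tag("NM", 0)
                    out.write(a)
    return path


def simulate_alignments(
    spec: CohortSpec,
    model: GeneModel,
    out_dir: str | Path,
    read_length: int = 50,
    frag_mean: int = 250,
    frag_sd: int = 30,
    depth: int = 500,
    samples: list[str] | None = None,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Per-sample SAM files for the cohort (or a subset) on one gene model.

    Each sample's isoform mixture comes from its true TAFs for the variants
    defined on that gene. Returns {sample_id: sam path} and the truth table.
    """
    truth = simulate_truth(spec)
    rng = spec.rng("alignments")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene_variants = [v for v, (g, _) in VARIANT_SKIPS.items() if g == model.gene]
    ids = samples if samples is not None else list(truth["sample_id"])
    paths = {}
    for sid in ids:
        row = truth.loc[sid]
        taf = {v: float(row[f"taf_{v}"]) for v in gene_variants}
        paths[sid] = simulate_sample_sam(
            model,
            taf,
            depth,
            out_dir / f"{sid}.{model.gene}.sam",
            read_length=read_length,
            frag_mean=frag_mean,
            frag_sd=frag_sd,
            bias_range=spec.coverage_3prime_bias,
            rng=rng,
            sample_id=sid,
        )
    return paths, truth


# ---------------------------------------------------------------------------
# DNA: exome region coverage, aCGH probes, SNP-array segments
# ---------------------------------------------------------------------------

def simulate_dna(
    spec: CohortSpec,
    base_depth: float = 20_000.0,
    region_ratio: float = 0.4,
    acgh_probe_sd: float = 0.15,
    n_probes_deleted: int = 18,
    n_probes_control: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Exome region read counts and aCGH probe log2 ratios.

    Region A (exons 2-7) expectation is reduced by the sample's true exon 2-7
    relative copy; region B (exons 8-22) tracks total locus copy. aCGH probes
    carry the locus-level log2 ratio, with the deleted-span probes shifted by
    log2(relative copy). Returns (region coverage table, aCGH probe table,
    truth).
    """
    truth = simulate_truth(spec)
    rng = spec.rng("dna")
    copy_scale = 2.0 ** truth["egfr_locus_log2"].to_numpy()
    rel = truth["exon2_7_relative_copy"].to_numpy()
    exp_b = base_depth * copy_scale
    exp_a = region_ratio * exp_b * rel
    counts = _draw_counts(rng, np.stack([exp_a, exp_b], axis=1), spec.noise_model,
                          spec.dispersion)
    coverage = pd.DataFrame(
        {"sample_id": truth["sample_id"], "counts_A": counts[:, 0], "counts_B": counts[:, 1]}
    )

    # probe positions on an abstract locus axis: deleted span then control span
    pos_del = np.linspace(0, 999, n_probes_deleted)
    pos_ctl = np.linspace(1000, 2999, n_probes_control)
    rows = []
    for i, sid in enumerate(truth["sample_id"]):
        base = truth["egfr_locus_log2"].iloc[i]
        l2_del = base + np.log2(rel[i]) + rng.normal(0, acgh_probe_sd, n_probes_deleted)
        l2_ctl = base + rng.normal(0, acgh_probe_sd, n_probes_control)
        rows.append(pd.DataFrame({
            "sample_id": sid,
            "position": np.concatenate([pos_del, pos_ctl]),
            "log2ratio": np.concatenate([l2_del, l2_ctl]),
        }))
    acgh = pd.concat(rows, ignore_index=True)
    return coverage, acgh, truth


#: abstract locus positions used by the simulated aCGH / segment tables
ACGH_DELETED_SPAN = (0.0, 1000.0)
ACGH_CONTROL_SPAN = (1000.0, 3000.0)
SNP6_EXON6_POS = 500.0
SNP6_EXON19_POS = 2000.0


def simulate_snp6_segments(spec: CohortSpec, segment_sd: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segmented SNP-array copy-number tables consistent with the cohort truth.

    Samples without intragenic loss get one segment covering the locus; samples
    with exon 2-7 loss get a breakpoint between the deleted and control spans.
    """
    truth = simulate_truth(spec)
    rng = spec.rng("snp6")
    rows = []
    for _, r in truth.iterrows():
        base = r["egfr_locus_log2"]
        if r["exon2_7_relative_copy"] >= 1.0:
            rows.append((r["sample_id"], "chr7_toy", 0.0, 3000.0,
                         base + rng.normal(0, segment_sd)))
        else:
            rows.append((r["sample_id"], "chr7_toy", 0.0, 1000.0,
                         base + np.log2(r["exon2_7_relative_copy"]) + rng.normal(0, segment_sd)))
            rows.append((r["sample_id"], "chr7_toy", 1000.0, 3000.0,
                         base + rng.normal(0, segment_sd)))
    seg = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "value"])
    return seg, truth


# ---------------------------------------------------------------------------
# preservation pairs (frozen vs FFPE)
# ---------------------------------------------------------------------------

def simulate_preservation_pairs(
    spec: CohortSpec,
    probeset: list[ProbeDef] | None = None,
    yield_range: tuple[float, float] = (0.2, 0.7),
    probe_noise_sd: float = 0.25,
) -> tuple[ProbeCountMatrix, ProbeCountMatrix, pd.DataFrame]:
    """Patient-matched frozen and FFPE count matrices.

    FFPE degradation is modelled as a per-sample RNA yield factor plus
    per-probe lognormal distortion before count noise; negative controls keep
    the flat optical background.
    """
    probeset = default_probeset() if probeset is None else probeset
    truth = simulate_truth(spec)
    rng = spec.rng("ffpe")
    exp = _nanostring_expectations(truth, probeset)
    neg_ids = [p.probe_id for p in probeset if p.probe_class == "negative_control"]

    frozen_counts = _draw_counts(rng, exp.to_numpy(), spec.noise_model, spec.dispersion)
    yields = rng.uniform(*yield_range, size=(len(truth), 1))
    distort = rng.lognormal(0.0, probe_noise_sd, size=exp.shape)
    ffpe_exp = exp.to_numpy() * yields * distort
    ffpe_exp_df = pd.DataFrame(ffpe_exp, index=exp.index, columns=exp.columns)
    ffpe_exp_df[neg_ids] = NEG_BACKGROUND
    ffpe_counts = _draw_counts(rng, ffpe_exp_df.to_numpy(), spec.noise_model, spec.dispersion)

    frozen = ProbeCountMatrix(pd.DataFrame(frozen_counts, index=exp.index, columns=exp.columns),
                              probes=probeset)
    ffpe = ProbeCountMatrix(pd.DataFrame(ffpe_counts, index=exp.index, columns=exp.columns),
                            probes=probeset)
    return frozen, ffpe, truth


def noiseless(spec: CohortSpec) -> CohortSpec:
    """Copy of the spec in the exact ideal limit: expectations returned
    without count noise and no nonspecific cross-hybridization signal."""
    return replace(spec, noise_model="none", cross_hyb_median=0.0)
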