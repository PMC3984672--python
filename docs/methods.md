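# Methods

This note documents the models, parameter choices and numerical decisions in
`rtkdel`, and what the synthetic cohort does and does not establish about
real data.

## Probe-count normalization and calling

Raw counts are normalized to a housekeeping panel (B2M, B4GALT1, CLTC, E2F4,
GAPDH, POLR2A, SDHA, TBP): each gene's count is divided by its cross-sample
mean, and the per-sample **median** of these ratios is the normalization
factor. The order of operations is pinned as ratio-to-mean first, median
second. The same factor is applied to negative-control probes, whose
normalized per-sample mean, times five, is the detection threshold.

Because each sample contributes to the cross-sample gene means, scale
invariance (doubling one sample's counts leaves its normalized values
unchanged) and idempotence (renormalizing a normalized matrix gives factors
of 1) hold only up to O(1/n); both are verified at 1 % tolerance on
200-sample cohorts.

Sample QC excludes samples whose housekeeping geometric mean falls below
0.25× the cohort median (config-exposed; the threshold is a package choice —
any value that separates percent-level under-loading from ordinary spread
behaves identically). The background-drift diagnostic rank-correlates
per-sample mean negative-control counts with per-sample totals over
**endogenous probes only** (including the negatives in the total builds a
spurious self-correlation, measurable in small panels) and uses a one-sided
(greater) test so the null flag rate equals α.

Junction-variant TAF is mutant/reference, reported raw and clipped to [0,1]
(mutant transcripts contain the reference region, so ratios above 1 are
noise); classification uses the clipped value with strata negative /
<1 % / 1–10 % (right-open) / ≥10 %. vII positivity additionally requires the
raw ratio to exceed 2 % of total EGFR counts. The C-terminal model is a
zero-intercept least-squares line of terminal-exon on anchor counts over the
central 90 % of the ratio distribution (5th–95th percentile, inclusive); a
free intercept would let optical background dominate low-expression samples.
Truncation strata: <10 % of expected is high, <60 % intermediate. Missing
probes make calling operations refuse rather than impute.

## qRT-PCR

Standard curves are OLS fits of CT on log10(concentration) over the six-point
dilution series (5, 1.7, 0.56, 0.19, 0.062, 0.021 ng by default); efficiency
is `10^(−1/slope) − 1`. Relative quantity is `(1+E)^(ct_ref − CT)`, where
`ct_ref` is the **minimum** CT on the curve (the highest-concentration
point; this quantity is sometimes labelled "CT_max" — the name refers to
maximal template, not maximal cycle count). Replicate CTs are averaged
before conversion by default; quantity-space averaging is available.
Samples are rejected when ≥2 TBP replicates fail below 36 cycles, or when
the unscaled MAD of quantified TBP replicates exceeds 25 % of their median
(the MAD rule operates on quantities, not CTs). Fitted efficiencies outside
(0, 1.5] signal broken input.

## RNA-seq junction counting

A split read supports junction (i, j) when a gap (`N`) operation joins the
end of exon i exactly to the start of exon j. Only perfect alignments count:
CIGAR restricted to `M`/`N`, no clips, insertions or deletions, and a zero
edit-distance tag when present (a flag relaxes the NM requirement).
Gapped-pair evidence (mates wholly inside non-adjacent exons with a
plausible fragment length on the skipping transcript) is tabulated
separately and excluded from fractions by default, because pair-implied
junctions are ambiguous between isoforms. A junction needs ≥2 supporting
reads per sample to count as detected; pooled analyses sum raw reads.

Mutant junctions are compared against the wild-type junction sharing the
same acceptor exon (E1–8 vs E7–8, E13–16 vs E15–16, PDGFRA E7–10 vs E9–10),
which cancels 3′ coverage bias by construction: fraction =
mutant/(mutant + wild-type). Confidence intervals are exact two-sided 95 %
Clopper–Pearson. Internal coordinates are 0-based half-open; SAM, and GFF3
I/O are 1-based per those standards, BED12 0-based.

When a counting-positive sample shows zero junction reads, the binomial
probability of zero successes at the counting TAF and the observed junction
coverage decides between "within sampling error" (>5 %) and genuine
discordance.

## DNA-level inference

The exome coverage model regresses deleted-region counts (exons 2–7) on
control-region counts (exons 8–22) with zero intercept over the middle 90 %
of per-sample ratios; the normalized ratio `counts_A/(slope × counts_B)` is
1 for copy-neutral samples and falls with intragenic loss. The trim is on
the ratio distribution, so a few true deletions cannot bend the normal
model. ROC analysis uses `1 − normalized ratio` and reports sensitivity at
95 % specificity (largest TPR with FPR ≤ 5 %). The binary deletion flag
defaults to normalized ratio < 0.8 (config-exposed; the score is continuous
and the ROC is the primary output). Read-start counting is the default
coverage definition.

The aCGH partition test is a classic equal-variance two-sample t test of
probe log2 ratios between the candidate deleted span (midpoint of intron 1
to the end of exon 7) and the control span (start of exon 8 through exon
21), two-sided, uncorrected, at p = 0.05. The reported `significant` flag is
directional (deleted-span mean below control) so gains are not called
deletions; the undirected rejection indicator is also returned, and it is
the quantity whose null rate calibrates to the nominal 5 %.

Segmented SNP-array input is compared at exon 6 versus exon 19; relative
deletion requires the exon-6 segment value to sit more than 0.2 log2 units
below exon 19 (config-exposed; the margin trades sensitivity to
low-fraction deletions against segment noise). High-level amplification is
log2 ratio strictly greater than 2; exactly 2 is negative.

## Agreement metrics

Spearman rank correlation with average ranks for ties; p-values by exact
permutation enumeration for n ≤ 10 and the t-approximation above. Binary
agreement treats the frozen-tissue (or reference-platform) call as truth;
undefined metrics from single-class references are reported as
not-applicable rather than 0. Positivity for the binary classifier is
detection plus TAF ≥ 1 % (marginal calls are "borderline" and grouped with
negative; config-exposed). Dilution linearity is the r² of an OLS line of
probe counts on mixing fraction.

## The synthetic cohort

`CohortSpec` defaults define the study conditions: 200 samples, 45 % EGFR-
and 10 % PDGFRA-amplified, amplified expression scaled 20×, variant
positivity only within the amplified stratum — P(vIII+|amp) = 0.5 with TAF ~
U(0.01, 0.9), P(vII+|amp) = 0.04, P(vV+|amp) = 0.10, P(Δ8,9+|PDGFRA-amp) =
0.4 — Poisson count noise (negative binomial with configurable dispersion
available, since real overdispersion of digital counting is small and not
known precisely), and a linear 1→2 5′→3′ exon depth ramp for RNA-seq.
Baseline expression and sample loading are lognormal; negative controls sit
at a flat expectation of 5 counts, independent of sample totals. Target
probes read out at max(signal, background): a probe whose target is absent
sits exactly at the optical background level.

A shared sub-threshold cross-hybridization fraction (lognormal, median
0.1 %, log-sd 1) is added to the vIII signal on both hybridization-based
platforms, reproducing the observation that sub-threshold measurements
correlate across platforms; an independent term of the same size models
probe-specific vII cross-hybridization. At this level the nonspecific signal
essentially never crosses the 1 % positivity bound.

DNA truth is coupled to expression: exon 2–7 relative copy is exactly 1 when
vIII TAF is 0 and `clip(1 − 0.9·TAF, 0.05, 0.995)` otherwise, so every
expressing sample shows relative loss and deeper loss accompanies higher
expression. Amplified samples draw locus log2 ratios from U(2.2, 3.8),
others from N(0, 0.08); aCGH probes add N(0, 0.15) noise, SNP-array
segments N(0, 0.05).

The read simulator draws fragments per isoform proportional to molar
fraction × transcript length (longer transcripts shed more fragments), which
is what makes junction coverage track molar TAF; fragment lengths are
N(250, 30) truncated at the 50 bp read length, and start positions are
bias-weighted by exon. Toy EGFR (28 exons) and PDGFRA (23 exons) models with
synthetic coordinates give exon 1 a 400 bp length so the vIII junction is
not within one fragment length of the transcript 5′ end. All simulators
derive one shared truth table from the spec seed through independent named
RNG streams, so the four modalities are jointly consistent and identical
seeds give bit-identical outputs.

**What passing tests show — and don't.** The generator reproduces the
statistical structure the methods assume (amplification-coupled expression,
orders-of-magnitude TAF range, count noise, 3′ bias, DNA–RNA coupling), so
truth-recovery results validate the *statistics*: normalization, thresholds,
trimmed fits, exact intervals and classifier logic. It does not model
hybridization chemistry, probe-specific affinity differences, cartridge
batch effects, FFPE fragmentation-length bias, alignment artifacts, tumor
purity or subclonal heterogeneity — so sensitivity/specificity figures on
synthetic cohorts are upper bounds for real tissue, not performance claims.

## Problem sizes

Tests and drivers use 200-sample cohorts (50 replicates for truth-recovery),
2000 replicates for type-I and CI-coverage calibrations, 20-seed dilution
series, and ~20 000 simulated fragments per sequenced sample (a few hundred
junction-spanning reads, comparable to deep coverage of an amplified locus);
a 30-sample subset is sequenced in the RNA-seq driver. These sizes give
binomial standard errors well inside the tested margins.
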