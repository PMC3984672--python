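# rtkdel

Quantification and classification of **intragenic receptor tyrosine kinase
deletion transcripts** in glioblastoma — EGFRvIII (exon 2–7 deletion), EGFRvII
(exon 13→16 junction), EGFRvV (C-terminal truncation) and PDGFRAΔ8,9 (exon
7→10 junction) — across four measurement platforms, driven by a
synthetic-cohort generator with known per-sample truth.

The package is aimed at people building or validating transcript-level assays
for deletion variants: it implements the normalization, QC, calling and
detection-limit statistics for digital probe counting (nCounter-style),
qRT-PCR relative quantification, RNA-seq junction counting, and DNA
copy-number inference, plus the agreement metrics used to compare them.

## The quantities computed

**Transcribed allelic fraction (TAF).** For a deletion variant, a
mutant-junction measurement *m* (junction probe counts, or junction-spanning
reads) is compared with a reference measurement *r* in the region shared by
mutant and wild-type transcripts (kinase domain probe, or the wild-type
junction at the same acceptor exon):

    TAF = m / r            (probe counting; clipped to [0,1])
    TAF = m / (m + r)      (junction reads)

Calls are stratified as negative (below 5× the mean normalized
negative-control counts), marginal (<1 %), intermediate (1–10 %) or high
(≥10 %). C-terminal truncation is called from under-representation of the
3′-terminal exon probe relative to a kinase-domain anchor, against a
zero-intercept line fitted to the central 90 % of the cohort.

**Detection limits.** With *k* mutant among *n* junction reads, exact
two-sided 95 % Clopper–Pearson intervals bound the expressible fraction; for
*k* = 0 the upper bound is `1 − 0.025^(1/n)`.

**qRT-PCR.** Efficiency `E = 10^(−1/slope) − 1` from the standard-curve slope
(CT on log10 concentration); relative quantity `(1+E)^(ct_ref − CT)`; vIII is
reported as a fraction of total EGFR after TBP normalization.

**DNA.** Exome read counts over EGFR exons 2–7 versus exons 8–22 are
normalized by a trimmed cohort regression; aCGH probes flanking the deletion
are compared by a per-sample t test; high-level amplification is a locus log2
ratio strictly above 2.

## Worked example

```python
from rtkdel.synthetic import CohortSpec, simulate_nanostring
from rtkdel.nanostring import normalize, qc_samples, call_junction_variant

spec = CohortSpec(n_samples=200, seed=20130)   # ~45% EGFR-amplified cohort
matrix, truth = simulate_nanostring(spec)
qc = qc_samples(matrix)
norm = normalize(matrix, exclude=list(qc.loc[qc.excluded, "sample_id"]))
calls = call_junction_variant(norm, "vIII", "EGFR_E1_8", "EGFR_KD")
print(calls["call_class"].value_counts())
```

prints

```
call_class
negative        134
high             43
marginal         21
intermediate      2
```

i.e. 66/200 samples show signal above the detection threshold; 21 of those
are marginal (below 1 % of total EGFR, mostly nonspecific hybridization),
while 45 are positive at ≥1 % — 43 of them with the mutant above 10 % of
total EGFR transcript. `(calls.positive == (truth.taf_vIII > 0.01)).all()`
is `True` for this seed: every positivity call matches the simulated truth.

The same cohort runs end to end through the numbered drivers:

```sh
python analysis/01_simulate_cohort.py     # all four platforms + truth
python analysis/02_nanostring_calls.py    # normalization, QC, variant calls
python analysis/03_qpcr_quant.py          # standard curves, TBP-normalized fractions
python analysis/04_rnaseq_validation.py   # junction counts, cross-tab, pooled CI
python analysis/05_dna_deletion.py        # coverage model, ROC, aCGH, SNP-array
python analysis/06_concordance.py         # dilution linearity, frozen-vs-FFPE
```

Each writes its tables under `results/` and prints a short summary (e.g.
`02`: vIII positive 22 % of the cohort and 46 % of amplified tumors, 100 %
sensitivity/specificity against truth; `05`: exome deletion score predicts
expressed vIII with AUC 0.999).

There is also a thin CLI (`rtkdel nanostring|qpcr|rnaseq|dna|concord`) over
the same functions for TSV/SAM inputs.

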