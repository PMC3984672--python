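#!/usr/bin/env python
"""Generate the synthetic study cohort with known truth across all four
platforms: digital probe counts, qRT-PCR CT tables, DNA region coverage /
aCGH probes / SNP-array segments. Writes everything under results/sim/.

The cohort emulates the study conditions: 200 tumors, ~45% EGFR-amplified,
half of amplified tumors vIII-positive with TAF spanning 1-90%, Poisson count
noise, and DNA exon 2-7 loss coupled to vIII expression.
"""

from pathlib import Path

from rtkdel.synthetic import (
    CohortSpec,
    simulate_dna,
    simulate_nanostring,
    simulate_qpcr,
    simulate_snp6_segments,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SPEC = CohortSpec(n_samples=200, seed=20130)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    matrix, truth = simulate_nanostring(SPEC)
    matrix.to_tsv(OUT / "nanostring_counts.tsv", OUT / "probes.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    cts = simulate_qpcr(SPEC)
    cts.samples.to_csv(OUT / "qpcr_cts.tsv", sep="\t", index=False)
    cts.standards.to_csv(OUT / "qpcr_standards.tsv", sep="\t", index=False)

    coverage, acgh, _ = simulate_dna(SPEC)
    coverage.to_csv(OUT / "exome_region_counts.tsv", sep="\t", index=False)
    acgh.to_csv(OUT / "acgh_probes.tsv", sep="\t", index=False, float_format="%.4f")

    segments, _ = simulate_snp6_segments(SPEC)
    segments.to_csv(OUT / "snp6_segments.tsv", sep="\t", index=False)

    n_amp = int(truth["amplified_egfr"].sum())
    n_viii = int((truth["taf_vIII"] > 0).sum())
    print(f"cohort: {SPEC.n_samples} samples -> {OUT}")
    print(f"  EGFR-amplified: {n_amp} ({n_amp / SPEC.n_samples:.0%})")
    print(f"  vIII-expressing: {n_viii} "
          f"({n_viii / SPEC.n_samples:.0%} of cohort, {n_viii / n_amp:.0%} of amplified)")


if __name__ == "__main__":
    main()
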