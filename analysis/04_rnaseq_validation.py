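#!/usr/bin/env python
"""Validate the counting-based vIII calls with simulated spliced RNA-seq:
junction extraction, variant fractions with exact binomial CIs, cross-tab
against the digital-counting classes, and the pooled detection limit over
low-expression samples.

A 30-sample subset is sequenced in silico (the full cohort would add nothing
but runtime); read depth is set so junction coverage is a few hundred reads,
comparable to deep coverage of an amplified locus.
"""

from pathlib import Path

import pandas as pd

from rtkdel.genemodel import toy_egfr
from rtkdel.rnaseq import (
    concordance_with_nanostring,
    default_variant_defs,
    extract_junctions,
    pooled_detection_limit,
    variant_fraction,
)
from rtkdel.synthetic import CohortSpec, simulate_alignments

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "rnaseq"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "sam"
SPEC = CohortSpec(n_samples=200, seed=20130)
N_SEQUENCED = 30
DEPTH = 20_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = toy_egfr()
    truth = pd.read_csv(BASE / "sim" / "truth.tsv", sep="\t").set_index("sample_id")
    subset = list(truth.index[:N_SEQUENCED])
    paths, _ = simulate_alignments(SPEC, model, SCRATCH, depth=DEPTH, samples=subset)

    defs = default_variant_defs(("vIII",))
    tables, fractions = {}, []
    for sid, path in paths.items():
        tab = extract_junctions(path, model)
        tables[sid] = tab
        fractions.append(variant_fraction(tab, defs, sample_id=sid))
    fr = pd.concat(fractions, ignore_index=True)
    fr.to_csv(OUT / "variant_fractions.tsv", sep="\t", index=False)

    ns_calls = pd.read_csv(BASE / "nanostring" / "calls.tsv", sep="\t")
    viii = ns_calls[ns_calls["variant"] == "vIII"]
    tab, detail = concordance_with_nanostring(viii, fr)
    tab.to_csv(OUT / "crosstab.tsv", sep="\t")
    detail.to_csv(OUT / "concordance_detail.tsv", sep="\t", index_label="sample_id")
    print("counting-class vs sequencing-bin cross-tabulation:")
    print(tab.to_string())

    # pooled detection limit over samples that express little EGFR and show
    # no confirmed mutant junction
    low_ids = set(truth.index[~truth["amplified_egfr"]]) & set(subset)
    sub_tables = [tables[s] for s in sorted(low_ids)]
    pooled = pooled_detection_limit(sub_tables, defs[0])
    print(f"pooled over {pooled['n_samples']} unamplified samples: "
          f"{pooled['mutant_reads']} mutant / {pooled['total_reads']} junction reads; "
          f"95% CI {100 * pooled['ci95_low']:.2f}-{100 * pooled['ci95_high']:.2f}%")
    pd.DataFrame([pooled]).to_csv(OUT / "pooled_detection_limit.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
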