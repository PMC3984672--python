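#!/usr/bin/env python
"""Normalize the simulated nCounter matrix, apply QC, and call all four
deletion variants; report prevalence overall and within amplified tumors and
score calls against the simulated truth.
"""

from pathlib import Path

import pandas as pd

from rtkdel.nanostring import (
    call_cterm,
    call_junction_variant,
    fit_cterm_model,
    normalize,
    qc_negative_drift,
    qc_samples,
)
from rtkdel.probes import VARIANT_PROBES, ProbeCountMatrix

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "sim", BASE / "nanostring"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = ProbeCountMatrix.from_tsv(SIM / "nanostring_counts.tsv", SIM / "probes.tsv")
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t").set_index("sample_id")

    drift = qc_negative_drift(matrix)
    print(f"negative-control drift: rho={drift['rho']:.3f} "
          f"p={drift['p_value']:.3f} -> {'pass' if drift['passed'] else 'FAIL'}")

    qc = qc_samples(matrix)
    qc.to_csv(OUT / "qc_report.tsv", sep="\t", index=False)
    excluded = list(qc.loc[qc["excluded"], "sample_id"])
    print(f"sample QC: {len(excluded)} excluded of {len(qc)}")

    norm = normalize(matrix, exclude=excluded)
    norm.values.to_csv(OUT / "normalized.tsv", sep="\t", index_label="sample_id")

    all_calls = []
    for variant in ("vIII", "vII", "pdgfra_d89"):
        mut, ref = VARIANT_PROBES[variant]
        calls = call_junction_variant(norm, variant, mut, ref)
        all_calls.append(calls)
    calls = pd.concat(all_calls)
    calls.to_csv(OUT / "calls.tsv", sep="\t", index=False)

    cterm_probe, anchor = VARIANT_PROBES["vV"]
    model = fit_cterm_model(norm, anchor, cterm_probe)
    cterm = call_cterm(norm, model)
    cterm.to_csv(OUT / "cterm_calls.tsv", sep="\t", index=False)
    print(f"C-terminal model: slope={model.slope:.3f} on {model.n_fit} samples")

    amp = truth["amplified_egfr"].reindex(norm.values.index)
    viii = calls[calls["variant"] == "vIII"]
    n = len(viii)
    pos = viii["positive"]
    print(f"vIII positive (TAF>=1%): {pos.sum()}/{n} ({pos.mean():.0%} of cohort, "
          f"{pos[amp.to_numpy()].mean():.0%} of amplified)")
    high = viii["call_class"] == "high"
    print(f"vIII high (TAF>=10%): {high.sum()}/{n} ({high.mean():.1%})")
    print(f"vV truncation: {int(cterm['positive'].sum())} positive "
          f"({cterm['positive'].mean():.1%}), {int(cterm['high_only'].sum())} high")

    truth_pos = (truth["taf_vIII"] > 0.01).reindex(viii.index)
    sens = (truth_pos & pos).sum() / truth_pos.sum()
    spec = (~truth_pos & ~pos).sum() / (~truth_pos).sum()
    print(f"against truth: sensitivity {sens:.1%}, specificity {spec:.1%}")


if __name__ == "__main__":
    main()
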