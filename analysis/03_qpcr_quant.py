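#!/usr/bin/env python
"""Fit qRT-PCR standard curves, quantify relative EGFR/vIII/TBP, apply
replicate QC, and compare the vIII fraction against the digital-counting TAF
calls (cross-platform concordance).
"""

from pathlib import Path

import pandas as pd

from rtkdel.concordance import rank_concordance
from rtkdel.qpcr import (
    fit_standard_curve,
    normalize_and_fraction,
    quantify_samples,
    reject_samples,
)

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "sim", BASE / "qpcr"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cts = pd.read_csv(SIM / "qpcr_cts.tsv", sep="\t")
    standards = pd.read_csv(SIM / "qpcr_standards.tsv", sep="\t")

    curves = {}
    for assay, grp in standards.groupby("assay"):
        c = fit_standard_curve(list(zip(grp["conc_ng"], grp["ct"])), assay)
        curves[assay] = c
        print(f"{assay}: slope={c.slope:.3f} efficiency={c.efficiency:.3f} "
              f"r2={c.r_squared:.4f}")

    rejection = reject_samples(cts[cts["assay"] == "TBP"], curves["TBP"])
    n_rej = int(rejection["rejected"].sum())
    print(f"replicate QC: {n_rej} of {rejection.shape[0]} samples rejected")

    quantities = quantify_samples(cts, curves)
    rel = normalize_and_fraction(quantities, rejection)
    rel.to_csv(OUT / "relquant.tsv", sep="\t", index=False)

    ns_calls = pd.read_csv(BASE / "nanostring" / "calls.tsv", sep="\t")
    viii = ns_calls[ns_calls["variant"] == "vIII"].set_index("sample_id")
    common = viii.index.intersection(rel.index)
    det = viii.loc[common, "detected"]
    rho, p = rank_concordance(
        viii.loc[common, "taf_raw"][det],
        rel.loc[common, "viii_fraction_raw"][det].fillna(0.0),
    )
    print(f"cross-platform vIII fraction concordance over {int(det.sum())} "
          f"detected samples: Spearman rho={rho:.3f} (p={p:.2e})")


if __name__ == "__main__":
    main()
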