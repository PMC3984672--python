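"""Probe annotations and the raw nCounter count-matrix container.

The digital counting platform reports one integer count per probe per sample.
Probes fall into three classes: targets (gene-specific), housekeeping
(normalization panel) and negative controls (no endogenous target; they
estimate optical/hybridization background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROBE_CLASSES = ("target", "housekeeping", "negative_control")
PROBE_ROLES = ("mutant_junction", "kinase_domain", "cterm_exon", "anchor_exon", "control", "none")

#: the 8-gene normalization panel
HOUSEKEEPING_GENES = ("B2M", "B4GALT1", "CLTC", "E2F4", "GAPDH", "POLR2A", "SDHA", "TBP")

#: variant -> (mutant/observed probe, reference/anchor probe) in the default panel
VARIANT_PROBES = {
    "vIII": ("EGFR_E1_8", "EGFR_KD"),
    "vII": ("EGFR_E13_16", "EGFR_KD"),
    "vV": ("EGFR_E28", "EGFR_E19"),
    "pdgfra_d89": ("PDGFRA_E7_10", "PDGFRA_KD"),
}


@dataclass(frozen=True)
class ProbeDef:
    probe_id: str
    probe_class: str
    gene: str = ""
    role: str = "none"
    target_sequence: str | None = None

    def __post_init__(self):
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe_class {self.probe_class!r}")
        if self.role not in PROBE_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.probe_class == "negative_control":
            if self.gene or self.role not in ("control", "none"):
                raise ValueError("negative-control probes carry no gene or target role")


def default_probeset() -> list[ProbeDef]:
    """The deletion-variant panel: junction and anchor probes for EGFR and
    PDGFRA, the 8 housekeeping genes, and 6 negative controls."""
    probes = [
        ProbeDef("EGFR_KD", "target", "EGFR", "kinase_domain"),
        ProbeDef("EGFR_E1_8", "target", "EGFR", "mutant_junction"),
        ProbeDef("EGFR_E13_16", "target", "EGFR", "mutant_junction"),
        ProbeDef("EGFR_E19", "target", "EGFR", "anchor_exon"),
        ProbeDef("EGFR_E28", "target", "EGFR", "cterm_exon"),
        ProbeDef("PDGFRA_KD", "target", "PDGFRA", "kinase_domain"),
        ProbeDef("PDGFRA_E7_10", "target", "PDGFRA", "mutant_junction"),
    ]
    probes += [ProbeDef(g, "housekeeping", g, "control") for g in HOUSEKEEPING_GENES]
    probes += [ProbeDef(f"NEG_{c}", "negative_control", "", "control") for c in "ABCDEF"]
    return probes


@dataclass
class ProbeCountMatrix:
    """Raw counts: samples x probes, with probe-class annotation."""

    counts: pd.DataFrame  # index: sample ids, columns: probe ids, integer
    probes: list[ProbeDef] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError("probe ids must be unique")
        if list(self.counts.columns) != ids:
            raise ValueError("count-matrix columns must match the probe list")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def probe(self, probe_id: str) -> ProbeDef:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def probe_ids(self, probe_class: str | None = None, gene: str | None = None) -> list[str]:
        out = []
        for p in self.probes:
            if probe_class is not None and p.probe_class != probe_class:
                continue
            if gene is not None and p.gene != gene:
                continue
            out.append(p.probe_id)
        return out

    # ---- I/O ----------------------------------------------------------
    def to_tsv(self, counts_path: str | Path, probes_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
        if probes_path is not None:
            write_probe_tsv(self.probes, probes_path)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, probes_path: str | Path) -> "ProbeCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
        probes = read_probe_tsv(probes_path)
        counts = counts[[p.probe_id for p in probes]]
        return cls(counts=counts, probes=probes)


def write_probe_tsv(probes: list[ProbeDef], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (p.probe_id, p.probe_class, p.gene, p.role, p.target_sequence or "")
            for p in probes
        ],
        columns=["probe_id", "probe_class", "gene", "role", "target_sequence"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_probe_tsv(path: str | Path) -> list[ProbeDef]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        ProbeDef(
            probe_id=r.probe_id,
            probe_class=r.probe_class,
            gene=r.gene,
            role=r.role or "none",
            target_sequence=r.target_sequence or None,
        )
        for r in df.itertuples()
    ]
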