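"""Exon models for junction counting and read simulation.

Coordinates are 0-based half-open internally; SAM emission and GFF3 I/O are
1-based per those standards. Toy EGFR/PDGFRA models (invented coordinates,
realistic exon counts) ship as code for tests and simulations.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import gffutils


@dataclass(frozen=True)
class Exon:
    number: int
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene: str
    exons: list[Exon]
    strand: str = "+"

    def __post_init__(self):
        if sorted(e.number for e in self.exons) != list(range(1, len(self.exons) + 1)):
            raise ValueError("exon numbering must be contiguous from 1")
        self.exons = sorted(self.exons, key=lambda e: e.number)
        prev_end = None
        for e in self.exons:
            if e.end <= e.start:
                raise ValueError(f"empty exon {e.number}")
            if prev_end is not None and e.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e.end
        if len(self.exons) < 2:
            raise ValueError("gene model needs at least 2 exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def exon(self, number: int) -> Exon:
        return self.exons[number - 1]

    def exon_ends(self) -> dict[int, int]:
        """Map genomic end coordinate -> exon number (donor side)."""
        return {e.end: e.number for e in self.exons}

    def exon_starts(self) -> dict[int, int]:
        """Map genomic start coordinate -> exon number (acceptor side)."""
        return {e.start: e.number for e in self.exons}

    def exon_containing(self, pos: int) -> int | None:
        for e in self.exons:
            if e.start <= pos < e.end:
                return e.number
        return None

    # ---- transcripts ---------------------------------------------------
    def transcript_exons(self, skip: tuple[int, int] | None = None) -> list[Exon]:
        """Exons of the spliced transcript; `skip=(a, b)` removes exons a..b
        inclusive (an intragenic deletion isoform)."""
        if skip is None:
            return list(self.exons)
        a, b = skip
        return [e for e in self.exons if not a <= e.number <= b]

    # ---- I/O -----------------------------------------------------------
    def to_bed12(self, path: str | Path) -> None:
        start, end = self.span
        sizes = ",".join(str(len(e)) for e in self.exons)
        starts = ",".join(str(e.start - start) for e in self.exons)
        line = "\t".join(
            [
                self.chrom,
                str(start),
                str(end),
                self.gene,
                "0",
                self.strand,
                str(start),
                str(end),
                "0",
                str(len(self.exons)),
                sizes + ",",
                starts + ",",
            ]
        )
        Path(path).write_text(line + "\n")

    @classmethod
    def from_bed12(cls, path: str | Path, gene: str | None = None) -> "GeneModel":
        for raw in Path(path).read_text().splitlines():
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.split("\t")
            if gene is not None and f[3] != gene:
                continue
            chrom, start = f[0], int(f[1])
            strand = f[5]
            sizes = [int(s) for s in f[10].rstrip(",").split(",")]
            offsets = [int(s) for s in f[11].rstrip(",").split(",")]
            exons = [
                Exon(i + 1, chrom, start + off, start + off + sz)
                for i, (off, sz) in enumerate(zip(offsets, sizes))
            ]
            if strand == "-":  # exon 1 is the 3'-most block on minus strand
                n = len(exons)
                exons = [Exon(n - e.number + 1, e.chrom, e.start, e.end) for e in exons]
            return cls(gene=f[3], exons=exons, strand=strand)
        raise ValueError(f"gene {gene!r} not found in {path}")

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        start, end = self.span
        gid = f"gene:{self.gene}"
        lines.append(
            f"{self.chrom}\trtkdel\tgene\t{start + 1}\t{end}\t.\t{self.strand}\t.\tID={gid};Name={self.gene}"
        )
        for e in self.exons:
            lines.append(
                f"{self.chrom}\trtkdel\texon\t{e.start + 1}\t{e.end}\t.\t{self.strand}\t.\t"
                f"ID=exon:{self.gene}:{e.number};Parent={gid};exon_number={e.number}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path, gene: str) -> "GeneModel":
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
        )
        exons = []
        strand = "+"
        for feat in db.features_of_type("exon"):
            parent = feat.attributes.get("Parent", [""])[0]
            if gene not in parent and feat.attributes.get("gene", [""])[0] != gene:
                continue
            number = int(feat.attributes["exon_number"][0])
            exons.append(Exon(number, feat.seqid, feat.start - 1, feat.end))
            strand = feat.strand
        if not exons:
            raise ValueError(f"no exon features for gene {gene!r} in {path}")
        return cls(gene=gene, exons=exons, strand=strand)


def _built_model(gene: str, chrom: str, n_exons: int, origin: int) -> GeneModel:
    exons = []
    pos = origin
    for i in range(1, n_exons + 1):
        # first exon carries the 5'UTR, so it is much longer than the rest
        length = 400 if i == 1 else 150 + (i * 7) % 60
        exons.append(Exon(i, chrom, pos, pos + length))
        pos += length + 400 + (i * 13) % 300
    return GeneModel(gene=gene, exons=exons)


def toy_egfr() -> GeneModel:
    """28-exon toy EGFR model (synthetic coordinates) for tests/simulation."""
    return _built_model("EGFR", "chr7_toy", 28, 55_000_000)


def toy_pdgfra() -> GeneModel:
    """23-exon toy PDGFRA model (synthetic coordinates)."""
    return _built_model("PDGFRA", "chr4_toy", 23, 54_000_000)
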