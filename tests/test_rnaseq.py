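"""Junction extraction from spliced alignments, variant fractions and exact
binomial detection limits, checked against brute-force read enumeration."""

import re
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from rtkdel.genemodel import GeneModel
from rtkdel.rnaseq import (
    VariantJunctionDef,
    bin_fraction,
    concordance_with_nanostring,
    default_variant_defs,
    extract_junctions,
    junction_support,
    pooled_detection_limit,
    variant_fraction,
)

HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chrT\tLN:1000\n"


def sam_line(name, flag, pos1, cigar, nm=0, rnext="*", pnext=0, nm_tag=True):
    seq_len = sum(int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar))
    seq = "A" * max(seq_len, 1)
    fields = [name, str(flag), "chrT", str(pos1), "60", cigar, rnext, str(pnext), "0",
              seq, "*"]
    if nm_tag:
        fields.append(f"NM:i:{nm}")
    return "\t".join(fields) + "\n"


@pytest.fixture
def fixture_sam(tmp_path, tiny_gene) -> Path:
    """Hand-built reads over the 3-exon toy gene (exons at 100-200, 300-400,
    500-600, 0-based). SAM POS is 1-based."""
    lines = [
        # two clean E1-E2 split reads (confirmed junction)
        sam_line("r01", 0, 161, "40M100N10M"),
        sam_line("r02", 0, 171, "30M100N20M"),
        # one E1-E3 split read (unconfirmed: single read)
        sam_line("r03", 0, 161, "40M300N10M"),
        # one E2-E3 split read
        sam_line("r04", 0, 361, "40M100N10M"),
        # gap with wrong donor boundary: no junction
        sam_line("r05", 0, 161, "35M105N10M"),
        # soft clip: discarded by the perfect-alignment filter
        sam_line("r06", 0, 161, "5S35M100N10M"),
        # insertion: discarded
        sam_line("r07", 0, 161, "20M2I20M"),
        # nonzero edit distance: discarded
        sam_line("r08", 0, 311, "50M", nm=1),
        # plain exonic read: no junction
        sam_line("r09", 0, 311, "50M"),
        # deletion op: discarded
        sam_line("r10", 0, 161, "20M5D20M"),
        # double-gap read touching E1-E2 and E2-E3
        sam_line("r11", 0, 191, "10M100N100M100N10M"),
        # unmapped: skipped
        sam_line("r12", 4, 0, "*"),
    ]
    p = tmp_path / "fixture.sam"
    p.write_text(HEADER + "".join(lines))
    return p


def brute_force_junctions(sam_path: Path, model: GeneModel) -> dict:
    """Independent oracle: parse SAM text directly and enumerate junctions."""
    ends = {e.end: e.number for e in model.exons}
    starts = {e.start: e.number for e in model.exons}
    counts: dict[tuple[int, int], int] = {}
    for line in Path(sam_path).read_text().splitlines():
        if line.startswith("@"):
            continue
        f = line.split("\t")
        flag, pos, cigar = int(f[1]), int(f[3]) - 1, f[5]
        if flag & 0x904:  # unmapped/secondary/supplementary
            continue
        ops = re.findall(r"(\d+)([A-Z=])", cigar)
        if any(op not in "MN" for _, op in ops):
            continue
        nm = [x for x in f[11:] if x.startswith("NM:i:")]
        if nm and int(nm[0][5:]) != 0:
            continue
        p = pos
        for n, op in ops:
            n = int(n)
            if op == "M":
                p += n
            else:
                d, a = ends.get(p), starts.get(p + n)
                if d is not None and a is not None and a > d:
                    counts[(d, a)] = counts.get((d, a), 0) + 1
                p += n
    return counts


class TestExtractJunctions:
    def test_matches_brute_force_enumeration(self, fixture_sam, tiny_gene):
        table = extract_junctions(fixture_sam, tiny_gene)
        oracle = brute_force_junctions(fixture_sam, tiny_gene)
        got = {
            (r.donor_exon, r.acceptor_exon): r.split_reads
            for r in table.itertuples()
        }
        assert got == oracle

    def test_expected_counts_by_hand(self, fixture_sam, tiny_gene):
        table = extract_junctions(fixture_sam, tiny_gene)
        assert junction_support(table, (1, 2)) == 3  # r01, r02, r11
        assert junction_support(table, (2, 3)) == 2  # r04, r11
        assert junction_support(table, (1, 3)) == 1  # r03 only
        confirmed = table.set_index(["donor_exon", "acceptor_exon"])["confirmed"]
        assert bool(confirmed.loc[(1, 2)]) and not bool(confirmed.loc[(1, 3)])

    def test_soft_clipped_read_contributes_nothing(self, tmp_path, tiny_gene):
        p = tmp_path / "clip.sam"
        p.write_text(HEADER + sam_line("c1", 0, 161, "5S35M100N10M"))
        table = extract_junctions(p, tiny_gene)
        assert table.empty

    def test_nm_relaxation_flag(self, tmp_path, tiny_gene):
        p = tmp_path / "nm.sam"
        p.write_text(HEADER + sam_line("n1", 0, 161, "40M100N10M", nm=2))
        assert extract_junctions(p, tiny_gene).empty
        relaxed = extract_junctions(p, tiny_gene, require_nm_zero=False)
        assert junction_support(relaxed, (1, 2)) == 1

    def test_gapped_pair_mode_counts_skipping_pairs(self, tmp_path, tiny_gene):
        lines = [
            # mates wholly in exons 1 and 3, no intervening exon coverage:
            # implied fragment on the exon1->exon3 transcript = 40 + 50 = 90
            sam_line("p1", 1 | 64, 161, "40M", rnext="=", pnext=501),
            sam_line("p1", 1 | 128, 501, "50M", rnext="=", pnext=161),
            # adjacent-exon pair: not junction evidence
            sam_line("p2", 1 | 64, 161, "40M", rnext="=", pnext=301),
            sam_line("p2", 1 | 128, 301, "50M", rnext="=", pnext=161),
        ]
        p = tmp_path / "pairs.sam"
        p.write_text(HEADER + "".join(lines))
        table = extract_junctions(p, tiny_gene, mode="split_plus_pairs")
        row = table[(table.donor_exon == 1) & (table.acceptor_exon == 3)]
        assert row["gapped_pairs"].iloc[0] == 1
        assert row["split_reads"].iloc[0] == 0
        assert not ((table.donor_exon == 1) & (table.acceptor_exon == 2)).any()

    def test_coordinate_roundtrip_bed_gff(self, fixture_sam, tiny_gene, tmp_path):
        # counts invariant under 0-based BED12 vs 1-based GFF3 representation
        bed, gff = tmp_path / "m.bed", tmp_path / "m.gff3"
        tiny_gene.to_bed12(bed)
        tiny_gene.to_gff3(gff)
        t_bed = extract_junctions(fixture_sam, GeneModel.from_bed12(bed, "TOY"))
        t_gff = extract_junctions(fixture_sam, GeneModel.from_gff3(gff, "TOY"))
        t_ref = extract_junctions(fixture_sam, tiny_gene)
        pd.testing.assert_frame_equal(t_bed, t_ref)
        pd.testing.assert_frame_equal(t_gff, t_ref)


def table_from_counts(counts: dict) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene": "EGFR",
            "donor_exon": [j[0] for j in counts],
            "acceptor_exon": [j[1] for j in counts],
            "split_reads": list(counts.values()),
            "gapped_pairs": 0,
        }
    )
    df["confirmed"] = df["split_reads"] >= 2
    return df


VIII = VariantJunctionDef("vIII", "EGFR", (1, 8), (7, 8))


class TestVariantFraction:
    def test_simple_fraction(self):
        vf = variant_fraction(table_from_counts({(1, 8): 3, (7, 8): 7}), [VIII])
        assert vf["fraction"].iloc[0] == pytest.approx(0.30)

    def test_single_read_not_detected(self):
        vf = variant_fraction(table_from_counts({(1, 8): 1, (7, 8): 500}), [VIII])
        assert not vf["detected"].iloc[0]
        assert vf["fraction"].iloc[0] == 0.0

    def test_zero_mutant_ci_closed_form(self):
        vf = variant_fraction(table_from_counts({(7, 8): 100}), [VIII])
        assert vf["ci95_high"].iloc[0] == pytest.approx(1 - 0.025 ** (1 / 100), rel=1e-12)
        assert vf["ci95_high"].iloc[0] == pytest.approx(0.0362, abs=5e-5)

    def test_no_coverage_flagged(self):
        vf = variant_fraction(table_from_counts({(2, 3): 5}), [VIII])
        assert vf["flag"].iloc[0] == "no coverage"
        assert np.isnan(vf["fraction"].iloc[0])

    def test_acceptor_mismatch_rejected(self):
        with pytest.raises(ValueError):
            VariantJunctionDef("bad", "EGFR", (1, 8), (6, 7))


class TestPooledDetectionLimit:
    def test_853_reads_upper_bound(self):
        res = pooled_detection_limit([table_from_counts({(7, 8): 853})], VIII)
        assert res["ci95_high"] * 100 == pytest.approx(0.43, abs=0.005)

    def test_1789_reads_upper_bound(self):
        res = pooled_detection_limit([table_from_counts({(7, 8): 1789})], VIII)
        assert res["ci95_high"] * 100 == pytest.approx(0.21, abs=0.005)

    def test_single_read_bound(self):
        res = pooled_detection_limit([table_from_counts({(7, 8): 1})], VIII)
        assert res["ci95_high"] == pytest.approx(0.975)

    def test_sums_across_samples(self):
        tables = [table_from_counts({(1, 8): 1, (7, 8): 9}),
                  table_from_counts({(1, 8): 2, (7, 8): 8})]
        res = pooled_detection_limit(tables, VIII)
        assert res["mutant_reads"] == 3 and res["total_reads"] == 20
        assert res["fraction"] == pytest.approx(0.15)

    def test_zero_pooled_reads_errors(self):
        with pytest.raises(ValueError):
            pooled_detection_limit([table_from_counts({(2, 3): 4})], VIII)


class TestCIcoverage:
    def test_clopper_pearson_coverage_at_two_percent(self, rng):
        # 2000 binomial draws at p=0.02: the exact interval must cover >=93%
        from rtkdel._stats import clopper_pearson

        n, p = 500, 0.02
        draws = rng.binomial(n, p, 2000)
        covered = 0
        for k in np.unique(draws):
            lo, hi = clopper_pearson(int(k), n)
            covered += int(((draws == k) & (lo <= p) & (p <= hi)).sum()) if lo <= p <= hi else 0
        assert covered / 2000 >= 0.93


class TestBiasRobustness:
    def test_doubling_acceptor_region_depth_cancels(self):
        # both junctions share the acceptor exon, so a common depth factor
        # leaves the fraction unchanged
        base = variant_fraction(table_from_counts({(1, 8): 30, (7, 8): 70}), [VIII])
        doubled = variant_fraction(table_from_counts({(1, 8): 60, (7, 8): 140}), [VIII])
        assert base["fraction"].iloc[0] == doubled["fraction"].iloc[0]


class TestConcordance:
    def ns_calls(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "call_class", "taf", "positive"])

    def rs_rows(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "fraction", "detected",
                                           "mutant_reads", "wildtype_reads"])

    def test_identical_classifications_are_diagonal(self):
        ns = self.ns_calls([("a", "high", 0.5, True), ("b", "intermediate", 0.05, True),
                            ("c", "negative", 0.0, False)])
        rs = self.rs_rows([("a", 0.5, True, 50, 50), ("b", 0.05, True, 5, 95),
                           ("c", np.nan, False, 0, 0)])
        tab, detail = concordance_with_nanostring(ns, rs)
        assert (detail["note"] == "").all()
        assert tab.loc["high", ">10%"] == 1
        assert tab.loc["intermediate", "1-10%"] == 1

    def test_low_coverage_discordance_within_sampling_error(self):
        # positive at 1.6% TAF with zero reads at 100x junction coverage:
        # P(0 reads) = 0.984^100 = 0.20 > 0.05
        ns = self.ns_calls([("a", "intermediate", 0.016, True)])
        rs = self.rs_rows([("a", 0.0, False, 0, 100)])
        _, detail = concordance_with_nanostring(ns, rs)
        assert detail.loc["a", "note"] == "within sampling error"

    def test_deep_coverage_discordance_is_flagged(self):
        ns = self.ns_calls([("a", "high", 0.3, True)])
        rs = self.rs_rows([("a", 0.0, False, 0, 5000)])
        _, detail = concordance_with_nanostring(ns, rs)
        assert detail.loc["a", "note"] == "discordant"

    def test_no_overlap_errors(self):
        ns = self.ns_calls([("a", "high", 0.5, True)])
        rs = self.rs_rows([("b", 0.5, True, 5, 5)])
        with pytest.raises(ValueError):
            concordance_with_nanostring(ns, rs)

    def test_jointly_simulated_cohort_mostly_diagonal(self, egfr_model, tmp_path):
        from rtkdel.nanostring import call_junction_variant, normalize
        from rtkdel.synthetic import CohortSpec, simulate_alignments, simulate_nanostring

        spec = CohortSpec(n_samples=20, seed=31)
        m, truth = simulate_nanostring(spec)
        calls = call_junction_variant(normalize(m), "vIII", "EGFR_E1_8", "EGFR_KD")
        paths, _ = simulate_alignments(spec, egfr_model, tmp_path, depth=20_000)
        defs = default_variant_defs(("vIII",))
        frames = []
        for sid, p in paths.items():
            tab = extract_junctions(p, egfr_model)
            frames.append(variant_fraction(tab, defs, sample_id=sid))
        rs = pd.concat(frames, ignore_index=True)
        tab, detail = concordance_with_nanostring(calls, rs)
        # deep junction coverage: platform class and sequencing bin must agree
        # for samples with real signal; marginal/negative samples both land in
        # the none-detected or <1% bins
        agree = 0
        for sid, row in detail.iterrows():
            ns_cls, bin_ = row["ns_class"], row["rnaseq_bin"]
            ok = (
                (ns_cls == "high" and bin_ == ">10%")
                or (ns_cls == "intermediate" and bin_ == "1-10%")
                or (ns_cls in ("negative", "marginal") and bin_ in ("none_detected", "<1%"))
            )
            agree += int(ok)
        assert agree / len(detail) >= 0.95
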