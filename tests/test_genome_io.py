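"""GFF3/FASTA round trips, coordinate conventions, windows, censuses."""

import pytest
from hypothesis import given, settings, strategies as st

from paralogon_scope.genome_io import (
    GFF3ParseError,
    Segment,
    extract_window,
    family_census,
    read_family_map,
    read_gene_models,
    write_gene_models,
)
from conftest import make_gene


def _write_inputs(tmp_path, gff_text, fasta_text, fam_text="gene_id\tfamily_id\ng1\tfamA\n"):
    gff = tmp_path / "in.gff3"
    gff.write_text(gff_text)
    fa = tmp_path / "in.fa"
    fa.write_text(fasta_text)
    fam = tmp_path / "fam.tsv"
    fam.write_text(fam_text)
    return gff, fa, fam


class TestReadGeneModels:
    def test_empty_gff_gives_empty_list(self, tmp_path):
        gff, fa, fam = _write_inputs(tmp_path, "##gff-version 3\n", "")
        records, issues = read_gene_models(gff, fa, fam, species="sp")
        assert records == [] and issues == []

    def test_one_based_inclusive_converted(self, tmp_path):
        gff, fa, fam = _write_inputs(
            tmp_path,
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1\t9\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\tx\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=m1\n",
            ">g1\nAAA\n",
        )
        records, issues = read_gene_models(gff, fa, fam, species="sp")
        (rec,) = records
        assert (rec.start, rec.end) == (0, 9)
        assert rec.end - rec.start == 9
        assert rec.exons == [(0, 9)]
        assert not issues

    def test_two_exon_gene_passes_invariants(self, tmp_path):
        # 30 nt + 33 nt = 63 nt = 21 codons
        gff, fa, fam = _write_inputs(
            tmp_path,
            "##gff-version 3\n"
            "chr1\tx\tgene\t101\t263\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t101\t263\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\tx\tCDS\t101\t130\t.\t+\t0\tID=c1;Parent=m1\n"
            "chr1\tx\tCDS\t231\t263\t.\t+\t0\tID=c2;Parent=m1\n",
            ">g1\n" + "M" + "A" * 20 + "\n",
        )
        records, issues = read_gene_models(gff, fa, fam, species="sp")
        (rec,) = records
        assert rec.cds_length == 63
        assert rec.validate() == []
        assert not issues

    def test_malformed_line_reports_line_number(self, tmp_path):
        gff, fa, fam = _write_inputs(
            tmp_path,
            "##gff-version 3\nchr1\tx\tgene\tnotanint\t9\t.\t+\t.\tID=g1\n",
            "",
        )
        with pytest.raises(GFF3ParseError, match=":2:"):
            read_gene_models(gff, fa, fam, species="sp")

    def test_cds_length_warning_flagged_not_dropped(self, tmp_path):
        gff, fa, fam = _write_inputs(
            tmp_path,
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t10\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1\t10\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\tx\tCDS\t1\t10\t.\t+\t0\tID=c1;Parent=m1\n",
            ">g1\nMAA\n",
        )
        records, issues = read_gene_models(gff, fa, fam, species="sp")
        assert len(records) == 1
        assert "cds_length_warning" in records[0].flags
        assert any("divisible by 3" in m for m in issues)

    def test_unknown_family_kept_and_flagged(self, tmp_path):
        gff, fa, fam = _write_inputs(
            tmp_path,
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t9\t.\t+\t.\tID=g2\n"
            "chr1\tx\tmRNA\t1\t9\t.\t+\t.\tID=m1;Parent=g2\n"
            "chr1\tx\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=m1\n",
            ">g2\nAAA\n",
        )
        records, _ = read_gene_models(gff, fa, fam, species="sp")
        assert records[0].family_id is None
        assert "unknown_family" in records[0].flags

    def test_bad_family_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\tfam\ng1\tfamA\n")
        with pytest.raises(ValueError, match="header"):
            read_family_map(p)


class TestRoundTrip:
    def test_write_then_read_identical(self, tmp_path, small_sim):
        species = "gar"
        recs = sorted(small_sim.records_for(species), key=lambda r: r.gene_id)
        write_gene_models(
            recs, tmp_path / "o.gff3", tmp_path / "o.fa", tmp_path / "o.tsv"
        )
        back, issues = read_gene_models(
            tmp_path / "o.gff3", tmp_path / "o.fa", tmp_path / "o.tsv", species
        )
        assert issues == []
        back = sorted(back, key=lambda r: r.gene_id)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert (a.gene_id, a.chrom, a.start, a.end, a.strand) == (
                b.gene_id, b.chrom, b.start, b.end, b.strand
            )
            assert a.exons == b.exons
            assert a.protein == b.protein
            assert a.family_id == b.family_id


class TestExtractWindow:
    @pytest.fixture
    def toy(self):
        return [
            make_gene("gA", start=1_000, family_id="f1"),
            make_gene("gB", start=5_000, family_id="f2"),
            make_gene("gC", start=50_000, family_id="f3"),
        ]

    def test_enumerated_overlap(self, toy):
        seg = extract_window(toy, "gB", 10_000)
        assert seg.gene_ids == ["gA", "gB"]

    def test_zero_flank_is_self_overlap(self, toy):
        seg = extract_window(toy, "gB", 0)
        assert seg.gene_ids == ["gB"]

    def test_clipped_at_zero(self, toy):
        seg = extract_window(toy, "gA", 10_000)
        assert seg.start == 0

    def test_missing_focal_errors(self, toy):
        with pytest.raises(KeyError):
            extract_window(toy, "nope", 100)

    def test_scaffold_gene_cannot_anchor(self):
        genes = [make_gene("gS", chrom="scaffold_12")]
        with pytest.raises(ValueError, match="scaffold"):
            extract_window(genes, "gS", 100)

    @given(st.integers(min_value=0, max_value=60_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_flank(self, flank):
        toy = [
            make_gene("gA", start=1_000),
            make_gene("gB", start=5_000),
            make_gene("gC", start=50_000),
        ]
        small = set(extract_window(toy, "gB", flank).gene_ids)
        big = set(extract_window(toy, "gB", flank + 7_000).gene_ids)
        assert small <= big


class TestFamilyCensus:
    @pytest.fixture
    def setting(self):
        records = [
            make_gene("a1", family_id="famA", start=1_000),
            make_gene("a2", family_id="famA", start=2_000),
            make_gene("b1", family_id="famB", start=3_000),
            make_gene("u1", family_id=None, start=4_000),
        ]
        seg = Segment("gar", "chr1", 0, 10_000, ["a1", "a2", "b1", "u1"])
        return records, [seg]

    def test_threshold_two(self, setting):
        records, segs = setting
        selected, census = family_census(segs, records, 2)
        assert selected == ["famA"]
        assert census.count("famA", "gar") == 2

    def test_threshold_one_selects_all(self, setting):
        records, segs = setting
        selected, _ = family_census(segs, records, 1)
        assert selected == ["famA", "famB"]

    def test_monotone_decreasing_in_threshold(self, setting):
        records, segs = setting
        prev = None
        for k in (1, 2, 3, 4):
            sel, _ = family_census(segs, records, k)
            if prev is not None:
                assert set(sel) <= set(prev)
            prev = sel

    def test_unknown_family_not_counted(self, setting):
        records, segs = setting
        _, census = family_census(segs, records, 1)
        assert census.counts.keys() == {"famA", "famB"}

    def test_min_members_validated(self, setting):
        records, segs = setting
        with pytest.raises(ValueError):
            family_census(segs, records, 0)
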