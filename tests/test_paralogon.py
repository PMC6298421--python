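"""Segment graphs, member assignment, and member tables."""

import pytest

from conftest import make_gene
from paralogon_scope.genome_io import Segment
from paralogon_scope.paralogon_assembly import (
    assign_members,
    build_segment_graph,
    member_table,
    render_member_table,
    write_graphml,
)
from paralogon_scope.wgd_timing import EVENT_1R2R, EVENT_LOCAL, OhnologGroup


def _toy_world():
    """Two species x two chromosomes; three families with 1R2R ohnolog pairs
    split across the chromosome pair, one family locally duplicated."""
    records, segments = [], []
    groups = {f: [] for f in ("f1", "f2", "f3", "floc")}
    pair_classes = {f: {} for f in groups}
    for sp in ("gar", "mammal"):
        for copy, chrom in (("A", "chr1"), ("B", "chr2")):
            gids = []
            for i, fam in enumerate(("f1", "f2", "f3")):
                gid = f"{sp}_{fam}_{copy}"
                records.append(
                    make_gene(gid, species=sp, chrom=chrom,
                              start=1000 + i * 10_000, family_id=fam)
                )
                gids.append(gid)
            segments.append(Segment(sp, chrom, 0, 100_000, gids))
    # ohnolog groups: one per copy per family, spanning both species
    for fam in ("f1", "f2", "f3"):
        for copy in ("A", "B"):
            groups[fam].append(
                OhnologGroup(fam, frozenset({f"gar_{fam}_{copy}", f"mammal_{fam}_{copy}"}),
                             frozenset({"gar", "mammal"}))
            )
        for sp in ("gar", "mammal"):
            pair_classes[fam][frozenset({f"{sp}_{fam}_A", f"{sp}_{fam}_B"})] = EVENT_1R2R
    # a local duplicate pair on gar chr1 only
    for tag in ("x", "y"):
        records.append(
            make_gene(f"gar_floc_{tag}", species="gar", chrom="chr1",
                      start=50_000 + (0 if tag == "x" else 500), family_id="floc")
        )
    segments[0].gene_ids.extend(["gar_floc_x", "gar_floc_y"])
    groups["floc"].append(
        OhnologGroup("floc", frozenset({"gar_floc_x", "gar_floc_y"}), frozenset({"gar"}))
    )
    pair_classes["floc"][frozenset({"gar_floc_x", "gar_floc_y"})] = EVENT_LOCAL
    return records, segments, groups, pair_classes


class TestSegmentGraph:
    def test_paralogy_edge_counts_split_families(self):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        k1 = ("gar", "chr1", 0, 100_000)
        k2 = ("gar", "chr2", 0, 100_000)
        assert g.paralogy[k1][k2]["weight"] == 3

    def test_local_duplicates_contribute_no_edge(self):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        for _, _, data in g.paralogy.edges(data=True):
            assert "floc" not in data["families"]

    def test_orthology_links_same_copy_across_species(self):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        k1 = ("gar", "chr1", 0, 100_000)
        k2 = ("mammal", "chr1", 0, 100_000)
        assert g.orthology[k1][k2]["weight"] == 3

    def test_no_shared_families_no_edges(self):
        records = [
            make_gene("a", species="gar", chrom="chr1", family_id="f1"),
            make_gene("b", species="gar", chrom="chr2", family_id="f2"),
        ]
        segs = [
            Segment("gar", "chr1", 0, 10_000, ["a"]),
            Segment("gar", "chr2", 0, 10_000, ["b"]),
        ]
        groups = {
            "f1": [OhnologGroup("f1", frozenset({"a"}), frozenset({"gar"}))],
            "f2": [OhnologGroup("f2", frozenset({"b"}), frozenset({"gar"}))],
        }
        g = build_segment_graph(segs, records, groups, {"f1": {}, "f2": {}})
        assert g.paralogy.number_of_edges() == 0
        assert g.orthology.number_of_edges() == 0

    def test_generation_restriction_blocks_cross_links(self):
        records, segments, groups, pcls = _toy_world()
        gen = {"gar": frozenset({"1R"}), "mammal": frozenset({"1R", "3R"})}
        g = build_segment_graph(
            segments, records, groups, pcls, species_generation=gen
        )
        assert g.orthology.number_of_edges() == 0


class TestAssignMembers:
    def test_members_partition_segments(self):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        members = assign_members(g, min_shared_families=2)
        seen = [s.key for m in members for s in m.segments]
        assert sorted(seen) == sorted(s.key for s in segments)
        assert len(seen) == len(set(seen))

    def test_quartet_like_pairing(self):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        members = assign_members(g, min_shared_families=2)
        # chr1 segments of both species together; chr2 likewise
        sets = {
            frozenset((s.species, s.chrom) for s in m.segments) for m in members
        }
        assert frozenset({("gar", "chr1"), ("mammal", "chr1")}) in sets
        assert frozenset({("gar", "chr2"), ("mammal", "chr2")}) in sets

    def test_raising_threshold_never_merges(self):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        coarse = assign_members(g, min_shared_families=1)
        fine = assign_members(g, min_shared_families=3)
        coarse_map = {s.key: m.label for m in coarse for s in m.segments}
        fine_map = {s.key: m.label for m in fine for s in m.segments}
        # refinement: same fine member -> same coarse member
        for k1 in fine_map:
            for k2 in fine_map:
                if fine_map[k1] == fine_map[k2]:
                    assert coarse_map[k1] == coarse_map[k2]

    def test_translocation_split_flagged(self):
        records, segments, groups, pcls = _toy_world()
        # split gar chr1 segment into two chromosomes carrying >=2 families each
        k = segments[0]
        segments[0] = Segment("gar", "chr1", 0, 50_000, ["gar_f1_A", "gar_f2_A"])
        segments.insert(
            1, Segment("gar", "chr1b", 0, 50_000, ["gar_f3_A", "gar_floc_x", "gar_floc_y"])
        )
        g = build_segment_graph(segments, records, groups, pcls)
        members = assign_members(g, min_shared_families=1)
        flagged = [m for m in members if m.translocation_split]
        assert any("gar" in m.translocation_split for m in flagged)

    def test_over_retention_warning(self):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        with pytest.warns(UserWarning, match="over-retention"):
            assign_members(
                g,
                min_shared_families=2,
                ohnolog_groups_by_family=groups,
                max_members={"gar": 1, "mammal": 1},
            )


class TestMemberTable:
    def test_losses_marked_with_crosses(self):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        members = assign_members(g, min_shared_families=2)
        table = member_table(members, ["f1", "f2", "f3", "fmissing"], records)
        col = table[(members[0].label, "gar")]
        assert col.loc["fmissing"] == "x"
        assert col.loc["f1"] != "x"

    def test_incomplete_sequences_flagged(self):
        records, segments, groups, pcls = _toy_world()
        # truncate one protein below half the family maximum
        for r in records:
            if r.gene_id == "gar_f1_A":
                r.protein = r.protein[:5]
        g = build_segment_graph(segments, records, groups, pcls)
        members = assign_members(g, min_shared_families=2)
        table = member_table(members, ["f1", "f2", "f3"], records)
        cells = table.to_numpy().ravel().tolist()
        assert any("(incomplete)" in str(c) for c in cells)

    def test_render_and_graphml(self, tmp_path):
        records, segments, groups, pcls = _toy_world()
        g = build_segment_graph(segments, records, groups, pcls)
        members = assign_members(g, min_shared_families=2)
        txt = render_member_table(member_table(members, ["f1", "f2"], records))
        assert "member" in txt
        write_graphml(g, tmp_path / "g.graphml")
        assert (tmp_path / "g.graphml").stat().st_size > 0
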