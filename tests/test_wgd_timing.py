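"""Species-overlap duplication labeling and WGD-epoch classification."""

import random

import dendropy
import pytest

from paralogon_scope.wgd_timing import (
    EVENT_1R2R,
    EVENT_3R,
    EVENT_LOCAL,
    SpeciesTree,
    build_duplication_scheme,
    classify_event,
    classify_tree,
    duplication_loss_cost,
    label_nodes,
    ohnolog_groups,
    ohnolog_pair_classes,
    reclassify_tandem_duplications,
    reconcile_nni,
)


def rooted(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestSpeciesTreeParsing:
    def test_wgd_comments_attach_to_correct_branches(self, species_tree):
        by_label = {
            species_tree.node_label(nd): evs for nd, evs in species_tree.wgd.items()
        }
        assert by_label == {"vertebrata": ["1R", "2R"], "teleostei": ["3R"]}

    def test_leaf_annotation_supported(self):
        st = SpeciesTree.from_newick("(a:1,(b:1,c:1[&WGD=4R]):1);")
        (nd,) = [n for n, e in st.wgd.items() if e == ["4R"]]
        assert st.node_label(nd) == "c"

    def test_duplicate_wgd_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SpeciesTree.from_newick("(a:1[&WGD=1R],(b:1,c:1):1[&WGD=1R]);")

    def test_mrca_and_events(self, species_tree):
        nd = species_tree.mrca({"zebrafish", "medaka"})
        assert species_tree.node_label(nd) == "teleostei"
        assert species_tree.events_above(nd) == ["3R"]


class TestLabelNodes:
    def test_disjoint_children_are_speciation(self, species_tree):
        t = rooted("((m2h,m2g),(m4h,m4g));")
        label_nodes(
            t, {"m2h": "mammal", "m2g": "gar", "m4h": "mammal", "m4g": "gar"}
        )
        events = [nd.event for nd in t.postorder_internal_node_iter()]
        assert events == ["speciation", "speciation", "duplication"]

    def test_unmapped_leaf_errors(self):
        t = rooted("((a,b),c);")
        with pytest.raises(ValueError, match="species"):
            label_nodes(t, {"a": "x", "b": "y"})

    def test_matches_brute_force_on_random_trees(self, species_tree):
        species = sorted(species_tree.species)
        rng = random.Random(4)
        for _ in range(25):
            leaves = [f"g{i}" for i in range(8)]
            spmap = {g: rng.choice(species) for g in leaves}
            topo = leaves[:]
            while len(topo) > 1:
                i, j = sorted(rng.sample(range(len(topo)), 2), reverse=True)
                a, b = topo[i], topo[j]
                topo = [x for k, x in enumerate(topo) if k not in (i, j)]
                topo.append(f"({a},{b})")
            t = rooted(topo[0] + ";")
            label_nodes(t, spmap)
            for nd in t.postorder_internal_node_iter():
                ch = nd.child_nodes()
                s1 = {spmap[l.taxon.label] for l in ch[0].leaf_iter()}
                s2 = {spmap[l.taxon.label] for l in ch[1].leaf_iter()}
                expected = "duplication" if s1 & s2 else "speciation"
                assert nd.event == expected


class TestClassifyEvent:
    def test_vertebrate_wide_duplication_is_1r2r(self, species_tree):
        cls, branch = classify_event({"mammal", "gar"}, species_tree)
        assert (cls, branch) == (EVENT_1R2R, "vertebrata")

    def test_teleost_duplication_is_3r(self, species_tree):
        cls, branch = classify_event(
            {"zebrafish", "stickleback", "medaka"}, species_tree
        )
        assert (cls, branch) == (EVENT_3R, "teleostei")

    def test_single_species_is_lineage_specific(self, species_tree):
        cls, branch = classify_event({"mammal"}, species_tree)
        assert (cls, branch) == (EVENT_LOCAL, "mammal")

    def test_invariant_under_gene_relabeling(self, species_tree):
        spmap1 = {"x1": "mammal", "x2": "gar", "x3": "mammal", "x4": "gar"}
        spmap2 = {"y9": "mammal", "y8": "gar", "y7": "mammal", "y6": "gar"}
        t1 = rooted("((x1,x2),(x3,x4));")
        t2 = rooted("((y9,y8),(y7,y6));")
        c1 = classify_tree(t1, species_tree, spmap1, "f")
        c2 = classify_tree(t2, species_tree, spmap2, "f")
        assert [c.event_class for c in c1] == [c.event_class for c in c2]


class TestOhnologGroups:
    def test_groups_partition_leaves(self, species_tree):
        t = rooted("(((m2h,m2g),(m4h,m4g)),out);")
        spmap = {
            "m2h": "mammal", "m2g": "gar", "m4h": "mammal", "m4g": "gar",
            "out": "lancelet",
        }
        classify_tree(t, species_tree, spmap, "f")
        groups = ohnolog_groups(t, spmap, "f")
        all_genes = sorted(g for grp in groups for g in grp.genes)
        assert all_genes == sorted(spmap)
        assert {frozenset(g.genes) for g in groups} >= {
            frozenset({"m2h", "m2g"}),
            frozenset({"m4h", "m4g"}),
        }

    def test_pair_classes_cover_cross_pairs(self, species_tree):
        t = rooted("((m2h,m2g),(m4h,m4g));")
        spmap = {"m2h": "mammal", "m2g": "gar", "m4h": "mammal", "m4g": "gar"}
        classify_tree(t, species_tree, spmap, "f")
        pairs = ohnolog_pair_classes(t)
        assert pairs[frozenset({"m2h", "m4h"})] == EVENT_1R2R
        assert frozenset({"m2h", "m2g"}) not in pairs


class TestTandemReclassification:
    def test_adjacent_copies_downgraded(self, species_tree):
        t = rooted("((am,ag),(bm,bg));")
        spmap = {"am": "mammal", "ag": "gar", "bm": "mammal", "bg": "gar"}
        calls = classify_tree(t, species_tree, spmap, "f")
        assert calls[0].event_class == EVENT_1R2R
        positions = {
            "am": ("mammal", "chr1", 100_000),
            "bm": ("mammal", "chr1", 110_000),
            "ag": ("gar", "chr2", 500_000),
            "bg": ("gar", "chr2", 505_000),
        }
        changed = reclassify_tandem_duplications(t, positions, tandem_bp=50_000)
        assert len(changed) == 1
        assert calls[0].event_class == EVENT_LOCAL

    def test_separate_chromosomes_untouched(self, species_tree):
        t = rooted("((am,ag),(bm,bg));")
        spmap = {"am": "mammal", "ag": "gar", "bm": "mammal", "bg": "gar"}
        calls = classify_tree(t, species_tree, spmap, "f")
        positions = {
            "am": ("mammal", "chr1", 100_000),
            "bm": ("mammal", "chr9", 100_000),
            "ag": ("gar", "chr2", 500_000),
            "bg": ("gar", "chr8", 500_000),
        }
        assert reclassify_tandem_duplications(t, positions) == []
        assert calls[0].event_class == EVENT_1R2R


class TestReconciliation:
    def test_dl_cost_zero_for_congruent_tree(self, species_tree):
        t = rooted("((((m,b),x),c),(g,(z,(s,o))));")
        spmap = {"m": "mammal", "b": "bird", "x": "amphibian",
                 "c": "coelacanth", "g": "gar", "z": "zebrafish",
                 "s": "stickleback", "o": "medaka"}
        assert duplication_loss_cost(t, species_tree, spmap) == 0

    def test_nni_fixes_misplaced_lineage(self, species_tree):
        # gar wrongly inside one 3R clade; NNI should restore it
        wrong = rooted("((za,(gar,(sa,ma)):0.004):0.05,(zb,(sb,mb)):0.05);")
        spmap = {
            "za": "zebrafish", "sa": "stickleback", "ma": "medaka",
            "zb": "zebrafish", "sb": "stickleback", "mb": "medaka",
            "gar": "gar",
        }
        before = duplication_loss_cost(wrong, species_tree, spmap)
        moves = reconcile_nni(wrong, species_tree, spmap, max_edge_length=0.02)
        after = duplication_loss_cost(wrong, species_tree, spmap)
        assert moves >= 1
        assert after < before

    def test_long_edges_protected(self, species_tree):
        wrong = rooted("((za,(gar,(sa,ma)):0.4):0.05,(zb,(sb,mb)):0.05);")
        spmap = {
            "za": "zebrafish", "sa": "stickleback", "ma": "medaka",
            "zb": "zebrafish", "sb": "stickleback", "mb": "medaka",
            "gar": "gar",
        }
        assert reconcile_nni(wrong, species_tree, spmap, max_edge_length=0.02) == 0


class TestDuplicationScheme:
    def test_zero_loss_counts(self, zero_noise_sim, species_tree):
        from paralogon_scope.msa_identity import build_msa
        from paralogon_scope.gene_trees import distance_matrix, nj_tree, root_at_outgroup

        ds = zero_noise_sim
        fam = "fam02"
        recs = sorted(
            (r for r in ds.records if r.family_id == fam), key=lambda r: r.gene_id
        )
        msa = build_msa({r.gene_id: r.protein for r in recs})
        tree = nj_tree(distance_matrix(msa))
        og = [r.gene_id for r in recs if r.species == "lancelet"]
        tree = root_at_outgroup(tree, og)
        spmap = {r.gene_id: r.species for r in recs}
        reconcile_nni(tree, species_tree, spmap)
        calls = classify_tree(tree, species_tree, spmap, fam)
        groups = ohnolog_groups(tree, spmap, fam)
        scheme = build_duplication_scheme({fam: (tree, calls, groups)}, species_tree)
        row = scheme.iloc[0]
        assert row.post2R_copies == 4
        assert row.post3R_copies == 8
        assert row.n_mammal == 4 and row.n_zebrafish == 8
        assert row.not_identified_in == ""

    def test_missing_species_reported_not_lost(self, species_tree):
        t = rooted("((m2h,m2g),(m4h,m4g));")
        spmap = {"m2h": "mammal", "m2g": "gar", "m4h": "mammal", "m4g": "gar"}
        calls = classify_tree(t, species_tree, spmap, "f")
        groups = ohnolog_groups(t, spmap, "f")
        scheme = build_duplication_scheme({"f": (t, calls, groups)}, species_tree)
        missing = scheme.iloc[0].not_identified_in.split(",")
        assert "bird" in missing and "zebrafish" in missing
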