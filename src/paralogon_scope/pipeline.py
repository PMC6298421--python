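"""End-to-end orchestration: windows -> alignments -> trees -> duplication
timing -> paralogon members -> intron gains, with optional truth-based
scoring when the input came from the simulator.

The pipeline is a pure function of (inputs, config, seed): every stage
writes its table under the output directory and the summary report is
byte-reproducible at a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_io, gene_trees, intron_events, msa_identity, paralogon_assembly
from . import wgd_timing
from .synthetic_genome import SimDataset
from .wgd_timing import SpeciesTree


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults follow the study design they emulate
    (10 Mb windows, 100 bootstrap replicates, neighbour threshold 2)."""

    flank_bp: int = 10_000_000
    min_members: int = 2
    n_bootstrap: int = 100
    support_threshold: float = 50.0
    min_tree_support: float = 50.0
    max_family_size: int = 12
    min_shared_families: int = 2
    segment_gap_bp: int = 10_000_000
    tandem_bp: int = 100_000
    reconcile_nni: bool = True
    nni_max_edge_length: float = 0.02
    d_max: float = 5.0
    mask_region_for_trees: str | None = "IL3"
    intron_column_tolerance: int = 0
    reference_species: str = "gar"
    outgroup_species: str = "lancelet"
    focal_family: str = "fam06"
    #: explicit family list (the real-data workflow's curated selection);
    #: overrides the window census when set.
    families: list[str] | None = None


@dataclass
class RunReport:
    seed: int
    config: PipelineConfig
    gene_counts: pd.DataFrame
    duplication_scheme: pd.DataFrame
    calls: list[dict]
    members: list[paralogon_assembly.ParalogonMember]
    member_assignment: pd.DataFrame
    member_table: pd.DataFrame
    intron_map: pd.DataFrame
    identity_table: pd.DataFrame
    families_analyzed: list[str]
    families_skipped: dict[str, str]
    log: list[str] = field(default_factory=list)
    metrics: dict | None = None

    def summary_dict(self) -> dict:
        return {
            "seed": self.seed,
            "families_analyzed": self.families_analyzed,
            "families_skipped": self.families_skipped,
            "n_calls": len(self.calls),
            "calls": sorted(
                (
                    {
                        "family": c["family"],
                        "class": c["class"],
                        "branch": c["branch"],
                        "left": sorted(c["left_genes"]),
                        "right": sorted(c["right_genes"]),
                        "weak": c["weak"],
                    }
                    for c in self.calls
                ),
                key=lambda c: (c["family"], c["left"], c["right"]),
            ),
            "n_members": len(self.members),
            "member_sizes": sorted(
                (m.label, len(m.segments)) for m in self.members
            ),
            "intron_sites": sorted(
                self.intron_map[["family_id", "residue", "phase", "gain_branch"]]
                .astype(str)
                .agg("|".join, axis=1)
                .tolist()
            )
            if len(self.intron_map)
            else [],
            "identity": {
                k: round(v, 6)
                for k, v in self.identity_table.set_index("comparison")[
                    "percent_identity"
                ].items()
            }
            if len(self.identity_table)
            else {},
            "metrics": self.metrics,
        }

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
        self.duplication_scheme.to_csv(
            out / "duplication_scheme.tsv", sep="\t", index=False
        )
        self.member_assignment.to_csv(out / "member_assignment.tsv", sep="\t", index=False)
        self.member_table.to_csv(out / "member_table.tsv", sep="\t")
        (out / "member_table.txt").write_text(
            paralogon_assembly.render_member_table(self.member_table)
            if len(self.member_table)
            else "(no members)\n"
        )
        self.intron_map.to_csv(out / "intron_map.tsv", sep="\t", index=False)
        self.identity_table.to_csv(out / "identity.tsv", sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(self.summary_dict(), indent=2, sort_keys=True) + "\n"
        )
        (out / "run.log").write_text("\n".join(self.log) + "\n")
        return out / "report.json"


def _pick_reference_gene(fam_records: list[genome_io.GeneRecord], species: str):
    cands = sorted(
        (r for r in fam_records if r.species == species and not r.on_scaffold),
        key=lambda r: r.gene_id,
    )
    return cands[0] if cands else None


def _segments_from_records(
    records: list[genome_io.GeneRecord],
    families: list[str],
    gap_bp: int,
    exclude_species: set[str],
) -> list[genome_io.Segment]:
    """Cluster the analyzed families' genes into segments per chromosome,
    splitting where consecutive genes are further apart than gap_bp."""
    segs: list[genome_io.Segment] = []
    pool = [
        r
        for r in records
        if r.family_id in families and r.species not in exclude_species
    ]
    by_chrom: dict[tuple[str, str], list[genome_io.GeneRecord]] = {}
    for r in pool:
        by_chrom.setdefault((r.species, r.chrom), []).append(r)
    for (sp, chrom), recs in sorted(by_chrom.items()):
        recs.sort(key=lambda r: (r.start, r.gene_id))
        run: list[genome_io.GeneRecord] = []
        for r in recs:
            if run and r.start - run[-1].end > gap_bp:
                segs.append(
                    genome_io.Segment(
                        sp, chrom, run[0].start, run[-1].end, [x.gene_id for x in run]
                    )
                )
                run = []
            run.append(r)
        if run:
            segs.append(
                genome_io.Segment(
                    sp, chrom, run[0].start, run[-1].end, [x.gene_id for x in run]
                )
            )
    return segs


def _masked_msa(msa: msa_identity.MSA, mask: msa_identity.RegionMask) -> msa_identity.MSA:
    keep = mask.columns
    rows = ["".join(r[c] for c in keep) for r in msa.rows]
    return msa_identity.MSA(list(msa.ids), rows)


def run_all(
    source: SimDataset | str | Path,
    outdir: str | Path,
    seed: int,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run every stage on a dataset (simulator output or exported directory)."""
    cfg = config or PipelineConfig()
    log: list[str] = [f"seed={seed}", f"config={dataclasses.asdict(cfg)}"]
    if isinstance(source, SimDataset):
        records = source.records
        spans = source.span_seqs
        regions = source.regions
        newick = source.species_tree_newick
    else:
        records, spans, regions, newick, _ = __import__(
            "paralogon_scope.synthetic_genome", fromlist=["load_dataset"]
        ).load_dataset(source)
    species_tree = SpeciesTree.from_newick(newick)
    by_id = {r.gene_id: r for r in records}
    species = sorted({r.species for r in records})
    outgroup = cfg.outgroup_species

    # ---- stage 1: windows and neighbour-family census ---------------------
    ref_species = cfg.reference_species
    focal = [
        r
        for r in records
        if r.family_id == cfg.focal_family and r.species == ref_species
        and not r.on_scaffold
    ]
    if not focal:
        for sp in species:
            if sp in (outgroup,):
                continue
            focal = [
                r
                for r in records
                if r.family_id == cfg.focal_family and r.species == sp
                and not r.on_scaffold
            ]
            if focal:
                ref_species = sp
                log.append(
                    f"focal family absent in {cfg.reference_species}; "
                    f"anchoring windows on {sp}"
                )
                break
    ref_records = [r for r in records if r.species == ref_species]
    windows = [
        genome_io.extract_window(ref_records, r.gene_id, cfg.flank_bp) for r in focal
    ]
    selected, census = genome_io.family_census(
        windows, ref_records, cfg.min_members, reference_species=ref_species
    )
    if cfg.focal_family not in selected and focal:
        selected = sorted(selected + [cfg.focal_family])
    if cfg.families is not None:
        selected = sorted(cfg.families)
        log.append(f"explicit family list: {selected}")
    log.append(f"windows={len(windows)} selected_families={selected}")

    # ---- stage 2: per-family alignments, trees, duplication calls ---------
    families_analyzed: list[str] = []
    families_skipped: dict[str, str] = {}
    family_results: dict = {}
    family_msas: dict[str, msa_identity.MSA] = {}
    calls_out: list[dict] = []
    groups_by_family: dict[str, list] = {}
    pairs_by_family: dict[str, dict] = {}

    for fi, fam in enumerate(selected):
        fam_records = sorted(
            (r for r in records if r.family_id == fam), key=lambda r: r.gene_id
        )
        per_species_max = max(
            sum(1 for r in fam_records if r.species == sp) for sp in species
        )
        if per_species_max > cfg.max_family_size:
            families_skipped[fam] = (
                f"family size {per_species_max} exceeds max {cfg.max_family_size}"
            )
            continue
        ingroup = [r for r in fam_records if r.species != outgroup]
        if len(ingroup) < 3:
            families_skipped[fam] = f"only {len(ingroup)} ingroup genes"
            continue
        msa = msa_identity.build_msa({r.gene_id: r.protein for r in fam_records})
        family_msas[fam] = msa

        tree_msa = msa
        if cfg.mask_region_for_trees and cfg.mask_region_for_trees in regions:
            ref_gene = _pick_reference_gene(fam_records, ref_species) or fam_records[0]
            mask = msa_identity.mask_from_regions(
                msa,
                ref_gene.gene_id,
                {cfg.mask_region_for_trees: regions[cfg.mask_region_for_trees]},
                mode="exclude",
            )
            tree_msa = _masked_msa(msa, mask)
        boot_seed = (seed * 9973 + fi * 271 + 17) % (2**31)
        tree = gene_trees.bootstrap_support(
            tree_msa, n_replicates=cfg.n_bootstrap, seed=boot_seed, d_max=cfg.d_max
        )
        supports = [
            float(nd.label)
            for nd in tree.preorder_node_iter()
            if nd.label is not None and not nd.is_leaf()
        ]
        og_leaves = [r.gene_id for r in fam_records if r.species == outgroup]
        if og_leaves and len(og_leaves) < len(fam_records):
            tree = gene_trees.root_at_outgroup(tree, og_leaves)
        else:
            tree.reroot_at_midpoint(update_bipartitions=False)
            tree.is_rooted = True
            log.append(f"{fam}: no outgroup sequence; midpoint-rooted")
        mean_support = float(np.mean(supports)) if supports else 100.0
        if mean_support < cfg.min_tree_support:
            families_skipped[fam] = (
                f"mean bootstrap {mean_support:.0f} below {cfg.min_tree_support:.0f}"
            )
            continue
        leaf_species = {r.gene_id: r.species for r in fam_records}
        if cfg.reconcile_nni:
            n_moves = wgd_timing.reconcile_nni(
                tree, species_tree, leaf_species,
                max_edge_length=cfg.nni_max_edge_length,
            )
            if n_moves:
                log.append(f"{fam}: {n_moves} reconciliation NNI move(s)")
        calls = wgd_timing.classify_tree(
            tree,
            species_tree,
            leaf_species,
            family_id=fam,
            support_threshold=cfg.support_threshold,
        )
        positions = {
            r.gene_id: (r.species, r.chrom, r.start) for r in fam_records
        }
        reclassified = wgd_timing.reclassify_tandem_duplications(
            tree, positions, tandem_bp=cfg.tandem_bp
        )
        if reclassified:
            log.append(f"{fam}: {len(reclassified)} tandem duplication(s) reclassified")
        groups = wgd_timing.ohnolog_groups(tree, leaf_species, fam)
        pairs = wgd_timing.ohnolog_pair_classes(tree)
        families_analyzed.append(fam)
        family_results[fam] = (tree, calls, groups)
        groups_by_family[fam] = [g for g in groups if g.species != {outgroup}]
        pairs_by_family[fam] = pairs
        for nd in tree.preorder_node_iter():
            call = getattr(nd, "call", None)
            if call is None:
                continue
            ch = nd.child_nodes()
            calls_out.append(
                {
                    "family": fam,
                    "class": call.event_class,
                    "branch": call.mapped_branch,
                    "left_genes": [l.taxon.label for l in ch[0].leaf_iter()],
                    "right_genes": [l.taxon.label for l in ch[1].leaf_iter()],
                    "support": call.support,
                    "weak": call.weak,
                }
            )

    scheme = (
        wgd_timing.build_duplication_scheme(family_results, species_tree)
        if family_results
        else pd.DataFrame()
    )

    # ---- stage 3: identity of the focal family ----------------------------
    identity_rows = []
    if cfg.focal_family in family_msas:
        msa = family_msas[cfg.focal_family]
        fam_records = [r for r in records if r.family_id == cfg.focal_family]
        ref_gene = _pick_reference_gene(fam_records, ref_species)
        if ref_gene is not None:
            tm_ranges = {n: r for n, r in regions.items() if n.startswith("TM")}
            var = cfg.mask_region_for_trees or "IL3"
            for sp in species:
                if sp == ref_species:
                    continue
                other = _pick_reference_gene(fam_records, sp)
                if other is None:
                    continue
                pair = (ref_gene.gene_id, other.gene_id)
                full = msa_identity.percent_identity(msa, pair)
                tm = msa_identity.percent_identity(
                    msa,
                    pair,
                    msa_identity.mask_from_regions(
                        msa, ref_gene.gene_id, tm_ranges, "include"
                    ),
                )
                rows = [("full", full), ("TM", tm)]
                if var in regions:
                    novar = msa_identity.percent_identity(
                        msa,
                        pair,
                        msa_identity.mask_from_regions(
                            msa, ref_gene.gene_id, {var: regions[var]}, "exclude"
                        ),
                    )
                    rows.append((f"excl_{var}", novar))
                for kind, val in rows:
                    identity_rows.append(
                        {
                            "comparison": f"{ref_species}:{sp}:{kind}",
                            "gene_a": ref_gene.gene_id,
                            "gene_b": other.gene_id,
                            "region": kind,
                            "percent_identity": val,
                        }
                    )
    identity_table = pd.DataFrame(
        identity_rows,
        columns=["comparison", "gene_a", "gene_b", "region", "percent_identity"],
    )

    # ---- stage 4: paralogon members ---------------------------------------
    segments = _segments_from_records(
        records, families_analyzed, cfg.segment_gap_bp, exclude_species={outgroup}
    )
    generation: dict[str, frozenset] = {}
    for sp in species:
        leaf = species_tree.mrca({sp})
        evs: set[str] = set()
        nd = leaf
        while nd is not None:
            evs |= set(species_tree.events_above(nd))
            nd = nd.parent_node
        generation[sp] = frozenset(evs)
    graph = paralogon_assembly.build_segment_graph(
        segments, records, groups_by_family, pairs_by_family,
        species_generation=generation,
    )
    teleosts: set[str] = set()
    for nd, evs in species_tree.wgd.items():
        if "3R" in evs:
            teleosts |= set(species_tree.leafset(nd))
    max_members = {
        sp: (8 if sp in teleosts else 4) for sp in species if sp != outgroup
    }
    members = paralogon_assembly.assign_members(
        graph,
        min_shared_families=cfg.min_shared_families,
        ohnolog_groups_by_family=groups_by_family,
        max_members=max_members,
    )
    table = (
        paralogon_assembly.member_table(members, families_analyzed, records)
        if members
        else pd.DataFrame()
    )
    assign_rows = []
    for m in members:
        for seg in m.segments:
            for gid in seg.gene_ids:
                assign_rows.append(
                    {
                        "gene_id": gid,
                        "family_id": by_id[gid].family_id,
                        "species": seg.species,
                        "chrom": seg.chrom,
                        "member": m.label,
                        "translocation_split": seg.species in m.translocation_split,
                    }
                )
    member_assignment = pd.DataFrame(
        assign_rows,
        columns=[
            "gene_id", "family_id", "species", "chrom", "member",
            "translocation_split",
        ],
    ).sort_values("gene_id").reset_index(drop=True)

    # ---- stage 5: intron sites and Dollo gains ----------------------------
    intron_rows = []
    for fam in families_analyzed:
        msa = family_msas[fam]
        fam_records = [r for r in records if r.family_id == fam]
        positions = []
        for r in fam_records:
            if r.gene_id in msa.ids:
                positions.extend(intron_events.map_intron_positions(r, msa))
        if not positions:
            continue
        sites = intron_events.match_positions(
            positions, column_tolerance=cfg.intron_column_tolerance
        )
        for grp_i, grp in enumerate(groups_by_family[fam]):
            group_genes = {
                g: by_id[g].species for g in grp.genes if by_id[g].species != outgroup
            }
            if not group_genes:
                continue
            for site in sites:
                carriers = set(site.gene_ids) & set(group_genes)
                if not carriers:
                    continue
                states = intron_events.presence_states(site, group_genes)
                rec = intron_events.dollo_gains(states, species_tree)
                any_pos = min(
                    (p for p in site.positions if p.gene_id in carriers),
                    key=lambda p: p.gene_id,
                )
                intron_rows.append(
                    {
                        "family_id": fam,
                        "group": f"{fam}.g{grp_i}",
                        "site_id": site.site_id,
                        "column": site.column,
                        "residue": any_pos.residue_index,
                        "phase": site.phase,
                        "gain_branch": rec.gain_branch,
                        "loss_branches": ",".join(rec.loss_branches),
                        "genes": ",".join(sorted(carriers)),
                    }
                )
    intron_map = pd.DataFrame(
        intron_rows,
        columns=[
            "family_id", "group", "site_id", "column", "residue", "phase",
            "gain_branch", "loss_branches", "genes",
        ],
    )

    counts = (
        pd.crosstab(
            pd.Series([r.family_id for r in records], name="family_id"),
            pd.Series([r.species for r in records], name="species"),
        )
        if records
        else pd.DataFrame()
    )

    report = RunReport(
        seed=seed,
        config=cfg,
        gene_counts=counts,
        duplication_scheme=scheme,
        calls=calls_out,
        members=members,
        member_assignment=member_assignment,
        member_table=table,
        intron_map=intron_map,
        identity_table=identity_table,
        families_analyzed=families_analyzed,
        families_skipped=families_skipped,
        log=log,
    )
    if outdir is not None:
        report.write(outdir)
    return report


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------

def evaluate(report: RunReport, truth) -> dict:
    """Score a run against the simulator's ledger.

    * duplication-event classification accuracy: each inferred duplication
      is scored against the majority divergence event (per the ledger) of
      the gene pairs it separates — the true event this call corresponds to;
      a tie counts as wrong.  The stricter unanimous-pair rate is reported
      alongside as `strict_accuracy`;
    * paralogon-membership adjusted Rand index over genes (truth label:
      ancestral chromosome + WGD copy lineage);
    * intron-gain recovery: fraction of observable true gains (at least one
      extant carrier) recovered with the exact residue, phase and branch.
    """
    from sklearn.metrics import adjusted_rand_score

    known = set(truth.genes.index)

    confusion: dict[tuple[str, str], int] = {}
    n_correct = 0
    n_strict = 0
    for call in report.calls:
        votes: dict[str, int] = {}
        for g1 in call["left_genes"]:
            for g2 in call["right_genes"]:
                if g1 in known and g2 in known:
                    c = truth.divergence_class(g1, g2)
                    votes[c] = votes.get(c, 0) + 1
        if not votes:
            truth_cls = "unknown"
        else:
            top = max(votes.values())
            winners = [c for c, n in votes.items() if n == top]
            truth_cls = winners[0] if len(winners) == 1 else "tied"
        confusion[(truth_cls, call["class"])] = (
            confusion.get((truth_cls, call["class"]), 0) + 1
        )
        if truth_cls == call["class"]:
            n_correct += 1
            if len(votes) == 1:
                n_strict += 1
    accuracy = n_correct / len(report.calls) if report.calls else float("nan")
    strict = n_strict / len(report.calls) if report.calls else float("nan")

    ma = report.member_assignment
    ari = float("nan")
    if len(ma):
        genes = [g for g in ma.gene_id if g in known]
        pred = ma.set_index("gene_id").loc[genes, "member"].tolist()
        true_labels = [truth.membership_label(g) for g in genes]
        ari = float(adjusted_rand_score(true_labels, pred))

    observable = {
        gid: info
        for gid, info in truth.gains.items()
        if truth.genes.introns.str.contains(f"(?:^|;)\\d+:\\d+:{gid}(?:;|$)").any()
    }
    inferred = set()
    for _, row in report.intron_map.iterrows():
        inferred.add(
            (row.family_id, int(row.residue), int(row.phase), row.gain_branch)
        )
    n_rec = sum(
        1
        for info in observable.values()
        if (info["family"], info["residue"], info["phase"], info["branch"]) in inferred
    )
    recovery = n_rec / len(observable) if observable else float("nan")

    return {
        "event_classification_accuracy": accuracy,
        "strict_accuracy": strict,
        "n_calls": len(report.calls),
        "confusion": {f"{t}->{p}": n for (t, p), n in sorted(confusion.items())},
        "membership_ari": ari,
        "n_member_genes": int(len(ma)),
        "intron_gain_recovery": recovery,
        "n_observable_gains": len(observable),
    }
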