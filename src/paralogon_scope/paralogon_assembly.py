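"""Assemble paralogon members from chromosomal segments and ohnolog calls.

Two graphs over segments are maintained:

* the *paralogy* graph (within a species): an edge between two segments
  counts the families with a tetraploidization-derived ohnolog pair split
  across them.  Connected components here are whole paralogons — the
  evidence that the regions descend from one pre-duplication region.
* the *orthology* graph (the separately stored cross-links): an edge counts
  the families whose genes on the two segments belong to the same ohnolog
  group, i.e. descend from the same post-WGD copy.  Connected components
  over orthology edges with at least `min_shared_families` shared families
  are the paralogon *members*; a member whose segments sit on different
  chromosomes of one species is flagged as split by translocation.

A single shared family is treated as insufficient evidence by default
(`min_shared_families=2`): one gene in common is compatible with chance or
with single-gene transposition, whereas the argument for common descent
rests on multiple co-localized families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .genome_io import GeneRecord, Segment
from .wgd_timing import EVENT_1R2R, EVENT_3R, OhnologGroup

DEFAULT_MIN_SHARED_FAMILIES = 2


@dataclass
class SegmentGraph:
    """Paralogy (within-species ohnolog splits) and orthology (same-copy
    cross-links) graphs over segments, keyed by Segment.key."""

    paralogy: nx.Graph
    orthology: nx.Graph
    segments: dict[tuple, Segment]


@dataclass
class ParalogonMember:
    """The segments (across species) descending from one post-WGD copy."""

    label: str
    segments: list[Segment]
    translocation_split: set[str] = field(default_factory=set)  # species
    flags: list[str] = field(default_factory=list)

    @property
    def species(self) -> set[str]:
        return {s.species for s in self.segments}


def build_segment_graph(
    segments: list[Segment],
    records: list[GeneRecord],
    ohnolog_groups_by_family: dict[str, list[OhnologGroup]],
    pair_classes_by_family: dict[str, dict[frozenset[str], str]],
    species_generation: dict[str, frozenset] | None = None,
) -> SegmentGraph:
    """Edges between segments from ohnolog relationships.

    Paralogy edge weight (same species): number of distinct families with a
    1R2R/3R-classified ohnolog pair split across the two segments.  Locally
    duplicated (lineage-specific) pairs contribute nothing.  Orthology edge
    weight: number of distinct families with same-ohnolog-group genes on both
    segments.

    `species_generation` maps each species to the set of WGD rounds on its
    lineage.  A paralogon member is a post-WGD chromosome copy of one ploidy
    generation, so orthology links are only drawn between species of the same
    generation: a pre-3R chromosome is the *parent* of two teleost members,
    not a member of the teleost octet.
    """
    by_id = {r.gene_id: r for r in records}
    seg_of_gene: dict[str, tuple] = {}
    segmap: dict[tuple, Segment] = {}
    for seg in segments:
        segmap[seg.key] = seg
        for gid in seg.gene_ids:
            seg_of_gene[gid] = seg.key

    group_of_gene: dict[str, tuple[str, int]] = {}
    for fam, groups in ohnolog_groups_by_family.items():
        for gi, grp in enumerate(groups):
            for gid in grp.genes:
                group_of_gene[gid] = (fam, gi)

    paralogy = nx.Graph()
    orthology = nx.Graph()
    paralogy.add_nodes_from(segmap)
    orthology.add_nodes_from(segmap)

    para_fams: dict[tuple, set[str]] = {}
    orth_fams: dict[tuple, set[str]] = {}
    genes = [g for g in seg_of_gene if g in group_of_gene]
    for i, g1 in enumerate(genes):
        fam1, grp1 = group_of_gene[g1]
        for g2 in genes[i + 1 :]:
            fam2, grp2 = group_of_gene[g2]
            if fam1 != fam2:
                continue
            k1, k2 = seg_of_gene[g1], seg_of_gene[g2]
            if k1 == k2:
                continue
            edge = (min(k1, k2), max(k1, k2))
            sp1, sp2 = by_id[g1].species, by_id[g2].species
            same_species = sp1 == sp2
            same_generation = (
                species_generation is None
                or species_generation.get(sp1) == species_generation.get(sp2)
            )
            if grp1 == grp2:
                if same_generation:
                    orth_fams.setdefault(edge, set()).add(fam1)
            elif same_species:
                cls = pair_classes_by_family.get(fam1, {}).get(frozenset((g1, g2)))
                if cls in (EVENT_1R2R, EVENT_3R):
                    para_fams.setdefault(edge, set()).add(fam1)
    for (k1, k2), fams in para_fams.items():
        paralogy.add_edge(k1, k2, weight=len(fams), families=sorted(fams))
    for (k1, k2), fams in orth_fams.items():
        orthology.add_edge(k1, k2, weight=len(fams), families=sorted(fams))
    return SegmentGraph(paralogy=paralogy, orthology=orthology, segments=segmap)


def assign_members(
    graph: SegmentGraph,
    min_shared_families: int = DEFAULT_MIN_SHARED_FAMILIES,
    ohnolog_groups_by_family: dict[str, list[OhnologGroup]] | None = None,
    max_members: dict[str, int] | None = None,
) -> list[ParalogonMember]:
    """Connected components of the orthology graph (edges with weight >=
    `min_shared_families`) become members; segments with no strong link each
    form their own (flagged) member.

    Raising the threshold can only refine the partition, never merge it.
    `max_members` maps species -> allowed copies (e.g. 4 without the teleost
    round, 8 with); exceeding it emits an over-retention warning.
    """
    if min_shared_families < 1:
        raise ValueError("min_shared_families must be >= 1")
    strong = nx.Graph()
    strong.add_nodes_from(graph.orthology.nodes)
    for u, v, data in graph.orthology.edges(data=True):
        if data["weight"] >= min_shared_families:
            strong.add_edge(u, v)

    comps = sorted(nx.connected_components(strong), key=lambda c: sorted(c)[0])
    members: list[ParalogonMember] = []
    for idx, comp in enumerate(comps):
        segs = sorted(
            (graph.segments[k] for k in comp),
            key=lambda s: (s.species, s.chrom, s.start),
        )
        chroms_per_species: dict[str, set[str]] = {}
        for s in segs:
            chroms_per_species.setdefault(s.species, set()).add(s.chrom)
        split = {sp for sp, ch in chroms_per_species.items() if len(ch) > 1}
        member = ParalogonMember(
            label=f"M{idx + 1}", segments=segs, translocation_split=split
        )
        if len(comp) == 1 and graph.orthology.degree(next(iter(comp))) == 0:
            member.flags.append("unlinked")
        members.append(member)

    if ohnolog_groups_by_family and max_members:
        member_of_seg = {
            s.key: m.label for m in members for s in m.segments
        }
        gene_to_seg = {
            gid: k for k, seg in graph.segments.items() for gid in seg.gene_ids
        }
        for fam, groups in ohnolog_groups_by_family.items():
            per_species: dict[str, set[str]] = {}
            for grp in groups:
                for gid in grp.genes:
                    k = gene_to_seg.get(gid)
                    if k is None:
                        continue
                    seg = graph.segments[k]
                    per_species.setdefault(seg.species, set()).add(
                        member_of_seg.get(k, k)
                    )
            for sp, mem in per_species.items():
                allowed = max_members.get(sp)
                if allowed is not None and len(mem) > allowed:
                    warnings.warn(
                        f"family {fam}: {len(mem)} members in {sp} exceeds the "
                        f"{allowed} copies the tetraploidizations allow "
                        "(over-retention)",
                        stacklevel=2,
                    )
    return members


def member_table(
    members: list[ParalogonMember],
    families: list[str],
    records: list[GeneRecord],
    incomplete_fraction: float = 0.5,
) -> pd.DataFrame:
    """Presence/loss matrix: rows = families, columns = (member, species),
    cells = gene ids, "x" for ohnolog loss / not-identified, and a trailing
    "(incomplete)" marker for sequences shorter than `incomplete_fraction`
    of the family's longest protein."""
    by_id = {r.gene_id: r for r in records}
    fam_max_len: dict[str, int] = {}
    for r in records:
        if r.family_id:
            fam_max_len[r.family_id] = max(
                fam_max_len.get(r.family_id, 0), len(r.protein)
            )
    columns = []
    data: dict[tuple[str, str], dict[str, str]] = {}
    for m in members:
        for sp in sorted(m.species):
            col = (m.label, sp)
            columns.append(col)
            cell: dict[str, str] = {}
            for seg in m.segments:
                if seg.species != sp:
                    continue
                for gid in seg.gene_ids:
                    rec = by_id[gid]
                    if rec.family_id not in families:
                        continue
                    txt = gid
                    if len(rec.protein) < incomplete_fraction * fam_max_len.get(
                        rec.family_id, 0
                    ):
                        txt += " (incomplete)"
                    cell[rec.family_id] = (
                        cell.get(rec.family_id, "") + ("," if rec.family_id in cell else "") + txt
                    )
            data[col] = cell
    table = pd.DataFrame(
        {col: [data[col].get(f, "x") for f in families] for col in columns},
        index=pd.Index(families, name="family_id"),
    )
    table.columns = pd.MultiIndex.from_tuples(columns, names=["member", "species"])
    return table


def render_member_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of the member table (one block per member)."""
    lines: list[str] = []
    for member in table.columns.get_level_values(0).unique():
        sub = table[member]
        lines.append(f"== member {member} ==")
        lines.append(sub.to_string())
        lines.append("")
    return "\n".join(lines)


def write_graphml(graph: SegmentGraph, path) -> None:
    g = nx.Graph()
    for k in graph.segments:
        g.add_node("|".join(map(str, k)))
    for u, v, d in graph.paralogy.edges(data=True):
        g.add_edge(
            "|".join(map(str, u)), "|".join(map(str, v)),
            weight=d["weight"], kind="paralogy", families=",".join(d["families"]),
        )
    for u, v, d in graph.orthology.edges(data=True):
        key = ("|".join(map(str, u)), "|".join(map(str, v)))
        if g.has_edge(*key):
            g[key[0]][key[1]]["kind"] = "both"
        else:
            g.add_edge(*key, weight=d["weight"], kind="orthology",
                       families=",".join(d["families"]))
    nx.write_graphml(g, path)
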