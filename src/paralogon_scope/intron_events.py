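"""Intron positions, phases, cross-species matching, and Dollo gains.

An intron interrupting a coding sequence after L nucleotides has phase
L mod 3 (0: between codons; 1 or 2: inside a codon) and maps to protein
residue floor(L / 3) — the codon interrupted, or the first codon after a
phase-0 boundary.  Residues are projected onto alignment columns through the
gene's row of the protein MSA, so intron positions become comparable across
genes and species.  Two positions are the same *site* iff they occupy the
same alignment column with the same phase (an optional ±1-column tolerance
exists but is off by default).

Gains are reconstructed by Dollo parsimony on the species tree: each site is
gained exactly once, on the branch above the MRCA of the species carrying it,
and lost on the minimal set of branches explaining the absences.  Uncertain
states constrain nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
from Bio.Seq import Seq

from .genome_io import GeneRecord
from .msa_identity import MSA
from .wgd_timing import SpeciesTree

PRESENT = "present"
ABSENT = "absent"
UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class IntronPosition:
    """A coding intron projected onto a protein alignment."""

    gene_id: str
    column: int
    phase: int
    residue_index: int
    donor_coordinate: int

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0/1/2, got {self.phase}")


@dataclass
class IntronSite:
    """A cluster of identical (column, phase) intron positions."""

    site_id: str
    column: int
    phase: int
    positions: list[IntronPosition]

    @property
    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.positions]


def map_intron_positions(
    gene: GeneRecord, msa: MSA, seq_id: str | None = None
) -> list[IntronPosition]:
    """One IntronPosition per internal exon boundary of `gene`.

    Phase = cumulative CDS length at the boundary mod 3; the residue index
    floor(cum/3) is mapped to its alignment column through the MSA row.
    Single-exon genes yield an empty list.
    """
    seq_id = seq_id or gene.gene_id
    if msa.degapped(seq_id) != gene.protein:
        raise ValueError(f"MSA row {seq_id} does not match protein of {gene.gene_id}")
    out: list[IntronPosition] = []
    cum = 0
    n_prot = len(gene.protein)
    for k, (s, e) in enumerate(gene.exons[:-1]):
        cum += e - s
        phase = cum % 3
        residue = cum // 3
        if residue >= n_prot:
            raise ValueError(
                f"{gene.gene_id}: exon boundary at {cum} nt beyond protein "
                f"({n_prot} aa); exon structure inconsistent with CDS"
            )
        # donor = genomic coordinate of the first intron base, strand-aware
        if gene.strand == "+":
            donor = e
        else:
            donor = s - 1
        out.append(
            IntronPosition(
                gene_id=gene.gene_id,
                column=msa.column_of(seq_id, residue),
                phase=phase,
                residue_index=residue,
                donor_coordinate=donor,
            )
        )
    return out


def match_positions(
    positions: list[IntronPosition], column_tolerance: int = 0
) -> list[IntronSite]:
    """Cluster intron positions into sites.

    Exact (column, phase) identity by default.  With ``column_tolerance=1``
    positions within one column (same phase) join the same site; phases never
    mix.
    """
    sites: list[IntronSite] = []
    for pos in sorted(positions, key=lambda p: (p.column, p.phase, p.gene_id)):
        placed = False
        for site in sites:
            if site.phase == pos.phase and abs(site.column - pos.column) <= column_tolerance:
                if column_tolerance == 0 and site.column != pos.column:
                    continue
                site.positions.append(pos)
                placed = True
                break
        if not placed:
            sites.append(
                IntronSite(
                    site_id=f"s{len(sites)}@c{pos.column}p{pos.phase}",
                    column=pos.column,
                    phase=pos.phase,
                    positions=[pos],
                )
            )
    return sites


@dataclass
class DolloReconstruction:
    gain_branch: str
    loss_branches: list[str]


def dollo_gains(
    states: dict[str, str], species_tree: SpeciesTree
) -> DolloReconstruction:
    """Dollo parsimony for one intron site.

    `states` maps species -> present/absent/uncertain; species missing from
    the map (e.g. the gene itself is gone) are unconstrained, like uncertain.
    The gain lands on the branch above the MRCA of present species; losses are
    the minimal branch set under it whose subtrees contain an absence and no
    presence.  Branches are reported as the label of the node below them.
    """
    present = {s for s, st in states.items() if st == PRESENT}
    absent = {s for s, st in states.items() if st == ABSENT}
    if not present:
        raise ValueError("Dollo needs at least one species with the intron present")
    unknown = (present | absent) - set(species_tree.species)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")

    gain_node = species_tree.mrca(present)
    losses: list[str] = []

    def has_present(nd: dendropy.Node) -> bool:
        return bool(species_tree.leafset(nd) & present)

    def has_absent(nd: dendropy.Node) -> bool:
        return bool(species_tree.leafset(nd) & absent)

    stack = [gain_node]
    while stack:
        nd = stack.pop()
        for ch in sorted(nd.child_nodes(), key=species_tree.node_label):
            if has_present(ch):
                stack.append(ch)
            elif has_absent(ch):
                losses.append(species_tree.node_label(ch))
            # subtrees with neither presence nor absence are unconstrained
    return DolloReconstruction(
        gain_branch=species_tree.node_label(gain_node),
        loss_branches=sorted(losses),
    )


def splice_site_check(
    gene: GeneRecord, span_seq: str, span_offset: int | None = None
) -> list[bool]:
    """Check each intron for the canonical GT..AG donor/acceptor consensus.

    `span_seq` is the forward-strand genomic sequence covering the gene span;
    `span_offset` is its genomic start (defaults to gene.start).  Minus-strand
    genes are checked on the reverse complement.  Non-consensus introns yield
    False (flagged, not rejected).
    """
    offset = gene.start if span_offset is None else span_offset
    if gene.start < offset or gene.end > offset + len(span_seq):
        raise ValueError(f"{gene.gene_id}: span sequence does not cover the gene")
    exons = sorted(gene.exons)
    results: list[bool] = []
    introns = [
        (e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])
    ]
    if gene.strand == "-":
        introns = introns[::-1]
    for s, e in introns:
        seq = span_seq[s - offset : e - offset].upper()
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        results.append(seq[:2] == "GT" and seq[-2:] == "AG")
    return results


def presence_states(
    site: IntronSite,
    group_genes: dict[str, str],
    uncertain_genes: set[str] | None = None,
) -> dict[str, str]:
    """Species states for one site within one ohnolog group.

    `group_genes` maps gene_id -> species for the genes of the group; genes in
    `uncertain_genes` (e.g. incomplete models) give `uncertain`, carriers give
    `present`, the rest `absent`.  Species without a gene are simply omitted.
    """
    uncertain_genes = uncertain_genes or set()
    carriers = set(site.gene_ids)
    states: dict[str, str] = {}
    for gid, sp in group_genes.items():
        if gid in carriers:
            states[sp] = PRESENT
        elif gid in uncertain_genes:
            states.setdefault(sp, UNCERTAIN)
        else:
            states.setdefault(sp, ABSENT)
    return states
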