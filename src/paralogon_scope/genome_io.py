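"""Gene-model I/O and neighbourhood windows.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the boundary.  Exons are stored in translation order (ascending
on '+', descending on '-').  Genes on scaffolds (chromosome name containing
"scaffold", case-insensitive) are retained and flagged; they may join
segments but never anchor a neighbourhood window.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO


class GFF3ParseError(ValueError):
    pass


@dataclass
class GeneRecord:
    """One protein-coding gene model."""

    gene_id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    family_id: str | None
    exons: list[tuple[int, int]]
    protein: str
    flags: set[str] = field(default_factory=set)

    @property
    def on_scaffold(self) -> bool:
        return "scaffold" in self.chrom.lower()

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def validate(self) -> list[str]:
        """Invariant check; returns human-readable issues (empty = valid)."""
        issues: list[str] = []
        if not (0 <= self.start < self.end):
            issues.append(f"{self.gene_id}: bad span [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            issues.append(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                issues.append(f"{self.gene_id}: exon [{s},{e}) outside gene span")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if e1 > s2:
                issues.append(f"{self.gene_id}: overlapping exons")
                break
        expect = ordered if self.strand == "+" else ordered[::-1]
        if self.exons != expect:
            issues.append(f"{self.gene_id}: exons not in translation order")
        if self.cds_length % 3 != 0:
            issues.append(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")
        elif self.protein and self.cds_length // 3 not in (
            len(self.protein),
            len(self.protein) + 1,  # CDS may include the stop codon
        ):
            issues.append(
                f"{self.gene_id}: CDS codons {self.cds_length // 3} != protein length "
                f"{len(self.protein)}"
            )
        return issues


@dataclass
class Segment:
    """A chromosomal interval and the genes it contains."""

    species: str
    chrom: str
    start: int
    end: int
    gene_ids: list[str]

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.species, self.chrom, self.start, self.end)


@dataclass
class FamilyCensus:
    """family_id -> species -> gene count over a set of segments."""

    counts: dict[str, dict[str, int]]

    def count(self, family_id: str, species: str) -> int:
        return self.counts.get(family_id, {}).get(species, 0)

    def total(self, family_id: str) -> int:
        return sum(self.counts.get(family_id, {}).values())


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _prescan_gff3(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GFF3ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(parts)}"
                )
            try:
                s, e = int(parts[3]), int(parts[4])
            except ValueError:
                raise GFF3ParseError(
                    f"{path}:{lineno}: non-integer coordinates {parts[3]!r}/{parts[4]!r}"
                ) from None
            if s < 1 or e < s:
                raise GFF3ParseError(f"{path}:{lineno}: bad interval {s}..{e}")


def read_family_map(path: str | Path) -> dict[str, str]:
    """TSV with header ``gene_id<TAB>family_id``."""
    out: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["gene_id", "family_id"]:
            raise ValueError(f"{path}: expected header gene_id<TAB>family_id")
        for row in reader:
            if not row:
                continue
            out[row[0]] = row[1]
    return out


def read_gene_models(
    gff3_path: str | Path,
    fasta_path: str | Path,
    family_map: dict[str, str] | str | Path,
    species: str,
) -> tuple[list[GeneRecord], list[str]]:
    """Read GFF3 gene/mRNA/CDS features plus a protein FASTA and a gene-family
    map into validated GeneRecords.

    Returns (records, issues).  Genes failing invariants are kept and their
    problems reported in `issues`; genes without a family mapping are kept
    with ``family_id=None`` and the ``unknown_family`` flag.
    """
    _prescan_gff3(gff3_path)
    if not isinstance(family_map, dict):
        family_map = read_family_map(family_map)
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    try:
        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return [], []
    records: list[GeneRecord] = []
    issues: list[str] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = gene.id
        cds = []
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            break
        if not cds:
            cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        exons = [(c.start - 1, c.end) for c in cds]
        if gene.strand == "-":
            exons = exons[::-1]
        protein = proteins.get(gid, "")
        if not protein:
            issues.append(f"{gid}: no protein sequence in {fasta_path}")
        rec = GeneRecord(
            gene_id=gid,
            species=species,
            chrom=gene.seqid,
            start=gene.start - 1,
            end=gene.end,
            strand=gene.strand,
            family_id=family_map.get(gid),
            exons=exons,
            protein=protein,
        )
        if rec.family_id is None:
            rec.flags.add("unknown_family")
        if rec.on_scaffold:
            rec.flags.add("scaffold")
        problems = rec.validate()
        if any("divisible by 3" in p for p in problems):
            rec.flags.add("cds_length_warning")
        issues.extend(problems)
        records.append(rec)
    return records, issues


def write_gene_models(
    records: list[GeneRecord],
    gff3_path: str | Path,
    fasta_path: str | Path,
    family_path: str | Path | None = None,
) -> None:
    """Write records as GFF3 (gene/mRNA/CDS) + protein FASTA (+ family TSV)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.gene_id))
    with open(gff3_path, "w") as out:
        out.write("##gff-version 3\n")
        for r in recs:
            base = [r.chrom, "paralogon_scope"]
            out.write(
                "\t".join(
                    base + ["gene", str(r.start + 1), str(r.end), ".", r.strand, ".",
                            f"ID={r.gene_id}"]
                )
                + "\n"
            )
            mid = f"{r.gene_id}.t1"
            out.write(
                "\t".join(
                    base + ["mRNA", str(r.start + 1), str(r.end), ".", r.strand, ".",
                            f"ID={mid};Parent={r.gene_id}"]
                )
                + "\n"
            )
            cum = 0
            rows = []
            for i, (s, e) in enumerate(r.exons):
                phase = (3 - cum % 3) % 3
                rows.append(
                    base
                    + ["CDS", str(s + 1), str(e), ".", r.strand, str(phase),
                       f"ID={r.gene_id}.cds{i};Parent={mid}"]
                )
                cum += e - s
            for row in sorted(rows, key=lambda x: int(x[3])):
                out.write("\t".join(row) + "\n")
    with open(fasta_path, "w") as out:
        for r in recs:
            out.write(f">{r.gene_id}\n{r.protein}\n")
    if family_path is not None:
        with open(family_path, "w") as out:
            out.write("gene_id\tfamily_id\n")
            for r in recs:
                out.write(f"{r.gene_id}\t{r.family_id or ''}\n")


# ---------------------------------------------------------------------------
# windows & censuses
# ---------------------------------------------------------------------------

DEFAULT_FLANK_BP = 10_000_000


def extract_window(
    records: list[GeneRecord], focal_gene_id: str, flank_bp: int = DEFAULT_FLANK_BP
) -> Segment:
    """All genes on the focal gene's chromosome overlapping
    [focal.start - flank, focal.end + flank), clipped at 0."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    by_id = {r.gene_id: r for r in records}
    if focal_gene_id not in by_id:
        raise KeyError(f"focal gene {focal_gene_id!r} not found")
    focal = by_id[focal_gene_id]
    if focal.on_scaffold:
        raise ValueError(
            f"focal gene {focal_gene_id!r} is on a scaffold and cannot anchor a window"
        )
    lo = max(0, focal.start - flank_bp)
    hi = focal.end + flank_bp
    hits = [
        r
        for r in records
        if r.species == focal.species
        and r.chrom == focal.chrom
        and r.start < hi
        and r.end > lo
    ]
    hits.sort(key=lambda r: (r.start, r.gene_id))
    return Segment(
        species=focal.species,
        chrom=focal.chrom,
        start=lo,
        end=hi,
        gene_ids=[r.gene_id for r in hits],
    )


def family_census(
    segments: list[Segment],
    records: list[GeneRecord],
    min_members: int,
    reference_species: str | None = None,
) -> tuple[list[str], FamilyCensus]:
    """Census neighbour families over segments; select the families with at
    least `min_members` members in the reference species' segments.

    Genes without a family assignment stay in segments but are never counted.
    Selection is sorted lexicographically.
    """
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    by_id = {r.gene_id: r for r in records}
    counts: dict[str, dict[str, int]] = {}
    for seg in segments:
        for gid in seg.gene_ids:
            rec = by_id[gid]
            if rec.family_id is None:
                continue
            fam = counts.setdefault(rec.family_id, {})
            fam[rec.species] = fam.get(rec.species, 0) + 1
    if reference_species is None:
        if not segments:
            return [], FamilyCensus({})
        reference_species = segments[0].species
    selected = sorted(
        f for f, per in counts.items() if per.get(reference_species, 0) >= min_members
    )
    return selected, FamilyCensus(counts)
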