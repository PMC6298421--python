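"""Forward simulator of gene-neighbourhood evolution through tetraploidizations.

The simulator evolves an ancestral chromosome of linked single-gene families
down a species tree whose branches may carry whole-genome duplications (two
rounds on the vertebrate stem, one on the teleost stem in the default
scenario).  Each WGD doubles every chromosome and then exposes every gene
copy to loss; other branches can apply background loss, local (tandem)
duplication, block translocation, amino-acid substitution, and — in the
post-3R teleost lineages — intron gain, concentrated in a low-conservation
loop region analogous to the third intracellular loop of a GPCR.

Every event is written to a truth ledger (`SimTruth`) that the analysis
pipeline never reads; exports go through the same GFF3/FASTA/TSV formats the
I/O module consumes, so the whole pipeline can be exercised and scored
end-to-end without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GeneRecord, write_gene_models
from .msa_identity import BLOSUM62
from .wgd_timing import SpeciesTree

# default species scenario: 8 vertebrates + a pre-1R outgroup.
DEFAULT_SPECIES_TREE = (
    "(lancelet:0.25,"
    "((((mammal:0.06,bird:0.055)amniota:0.02,amphibian:0.07)tetrapoda:0.015,"
    "coelacanth:0.05)sarcopterygii:0.015,"
    "(gar:0.055,(zebrafish:0.06,(stickleback:0.05,medaka:0.05)neoteleostei:0.02)"
    "teleostei:0.03[&WGD=3R])actinopterygii:0.015)"
    "vertebrata:0.06[&WGD=1R,2R]);"
)

#: GPCR-like protein layout (residue ranges, 0-based half-open).  IL3 is the
#: low-conservation region with the elevated substitution/intron-gain rates.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "Nterm": (0, 30),
    "TM1": (30, 54),
    "IL1": (54, 62),
    "TM2": (62, 86),
    "EL1": (86, 94),
    "TM3": (94, 118),
    "IL2": (118, 128),
    "TM4": (128, 152),
    "EL2": (152, 164),
    "TM5": (164, 188),
    "IL3": (188, 338),
    "TM6": (338, 362),
    "EL3": (362, 370),
    "TM7": (370, 394),
    "Cterm": (394, 480),
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# fixed empirical exchange process: replacement probabilities proportional to
# exp(BLOSUM62/2), zero on the diagonal.
_EX = np.exp(BLOSUM62[:20, :20] / 2.0)
np.fill_diagonal(_EX, 0.0)
EXCHANGE = _EX / _EX.sum(axis=1, keepdims=True)

# minimal reverse codon table (first codon per amino acid, alphabetical)
_CODON = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACA", "V": "GTA",
    "W": "TGG", "Y": "TAC",
}


@dataclass
class SimConfig:
    """Simulation scenario; the defaults are the package's study conditions."""

    seed: int
    species_tree_newick: str = DEFAULT_SPECIES_TREE
    outgroup: str = "lancelet"
    reference_species: str = "gar"
    n_chromosomes: int = 1
    families_per_chromosome: int = 12
    focal_family_index: int = 5
    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    variable_region: str = "IL3"
    variable_multiplier: float = 4.0
    gene_spacing_bp: int = 400_000
    wgd_loss_prob: float = 0.25
    branch_loss_prob: float = 0.0
    translocation_prob: float = 0.05
    local_dup_prob: float = 0.01
    intron_gain_rate: float = 0.15
    intron_gain_below: str = "3R"
    intron_variable_bias: float = 0.8
    intron_length_range: tuple[int, int] = (80, 300)
    wgd_positions: dict[str, float] = field(
        default_factory=lambda: {"1R": 0.35, "2R": 0.6, "3R": 0.5}
    )

    def __post_init__(self) -> None:
        for name, p in (
            ("wgd_loss_prob", self.wgd_loss_prob),
            ("branch_loss_prob", self.branch_loss_prob),
            ("translocation_prob", self.translocation_prob),
            ("local_dup_prob", self.local_dup_prob),
            ("intron_variable_bias", self.intron_variable_bias),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0,1]")
        if self.intron_gain_rate < 0 or self.variable_multiplier < 0:
            raise ValueError("rates must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def protein_length(self) -> int:
        return max(e for _, e in self.regions.values())

    @property
    def variable_range(self) -> tuple[int, int]:
        return self.regions[self.variable_region]


@dataclass
class _SimGene:
    family: str
    anc_chrom: str
    path: tuple[str, ...]          # event tokens, e.g. ("1R:A", "3R:b", "LD7:a")
    protein: np.ndarray            # indices into AA20
    introns: tuple[tuple[int, int, str], ...]  # (residue, phase, gain_id)
    pos: int
    strand: str

    @property
    def wgd_lineage(self) -> str:
        return "".join(t.split(":")[1] for t in self.path if t[0].isdigit())


@dataclass
class SimTruth:
    """Event ledger; written by the simulator, never read by the pipeline."""

    genes: pd.DataFrame
    gains: dict[str, dict]
    losses: list[dict]
    translocations: list[dict]
    local_duplications: list[dict]

    def membership_label(self, gene_id: str) -> str:
        row = self.genes.loc[gene_id]
        return f"{row.anc_chrom}:{row.wgd_lineage}"

    def divergence_event(self, g1: str, g2: str) -> str | None:
        """First event token at which two same-family genes' histories part;
        None when one history is a prefix of the other or both are equal
        (pure speciation)."""
        p1 = tuple(self.genes.loc[g1].path.split("|")) if self.genes.loc[g1].path else ()
        p2 = tuple(self.genes.loc[g2].path.split("|")) if self.genes.loc[g2].path else ()
        for a, b in zip(p1, p2):
            if a != b:
                return a
        return None

    def divergence_class(self, g1: str, g2: str) -> str:
        ev = self.divergence_event(g1, g2)
        if ev is None:
            return "speciation"
        tag = ev.split(":")[0]
        if tag in ("1R", "2R"):
            return "1R2R"
        if tag == "3R":
            return "3R"
        return "lineage_specific"


@dataclass
class SimDataset:
    config: SimConfig
    records: list[GeneRecord]
    span_seqs: dict[str, str]
    regions: dict[str, tuple[int, int]]
    species_tree_newick: str
    truth: SimTruth

    def records_for(self, species: str) -> list[GeneRecord]:
        return [r for r in self.records if r.species == species]

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _substitute(
    protein: np.ndarray, dt: float, site_mult: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    counts = rng.poisson(dt * site_mult)
    if not counts.any():
        return protein
    protein = protein.copy()
    for site in np.nonzero(counts)[0]:
        for _ in range(counts[site]):
            protein[site] = rng.choice(20, p=EXCHANGE[protein[site]])
    return protein


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.st = SpeciesTree.from_newick(config.species_tree_newick)
        self.rng = np.random.default_rng(config.seed)
        P = config.protein_length
        vs, ve = config.variable_range
        self.site_mult = np.ones(P)
        self.site_mult[vs:ve] = config.variable_multiplier
        self.gain_counter = 0
        self.local_counter = 0
        self.scaffold_counter = 0
        self.truth_gains: dict[str, dict] = {}
        self.truth_losses: list[dict] = []
        self.truth_trans: list[dict] = []
        self.truth_local: list[dict] = []
        self.leaf_genomes: dict[str, dict[tuple, list[_SimGene]]] = {}
        # branches below the WGD event named in intron_gain_below get gains
        gain_root = None
        for nd, evs in self.st.wgd.items():
            if config.intron_gain_below in evs:
                gain_root = nd
        self.gain_nodes = set()
        if gain_root is not None:
            stack = [gain_root]
            while stack:
                nd = stack.pop()
                self.gain_nodes.add(nd)
                stack.extend(nd.child_nodes())

    # -- setup --------------------------------------------------------------

    def ancestral_genome(self) -> dict[tuple, list[_SimGene]]:
        cfg = self.cfg
        genome: dict[tuple, list[_SimGene]] = {}
        fam_no = 0
        for c in range(cfg.n_chromosomes):
            chrom_key = (f"c{c + 1}",)
            genes = []
            for i in range(cfg.families_per_chromosome):
                fam_no += 1
                fam = f"fam{fam_no:02d}"
                protein = self.rng.integers(0, 20, size=cfg.protein_length)
                genes.append(
                    _SimGene(
                        family=fam,
                        anc_chrom=chrom_key[0],
                        path=(),
                        protein=protein,
                        introns=(),
                        pos=(i + 1) * cfg.gene_spacing_bp,
                        strand="+" if self.rng.random() < 0.5 else "-",
                    )
                )
            genome[chrom_key] = genes
        return genome

    # -- per-branch processes ----------------------------------------------

    def _apply_wgd(
        self, genome: dict[tuple, list[_SimGene]], event: str, branch_label: str
    ) -> dict[tuple, list[_SimGene]]:
        copies = ("A", "B") if event in ("1R", "2R") else ("a", "b")
        out: dict[tuple, list[_SimGene]] = {}
        for chrom_key, genes in genome.items():
            for copy in copies:
                new_key = chrom_key + (f"{event}{copy}",)
                new_genes = []
                for g in genes:
                    kept = self.rng.random() >= self.cfg.wgd_loss_prob
                    ng = dataclasses.replace(
                        g, path=g.path + (f"{event}:{copy}",), protein=g.protein
                    )
                    if kept:
                        new_genes.append(ng)
                    else:
                        self.truth_losses.append(
                            {
                                "branch": branch_label,
                                "family": g.family,
                                "lineage": ng.wgd_lineage,
                                "after": event,
                            }
                        )
                out[new_key] = new_genes
        return out

    def _background_loss(self, genome, branch_label) -> None:
        if self.cfg.branch_loss_prob <= 0:
            return
        for chrom_key, genes in genome.items():
            survivors = []
            for g in genes:
                if self.rng.random() < self.cfg.branch_loss_prob:
                    self.truth_losses.append(
                        {
                            "branch": branch_label,
                            "family": g.family,
                            "lineage": g.wgd_lineage,
                            "after": "background",
                        }
                    )
                else:
                    survivors.append(g)
            genome[chrom_key] = survivors

    def _local_duplications(self, genome, branch_label, prob=None) -> None:
        prob = self.cfg.local_dup_prob if prob is None else prob
        if prob <= 0:
            return
        for chrom_key in sorted(genome):
            genes = genome[chrom_key]
            added = []
            for g in genes:
                if self.rng.random() < prob:
                    self.local_counter += 1
                    tag = f"LD{self.local_counter}"
                    used = {x.pos for x in genes} | {x.pos for x in added}
                    pos = g.pos + 10_000
                    while pos in used:
                        pos += 7_919
                    copy = dataclasses.replace(g, path=g.path + (f"{tag}:b",), pos=pos)
                    g.path = g.path + (f"{tag}:a",)
                    added.append(copy)
                    self.truth_local.append(
                        {"branch": branch_label, "family": g.family, "tag": tag}
                    )
            if added:
                genome[chrom_key] = sorted(genes + added, key=lambda x: x.pos)

    def _translocations(self, genome, branch_label) -> None:
        if self.cfg.translocation_prob <= 0:
            return
        for chrom_key in sorted(genome):
            if self.rng.random() >= self.cfg.translocation_prob:
                continue
            genes = genome[chrom_key]
            if len(genes) < 2:
                continue
            blk = int(self.rng.integers(1, min(3, len(genes) - 1) + 1))
            start = int(self.rng.integers(0, len(genes) - blk + 1))
            moved = genes[start : start + blk]
            genome[chrom_key] = genes[:start] + genes[start + blk :]
            others = [k for k in sorted(genome) if k != chrom_key]
            if self.rng.random() < 0.5 or not others:
                self.scaffold_counter += 1
                target = (f"T{self.scaffold_counter}",)
                genome.setdefault(target, [])
                base = self.cfg.gene_spacing_bp
            else:
                target = others[int(self.rng.integers(0, len(others)))]
                occupied = [g.pos for g in genome[target]]
                base = (max(occupied) if occupied else 0) + 30_000_000
            for i, g in enumerate(moved):
                g.pos = base + i * self.cfg.gene_spacing_bp
            genome[target] = sorted(genome[target] + moved, key=lambda x: x.pos)
            self.truth_trans.append(
                {
                    "branch": branch_label,
                    "from": "-".join(chrom_key),
                    "to": "-".join(target),
                    "families": ",".join(g.family for g in moved),
                }
            )

    def _intron_gains(self, genome, branch_label) -> None:
        cfg = self.cfg
        if cfg.intron_gain_rate <= 0:
            return
        P = cfg.protein_length
        vs, ve = cfg.variable_range
        for chrom_key in sorted(genome):
            for g in genome[chrom_key]:
                n = int(self.rng.poisson(cfg.intron_gain_rate))
                for _ in range(n):
                    for _try in range(50):
                        if self.rng.random() < cfg.intron_variable_bias:
                            residue = int(self.rng.integers(vs, ve))
                        else:
                            residue = int(self.rng.integers(1, P - 1))
                        phase = int(self.rng.integers(0, 3))
                        if residue == 0 and phase == 0:
                            continue
                        if all(
                            (r, p) != (residue, phase) for r, p, _ in g.introns
                        ):
                            break
                    else:
                        continue
                    self.gain_counter += 1
                    gid = f"ig{self.gain_counter}"
                    g.introns = tuple(
                        sorted(g.introns + ((residue, phase, gid),))
                    )
                    self.truth_gains[gid] = {
                        "family": g.family,
                        "branch": branch_label,
                        "residue": residue,
                        "phase": phase,
                        "lineage": g.wgd_lineage,
                    }

    # -- tree walk ----------------------------------------------------------

    def run(self) -> None:
        genome = self.ancestral_genome()
        self._descend(self.st.tree.seed_node, genome)

    def _count(self, genome) -> int:
        return sum(len(v) for v in genome.values())

    def _descend(self, node, genome) -> None:
        for child in node.child_nodes():
            label = self.st.node_label(child)
            dt = child.edge.length or 0.0
            g2 = {
                k: [
                    dataclasses.replace(x, protein=x.protein.copy())
                    for x in v
                ]
                for k, v in genome.items()
            }
            events = sorted(
                self.st.events_above(child),
                key=lambda e: self.cfg.wgd_positions.get(e, 0.5),
            )
            # chained ledger identity: after each doubling,
            # count = 2 x previous - losses; then - background + local dups.
            # The branch is cut into segments at the WGD positions; local
            # duplications fire at segment midpoints with probability
            # proportional to segment length, so a tandem event is uniform
            # in time rather than pinned between the two basal doublings.
            expect = self._count(g2)
            cuts = [
                (self.cfg.wgd_positions.get(ev, 0.5), ev) for ev in events
            ] + [(1.0, None)]
            cuts.sort()
            last = 0.0
            for frac, ev in cuts:
                seg = max(frac - last, 0.0)
                half = 0.5 * seg * dt
                for k in sorted(g2):
                    for x in g2[k]:
                        x.protein = _substitute(x.protein, half, self.site_mult, self.rng)
                local_before = len(self.truth_local)
                self._local_duplications(
                    g2, label, prob=self.cfg.local_dup_prob * seg
                )
                expect += len(self.truth_local) - local_before
                for k in sorted(g2):
                    for x in g2[k]:
                        x.protein = _substitute(x.protein, half, self.site_mult, self.rng)
                if ev is not None:
                    losses_before = len(self.truth_losses)
                    g2 = self._apply_wgd(g2, ev, label)
                    expect = 2 * expect - (len(self.truth_losses) - losses_before)
                last = frac
            losses_before = len(self.truth_losses)
            self._background_loss(g2, label)
            expect -= len(self.truth_losses) - losses_before
            self._translocations(g2, label)
            if child in self.gain_nodes:
                self._intron_gains(g2, label)
            n_after = self._count(g2)
            assert n_after == expect, (
                f"gene-count ledger violated on branch {label}: "
                f"{n_after} != {expect}"
            )
            if child.is_leaf():
                self.leaf_genomes[child.taxon.label] = g2
            else:
                self._descend(child, g2)


# ---------------------------------------------------------------------------
# realization as gene models
# ---------------------------------------------------------------------------

def _exonize(
    protein_len: int, introns: tuple[tuple[int, int, str], ...]
) -> list[int]:
    """Coding-exon nucleotide lengths from (residue, phase) intron positions."""
    cds_len = 3 * protein_len
    bounds = sorted(3 * r + p for r, p, _ in introns)
    if any(b <= 0 or b >= cds_len for b in bounds):
        raise ValueError("intron boundary outside CDS")
    prev = 0
    out = []
    for b in bounds:
        out.append(b - prev)
        prev = b
    out.append(cds_len - prev)
    return out


def _realize_leaf(
    species: str,
    genome: dict[tuple, list[_SimGene]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneRecord], dict[str, str], list[dict]]:
    """Turn a leaf genome into GeneRecords + gene-span sequences + truth rows."""
    records: list[GeneRecord] = []
    spans: dict[str, str] = {}
    truth_rows: list[dict] = []
    lo, hi = cfg.intron_length_range
    counter = 0
    for idx, chrom_key in enumerate(sorted(genome)):
        chrom = f"chr{idx + 1}"
        for g in sorted(genome[chrom_key], key=lambda x: x.pos):
            counter += 1
            gid = f"{species}_g{counter:03d}"
            prot = "".join(AA20[i] for i in g.protein)
            exon_nt = _exonize(len(prot), g.introns)
            intron_lens = [int(rng.integers(lo, hi + 1)) for _ in exon_nt[:-1]]
            cds = "".join(_CODON[a] for a in prot)
            pieces = []
            cpos = 0
            coding_intervals = []  # in coding orientation, relative to span
            off = 0
            for i, el in enumerate(exon_nt):
                pieces.append(cds[cpos : cpos + el])
                coding_intervals.append((off, off + el))
                off += el
                cpos += el
                if i < len(intron_lens):
                    fill = "".join(
                        "ACGT"[j] for j in rng.integers(0, 4, size=intron_lens[i] - 4)
                    )
                    pieces.append("GT" + fill + "AG")
                    off += intron_lens[i]
            coding_seq = "".join(pieces)
            span_len = len(coding_seq)
            start = g.pos
            end = start + span_len
            if g.strand == "+":
                exons = [(start + a, start + b) for a, b in coding_intervals]
                span = coding_seq
            else:
                exons = [(end - b, end - a) for a, b in coding_intervals]
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                span = "".join(comp[c] for c in reversed(coding_seq))
            rec = GeneRecord(
                gene_id=gid,
                species=species,
                chrom=chrom,
                start=start,
                end=end,
                strand=g.strand,
                family_id=g.family,
                exons=exons,
                protein=prot,
            )
            problems = rec.validate()
            assert not problems, problems
            records.append(rec)
            spans[gid] = span
            truth_rows.append(
                {
                    "gene_id": gid,
                    "species": species,
                    "family_id": g.family,
                    "anc_chrom": g.anc_chrom,
                    "wgd_lineage": g.wgd_lineage,
                    "path": "|".join(g.path),
                    "chrom": chrom,
                    "introns": ";".join(
                        f"{r}:{p}:{i}" for r, p, i in g.introns
                    ),
                }
            )
    return records, spans, truth_rows


def simulate(config: SimConfig) -> SimDataset:
    """Run the scenario; fully reproducible from config.seed."""
    sim = _Simulator(config)
    sim.run()
    records: list[GeneRecord] = []
    spans: dict[str, str] = {}
    rows: list[dict] = []
    rng_exp = np.random.default_rng([config.seed, 104_729])
    for species in sorted(sim.leaf_genomes):
        recs, sp, tr = _realize_leaf(
            species, sim.leaf_genomes[species], config, rng_exp
        )
        records.extend(recs)
        spans.update(sp)
        rows.extend(tr)
    genes = pd.DataFrame(rows).set_index("gene_id")
    truth = SimTruth(
        genes=genes,
        gains=sim.truth_gains,
        losses=sim.truth_losses,
        translocations=sim.truth_trans,
        local_duplications=sim.truth_local,
    )
    return SimDataset(
        config=config,
        records=records,
        span_seqs=spans,
        regions=dict(config.regions),
        species_tree_newick=config.species_tree_newick,
        truth=truth,
    )


def expected_retention(config: SimConfig, species: str | None = None) -> dict[str, float]:
    """Closed-form expected copy number per species for one ancestral gene:
    product over the root-to-leaf path of 2*(1-wgd_loss) per WGD and
    (1-branch_loss) per branch."""
    st = SpeciesTree.from_newick(config.species_tree_newick)
    out: dict[str, float] = {}

    def walk(node, e: float) -> None:
        for child in node.child_nodes():
            e2 = e
            for _ in st.events_above(child):
                e2 *= 2.0 * (1.0 - config.wgd_loss_prob)
            e2 *= 1.0 - config.branch_loss_prob
            if child.is_leaf():
                out[child.taxon.label] = e2
            else:
                walk(child, e2)

    walk(st.tree.seed_node, 1.0)
    if species is not None:
        return {species: out[species]}
    return out


# ---------------------------------------------------------------------------
# export / load
# ---------------------------------------------------------------------------

def export(dataset: SimDataset, outdir: str | Path) -> Path:
    """Write the dataset in the standard formats (GFF3 + FASTA + newick +
    family TSV + regions TSV); the truth ledger goes to a separate file that
    the pipeline never consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fam_rows = []
    for species in dataset.species:
        recs = dataset.records_for(species)
        write_gene_models(
            recs, out / f"{species}.gff3", out / f"{species}.protein.fa"
        )
        with open(out / f"{species}.spans.fa", "w") as fh:
            for r in sorted(recs, key=lambda r: r.gene_id):
                fh.write(f">{r.gene_id}\n{dataset.span_seqs[r.gene_id]}\n")
        fam_rows.extend(
            (r.gene_id, r.family_id) for r in sorted(recs, key=lambda r: r.gene_id)
        )
    with open(out / "families.tsv", "w") as fh:
        fh.write("gene_id\tfamily_id\n")
        for gid, fam in fam_rows:
            fh.write(f"{gid}\t{fam}\n")
    (out / "species_tree.nwk").write_text(dataset.species_tree_newick + "\n")
    with open(out / "regions.tsv", "w") as fh:
        fh.write("name\tstart\tend\n")
        for name, (s, e) in dataset.regions.items():
            fh.write(f"{name}\t{s + 1}\t{e}\n")  # 1-based inclusive on disk
    dataset.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    pd.DataFrame.from_dict(dataset.truth.gains, orient="index").to_csv(
        out / "truth_gains.tsv", sep="\t", index_label="gain_id"
    )
    return out


def load_dataset(indir: str | Path):
    """Read back an exported dataset (pipeline view: no truth).

    Returns (records, span_seqs, regions, species_tree_newick, family_map).
    """
    from Bio import SeqIO

    from .genome_io import read_family_map, read_gene_models
    from .msa_identity import read_region_file

    indir = Path(indir)
    family_map = read_family_map(indir / "families.tsv")
    records: list[GeneRecord] = []
    spans: dict[str, str] = {}
    for gff in sorted(indir.glob("*.gff3")):
        species = gff.stem
        recs, issues = read_gene_models(
            gff, indir / f"{species}.protein.fa", family_map, species
        )
        if issues:
            raise ValueError(f"{species}: {issues[:3]}")
        records.extend(recs)
        span_fa = indir / f"{species}.spans.fa"
        if span_fa.exists():
            for rec in SeqIO.parse(str(span_fa), "fasta"):
                spans[rec.id] = str(rec.seq)
    regions = read_region_file(indir / "regions.tsv")
    newick = (indir / "species_tree.nwk").read_text().strip()
    return records, spans, regions, newick, family_map
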