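# Methods

## Problem and approach

A gene family in jawed vertebrates typically owes part of its size to the
two rounds of whole-genome duplication at the base of the vertebrates (1R
and 2R) and, in teleost fishes, to a third round (3R) on the teleost stem.
Deciding, for each duplication in a family's history, whether it was one of
the tetraploidizations or an independent (local/tandem) event requires three
kinds of evidence, and this package implements all three as one pipeline:

1. **Sequence phylogeny.** Protein sequences of all family members are
   aligned; a distance tree with bootstrap supports is built; internal nodes
   are labelled speciation/duplication by the species-overlap rule (a node
   is a duplication iff its two child clades share a species).
2. **Conserved synteny.** Chromosomal neighbourhoods of the focal gene are
   censused for other families that duplicated in the same epochs; segments
   that share several such ohnolog families are assembled into the members
   of a paralogon (the quartet of regions left by 1R/2R, the octet left by
   3R).
3. **Gene structure.** Coding-intron positions and phases are projected
   onto the protein alignment; identical (column, phase) sites across
   species are treated as one intron, and each intron's origin is placed on
   the species tree by Dollo parsimony (one gain, minimal losses).

Each duplication node maps to the species-tree branch above the most recent
common ancestor of the species it spans.  If that branch carries the 1R/2R
annotation the event is classed `1R2R`; the two basal rounds are never
separated, because trees genuinely cannot order them (they are close in time
and the data contain almost no signal for the split).  A branch carrying 3R
gives `3R`; anything else is `lineage_specific`.

## Alignment and identity

Pairwise alignment is global Needleman–Wunsch with affine gaps
(BLOSUM62, gap open 10, gap extend 0.5; a gap of length k costs
`open + (k-1)·extend`).  Scores are scaled to integers internally so that
the tie-break rules (diagonal, then up, then left) are exact rather than
float-fragile; the test suite checks the optimum against brute-force
enumeration on short strings and against an independent C implementation on
longer ones.  The multiple aligner is single-pass progressive: a
neighbour-joining guide tree on score dissimilarities
(`max(S(a,a),S(b,b)) − S(a,b)`), then profile–profile alignment with
expected-score columns.  No iterative refinement is performed; for the
strongly conserved receptor-like families this package targets, a single
pass suffices, and residual misalignment is confined to the variable loop
that the tree stage masks anyway.

Percent identity between two rows of an alignment is
`100 × identical / columns where at least one row has a residue`, optionally
restricted to named regions (the seven transmembrane helices, the third
intracellular loop, …) projected from a reference sequence onto alignment
columns.  Region files are 1-based inclusive on the reference protein and
converted at the file boundary.  Because published identity percentages
rarely state their denominator, comparisons against printed values should
allow a ±2-point tolerance.

## Trees

Distances are Poisson-corrected p-distances, `d = −ln(1 − p)` over columns
where both sequences have residues, capped at `d_max = 5` near saturation.
Neighbour joining is the canonical Saitou–Nei algorithm; ties in the
Q-criterion resolve to the smallest index pair in cluster-creation order and
negative limb lengths are clamped to zero with a warning.  On additive
matrices NJ provably recovers the generating topology; the acceptance suite
verifies this exhaustively on random trees of up to seven taxa.  Bootstrap
supports are percentages over column-resampled replicates (default 100);
the default tree input excludes the variable loop region, mirroring the
practice of building the primary tree from the alignment without the
unalignable segment.  Trees are rooted on the outgroup's pendant edge (or
the maximal-purity edge, flagged, when the outgroup is not monophyletic).

**Species-tree-aware correction.**  A distance tree occasionally misplaces
one lineage across a short internal edge — the signal over such an edge is
a handful of substitutions, and a realization can simply come out wrong.
Before classification, nearest-neighbour interchanges are therefore tried
across every internal edge not longer than 0.02 substitutions/site, and a
move is accepted only when it strictly lowers the duplication+loss
reconciliation cost against the species tree.  Long edges are never
rearranged, so deeply diverged ohnolog clades with heavy loss patterns
cannot be collapsed into "orthologs"; the ceiling is deliberately of the
order of the shortest true internal branches.  This is the tree-based
counterpart of arguing from species distributions when node support is
thin.

**Tandem vs ohnolog.**  A tandem duplication that happens on the same
species-tree branch as a tetraploidization leaves both copies in every
descendant species and is indistinguishable from an ohnolog pair by species
distribution alone.  The chromosomal signature separates the two: after
timing, any WGD-classed duplication whose two copies sit within 100 kb on
one chromosome in a majority of the species carrying both is downgraded to
`lineage_specific`.  The converse failure (a tandem pair between 1R and 2R
whose interleaved copies are then reciprocally lost from the two
post-2R chromosomes) is genuinely unresolvable by any of the three evidence
types and is accepted as an error mode.

## Paralogon assembly

Ohnolog groups (genes descending from one post-WGD copy) are obtained by
cutting each classified gene tree at its 1R2R/3R duplication nodes.  Two
graphs over chromosome segments are built: *paralogy* edges (within a
species) count families with a WGD-classed ohnolog pair split across two
segments — their components are whole paralogons; *orthology* edges count
families with same-group genes on two segments — their components, over
edges with at least 2 shared families, are the paralogon members.  One
shared family is deliberately insufficient: it is compatible with chance or
single-gene transposition, whereas the descent argument rests on multiple
co-localized families.  Orthology links are only drawn between species with
the same set of WGDs on their lineage: a pre-3R chromosome is the parent of
two teleost chromosomes, not a member of the teleost octet, so the quartet
and the octet are separate member sets.  A member whose segments lie on
different chromosomes of one species is flagged as split by translocation.
Species lacking a family's gene are reported as "not identified" — absence
of a gene model cannot distinguish loss from an unsequenced or unannotated
region — and sequences shorter than half the family maximum are marked
incomplete rather than dropped.

## Intron gains

An intron after L coding nucleotides has phase `L mod 3` and projects to
protein residue `⌊L/3⌋`, hence to an alignment column.  Sites are matched
across genes by exact (column, phase) identity; a ±1-column tolerance
exists but is off by default, because observed cases are either identical
or clearly different, and a fuzzy window would merge genuinely independent
gains.  Per ohnolog group, species with the gene but not the intron count
as absent, species with explicitly uncertain models constrain nothing, and
species without the gene are simply missing.  Dollo parsimony places one
gain on the branch above the MRCA of the carriers and losses on the minimal
set of branches whose subtrees contain an absence and no presence; the test
suite checks every presence pattern on a six-leaf tree against exhaustive
loss-set search.  Donor/acceptor dinucleotides are checked against the
GT..AG consensus (strand-aware); non-consensus introns are flagged, not
rejected.

## The synthetic genome simulator

The simulator is the package's source of fully truth-annotated data.  Its
default scenario mirrors the study design the pipeline is meant for: a
pre-1R outgroup (lancelet) plus eight vertebrates — mammal, bird, amphibian,
coelacanth, gar, and three teleosts (zebrafish, stickleback, medaka) — with
1R and 2R on the vertebrate stem and 3R on the teleost stem.  One ancestral
chromosome carries 12 single-gene families at 400 kb spacing; each WGD
doubles every chromosome and then exposes each copy to loss with
probability 0.25; translocations move blocks of 1–3 genes to a fresh or
distant location (0.05 per chromosome per branch); tandem duplications fire
uniformly in branch time (0.01 per gene per branch) and insert the copy
10 kb away.  Proteins are 480 aa with a GPCR-like layout (N-terminus, seven
transmembrane helices, loops, C-terminus); substitutions follow a fixed
empirical exchange process (replacement probabilities ∝ exp(BLOSUM62/2))
with a 4× rate multiplier on the 150-residue IL3-like loop.  Branch lengths
are set so that gar–mammal identity is ≈84% outside the loop and ≈74%
overall — the conserved-receptor regime the identity figures of such
families show.  Intron gains occur only in post-3R teleost lineages
(0.15 per gene per branch), 80% of them inside the variable loop, always
with canonical GT..AG boundaries.  Chromosome and gene identifiers are
renamed per species so that no output file leaks copy identity; the truth
ledger (ancestral origin, WGD copy lineage, every loss, translocation,
tandem duplication and intron gain) is written separately and never read by
the pipeline.  A chained count identity (after each doubling,
`count = 2×previous − losses`, then `−background losses + tandem copies`)
is asserted on every branch of every simulation.

What the simulator does *not* model: nucleotide-level evolution (coding
sequence is back-translated with fixed codons), insertions/deletions in
proteins, rate variation beyond the single loop multiplier, gene conversion
between ohnologs, and realistic chromosome counts.  Passing recovery tests
therefore shows that the inference machinery is correct under its stated
model, not that real annotation noise, assembly gaps, or alignment
ambiguity are handled — those enter real analyses through the explicit
curation knobs (family-size cap, support thresholds, uncertain intron
states).

## Evaluation metrics

With simulator truth available, a run is scored by: (i) duplication-event
classification accuracy — each inferred duplication is matched to the
majority divergence event (per the ledger) among the gene pairs it
separates and counted correct when the classes agree; ties count as wrong,
and the stricter unanimous-pair rate is reported alongside; (ii) adjusted
Rand index between inferred member labels and the true
(ancestral chromosome, WGD copy lineage) labels over all assigned genes;
(iii) the fraction of true intron gains with at least one surviving carrier
that are recovered with exact residue, phase and gain branch.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| flank | 10 Mb | neighbourhood window on each side of the focal gene |
| min_members | 2 | neighbour-family census threshold in the reference species (3 = stricter variant for gene-dense regions) |
| bootstrap | 100 | column-resampling replicates |
| support threshold | 50 | below this a duplication call is flagged weak |
| min_shared_families | 2 | orthology-edge weight needed to join segments into a member |
| max family size | 12 | per-species cap above which a family is excluded (massive local expansions) |
| tandem_bp | 100 kb | adjacency radius for tandem reclassification |
| NNI edge ceiling | 0.02 subs/site | only shorter edges may be rearranged |
| d_max | 5 | distance saturation cap |

The window census models the real-data workflow, where neighbour families
are discovered from the reference species' regions; an explicit family list
can be supplied instead (the analogue of a curated selection), and the
recovery experiments use the full simulated family list so that every
simulated event counts against the metrics.

## Problem sizes

The validation experiments run 20 independent simulations of the default
scenario (~250–300 genes each, ~35 duplication events and ~30 observable
intron gains per run), a zero-noise run (~520 genes), 200 random additive
matrices of up to 7 taxa, all 63 Dollo patterns on a 6-leaf tree, and ~400
short alignment pairs against brute force; the whole set completes in a few
minutes on one CPU.
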