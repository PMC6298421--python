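"""Validation experiments: oracle-equivalence suites and scaled-down
parameter-recovery runs on the synthetic scenario.

Everything here recomputes its result from scratch at call time; nothing is
cached or hard-coded.  The oracles (exhaustive alignment enumeration, random
additive distance matrices, exhaustive Dollo loss-set search) are written
independently of the implementations they check.
"""

from __future__ import annotations

import json
import random
from dataclasses import replace

import dendropy
import numpy as np

from .gene_trees import DistanceMatrix, nj_tree, unrooted_splits
from .intron_events import ABSENT, PRESENT, dollo_gains
from .msa_identity import AA_ALPHABET, BLOSUM62, global_align
from .pipeline import PipelineConfig, evaluate, run_all
from .synthetic_genome import SimConfig, simulate
from .wgd_timing import SpeciesTree

# ---------------------------------------------------------------------------
# criterion-style oracle suites
# ---------------------------------------------------------------------------

def brute_force_alignment_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal affine-gap global alignment score by enumerating every
    monotone alignment of two short strings."""
    best: float | None = None

    def rec(i: int, j: int, cols: list) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            s, prev = 0.0, None
            for x, y in cols:
                if x is not None and y is not None:
                    s += BLOSUM62[AA_ALPHABET.index(a[x]), AA_ALPHABET.index(b[y])]
                    prev = "m"
                else:
                    cur = "x" if x is None else "y"
                    s -= gap_extend if prev == cur else gap_open
                    prev = cur
            if best is None or s > best:
                best = s
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(i, j)])
        if i < len(a):
            rec(i + 1, j, cols + [(i, None)])
        if j < len(b):
            rec(i, j + 1, cols + [(None, j)])

    rec(0, 0, [])
    return best


def alignment_oracle_rate(seed: int, n_random: int = 200) -> float:
    """Fraction of short test pairs where the DP aligner equals the
    brute-force optimum: exhaustive over a 2-letter alphabet up to length 3,
    plus random pairs up to length 6 over a 4-letter alphabet."""
    pairs: list[tuple[str, str]] = []
    two = ["".join(p) for L in (1, 2, 3) for p in _strings("AC", L)]
    pairs.extend((x, y) for x in two for y in two)
    rng = random.Random(seed)
    for _ in range(n_random):
        a = "".join(rng.choice("ACDE") for _ in range(rng.randint(1, 6)))
        b = "".join(rng.choice("ACDE") for _ in range(rng.randint(1, 6)))
        pairs.append((a, b))
    ok = sum(
        1
        for a, b in pairs
        if abs(global_align(a, b).score - brute_force_alignment_score(a, b)) < 1e-9
    )
    return ok / len(pairs)


def _strings(alphabet: str, length: int):
    if length == 0:
        yield ""
        return
    for prefix in _strings(alphabet, length - 1):
        for c in alphabet:
            yield prefix + c


def random_additive_case(n: int, rng: random.Random):
    """A random binary unrooted topology with positive branch lengths and its
    exact path-length distance matrix."""
    taxa = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for lab in taxa:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nd.edge.length = rng.uniform(0.1, 1.0)
        nodes.append(nd)
    while len(nodes) > 3:
        i, j = rng.sample(range(len(nodes)), 2)
        a, b = nodes[i], nodes[j]
        p = dendropy.Node()
        p.add_child(a)
        p.add_child(b)
        p.edge.length = rng.uniform(0.1, 1.0)
        nodes = [x for x in nodes if x not in (a, b)] + [p]
    root = dendropy.Node()
    for x in nodes:
        root.add_child(x)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = pdm.distance(tns.get_taxon(taxa[i]), tns.get_taxon(taxa[j]))
    return tree, DistanceMatrix(taxa, m)


def nj_additive_recovery_rate(seed: int, n_trees: int = 200, max_taxa: int = 7) -> float:
    """Fraction of random additive matrices whose NJ tree matches the
    generating topology exactly (split sets compared)."""
    rng = random.Random(seed)
    ok = 0
    for _ in range(n_trees):
        n = rng.randint(4, max_taxa)
        true, dm = random_additive_case(n, rng)
        if unrooted_splits(nj_tree(dm)) == unrooted_splits(true):
            ok += 1
    return ok / n_trees


DOLLO_TEST_TREE = "(((A:1,B:1)ab:1,C:1)abc:1,((D:1,E:1)de:1,F:1)def:1)root;"


def _brute_force_min_losses(st: SpeciesTree, present: set[str], absent: set[str]) -> int:
    """Smallest loss-edge set consistent with a single gain at the MRCA of
    the present species, by exhaustive subset search."""
    gain = st.mrca(present)
    edges = []
    stack = list(gain.child_nodes())
    while stack:
        nd = stack.pop()
        edges.append(nd)
        stack.extend(nd.child_nodes())
    leaves_under_gain = st.leafset(gain)
    from itertools import combinations

    for k in range(len(edges) + 1):
        for combo in combinations(edges, k):
            lost = set()
            for nd in combo:
                lost |= set(st.leafset(nd))
            # a loss set is consistent when no present species is covered and
            # every absent species inside the gain clade is covered; absences
            # outside the gain clade never had the intron and cost nothing.
            ok = all(p not in lost for p in present) and all(
                (a in lost) or (a not in leaves_under_gain) for a in absent
            )
            if ok:
                return k
    return -1


def dollo_oracle_rate(tree_newick: str = DOLLO_TEST_TREE) -> float:
    """Over every non-empty presence pattern on a fixed 6-leaf tree
    (absences = complement), the fraction where the Dollo reconstruction has
    a valid, minimal loss set and the correct gain branch."""
    st = SpeciesTree.from_newick(tree_newick)
    leaves = sorted(st.species)
    n_ok = 0
    total = 0
    for bits in range(1, 2 ** len(leaves)):
        present = {leaves[i] for i in range(len(leaves)) if bits >> i & 1}
        absent = set(leaves) - present
        total += 1
        states = {s: PRESENT for s in present} | {s: ABSENT for s in absent}
        rec = dollo_gains(states, st)
        gain_nd = st.mrca(present)
        if rec.gain_branch != st.node_label(gain_nd):
            continue
        # validity: losses cover exactly the absent leaves under the gain
        lost = set()
        for lab in rec.loss_branches:
            lost |= set(st.leafset(st.node_by_label(lab)))
        covered = lost & st.leafset(gain_nd)
        if covered != (absent & set(st.leafset(gain_nd))):
            continue
        if len(rec.loss_branches) != _brute_force_min_losses(st, present, absent):
            continue
        n_ok += 1
    return n_ok / total


# ---------------------------------------------------------------------------
# synthetic-scenario experiments
# ---------------------------------------------------------------------------

def _run_one(sim_seed: int, sim_overrides: dict | None = None):
    cfg = SimConfig(seed=sim_seed, **(sim_overrides or {}))
    ds = simulate(cfg)
    fams = sorted({r.family_id for r in ds.records})
    pcfg = PipelineConfig(families=fams)
    report = run_all(ds, None, seed=sim_seed, config=pcfg)
    return ds, report, evaluate(report, ds.truth)


def recovery_experiment(seed: int, n_seeds: int = 20) -> dict:
    """The scaled-down parameter-recovery study: n_seeds independent
    simulations under the default scenario, pipeline re-run on each, metrics
    pooled over all events/genes/gains."""
    n_calls = n_correct = 0
    ari_labels_true: list[str] = []
    ari_labels_pred: list[str] = []
    n_gains = n_recovered = 0
    per_seed = []
    for i in range(n_seeds):
        sim_seed = (seed * 1_000 + i) % (2**31)
        ds, report, m = _run_one(sim_seed)
        n_calls += m["n_calls"]
        n_correct += round(m["event_classification_accuracy"] * m["n_calls"])
        n_gains += m["n_observable_gains"]
        n_recovered += round(m["intron_gain_recovery"] * m["n_observable_gains"])
        known = set(ds.truth.genes.index)
        ma = report.member_assignment
        for gid, mem in zip(ma.gene_id, ma.member):
            if gid in known:
                ari_labels_true.append(f"s{i}:{ds.truth.membership_label(gid)}")
                ari_labels_pred.append(f"s{i}:{mem}")
        per_seed.append(
            {
                "seed": sim_seed,
                "accuracy": m["event_classification_accuracy"],
                "ari": m["membership_ari"],
                "recovery": m["intron_gain_recovery"],
            }
        )
    from sklearn.metrics import adjusted_rand_score

    return {
        "classification_accuracy": n_correct / n_calls if n_calls else float("nan"),
        "membership_ari": float(
            adjusted_rand_score(ari_labels_true, ari_labels_pred)
        ),
        "intron_gain_recovery": n_recovered / n_gains if n_gains else float("nan"),
        "n_calls": n_calls,
        "n_observable_gains": n_gains,
        "per_seed": per_seed,
    }


def zero_noise_experiment(seed: int) -> dict:
    """Loss/translocation/local-duplication rates zero: the paralogon must be
    recovered as exact quartets (pre-3R genomes) and octets (teleosts), with
    perfect classification and membership."""
    overrides = dict(
        wgd_loss_prob=0.0,
        translocation_prob=0.0,
        local_dup_prob=0.0,
    )
    ds, report, m = _run_one(seed, overrides)
    st = SpeciesTree.from_newick(ds.species_tree_newick)
    teleosts: set[str] = set()
    for nd, evs in st.wgd.items():
        if "3R" in evs:
            teleosts |= set(st.leafset(nd))
    non_teleost_members = set()
    teleost_members = set()
    for mem in report.members:
        for sp in mem.species:
            if sp in teleosts:
                teleost_members.add(mem.label)
            else:
                non_teleost_members.add(mem.label)
    return {
        "non_teleost_member_count": len(non_teleost_members),
        "teleost_member_count": len(teleost_members),
        "classification_accuracy": m["event_classification_accuracy"],
        "membership_ari": m["membership_ari"],
        "intron_gain_recovery": m["intron_gain_recovery"],
        "n_observable_gains": m["n_observable_gains"],
    }


def determinism_check(seed: int, tmpdir) -> bool:
    """Two full runs at one seed must emit byte-identical reports."""
    from pathlib import Path

    outs = []
    for tag in ("a", "b"):
        ds = simulate(SimConfig(seed=seed))
        fams = sorted({r.family_id for r in ds.records})
        out = Path(tmpdir) / tag
        run_all(ds, out, seed=seed, config=PipelineConfig(families=fams))
        outs.append((out / "report.json").read_bytes())
    return outs[0] == outs[1]
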