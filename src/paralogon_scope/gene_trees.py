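"""Distance-based gene-tree inference: Poisson-corrected distances, canonical
neighbour joining, nonparametric bootstrap, and outgroup rooting.

Neighbour joining follows the Saitou-Nei Q criterion with fully deterministic
behaviour: ties in Q resolve to the smallest (i, j) pair in cluster-creation
order, and negative branch lengths are clamped to zero with a warning.  On an
additive distance matrix NJ provably recovers the generating topology, which
the test suite exercises exhaustively against random tree generators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .msa_identity import GAP, MSA

DEFAULT_DMAX = 5.0


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over named taxa."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("nonzero diagonal")
        if not np.isfinite(m).all() or (m < 0).any():
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m

    def to_phylip(self) -> str:
        lines = [f" {len(self.ids)}"]
        for i, t in enumerate(self.ids):
            row = " ".join(f"{x:.6f}" for x in self.matrix[i])
            lines.append(f"{t}  {row}")
        return "\n".join(lines) + "\n"


def poisson_distance(
    msa: MSA, pair: tuple[str, str], d_max: float = DEFAULT_DMAX
) -> float:
    """Poisson-corrected distance d = -ln(1 - p) over shared (both non-gap)
    columns, capped at d_max near saturation."""
    xa = np.frombuffer(msa.row(pair[0]).encode(), dtype=np.uint8)
    xb = np.frombuffer(msa.row(pair[1]).encode(), dtype=np.uint8)
    g = ord(GAP)
    shared = (xa != g) & (xb != g)
    n = int(shared.sum())
    if n == 0:
        raise ValueError(f"no shared columns between {pair[0]} and {pair[1]}")
    p = float(((xa != xb) & shared).sum() / n)
    if p >= 1.0 - math.exp(-d_max):
        return d_max
    return -math.log(1.0 - p)


def distance_matrix(msa: MSA, d_max: float = DEFAULT_DMAX) -> DistanceMatrix:
    n = msa.n
    enc = np.stack(
        [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    )
    g = ord(GAP)
    res = enc != g
    m = np.zeros((n, n))
    cap = 1.0 - math.exp(-d_max)
    for i in range(n):
        for j in range(i + 1, n):
            shared = res[i] & res[j]
            ns = int(shared.sum())
            if ns == 0:
                raise ValueError(
                    f"no shared columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            p = float(((enc[i] != enc[j]) & shared).sum() / ns)
            m[i, j] = m[j, i] = d_max if p >= cap else -math.log(1.0 - p)
    return DistanceMatrix(list(msa.ids), m)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

_TRIU_CACHE: dict[int, tuple] = {}


def _clamp(x: float) -> float:
    if x < 0:
        warnings.warn(f"negative branch length {x:.4g} clamped to 0", stacklevel=3)
        return 0.0
    return x


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbour joining; returns an unrooted dendropy tree whose
    seed node is the final trifurcation (or the 3-taxon star)."""
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")

    tns = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(dist.ids):
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=label)
        nodes[i] = nd

    # distance store with room for agglomerated clusters; `active` stays in
    # cluster-creation order so a row-major argmin on Q realizes the
    # smallest-(i, j) tie-break.
    cap = 2 * n
    D = np.zeros((cap, cap))
    D[:n, :n] = dist.matrix
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        if m not in _TRIU_CACHE:
            _TRIU_CACHE[m] = np.triu_indices(m, k=1)
        iu = _TRIU_CACHE[m]
        flat = np.full((m, m), np.inf)
        flat[iu] = Q[iu]
        ai, bi = divmod(int(np.argmin(flat)), m)
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = _clamp(lj)
        nodes[nxt] = parent
        rest = np.array([k for k in active if k not in (i, j)])
        newd = 0.5 * (D[i, rest] + D[j, rest] - dij)
        D[nxt, rest] = newd
        D[rest, nxt] = newd
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = active
    center = dendropy.Node()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx_, ln in ((i, li), (j, lj), (k, lk)):
        center.add_child(nodes[idx_])
        nodes[idx_].edge.length = _clamp(ln)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions & bootstrap
# ---------------------------------------------------------------------------

def unrooted_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of an (un)rooted tree, each canonicalized as the
    side not containing the lexicographically first taxon."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    all_set = frozenset(leaves)
    ref = leaves[0]
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def bootstrap_support(
    msa: MSA,
    n_replicates: int = 100,
    seed: int | None = None,
    d_max: float = DEFAULT_DMAX,
) -> dendropy.Tree:
    """NJ tree from the full alignment, with internal nodes labelled by the
    percentage of column-resampled replicates containing the same split.

    Pairs with no shared columns in a replicate are assigned the saturation
    cap d_max rather than aborting the replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    point = nj_tree(distance_matrix(msa, d_max=d_max))
    target = {}
    leaves = sorted(l.taxon.label for l in point.leaf_node_iter())
    all_set = frozenset(leaves)
    ref = leaves[0]
    for nd in point.preorder_node_iter():
        if nd is point.seed_node or nd.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        canon = all_set - side if ref in side else side
        if 1 < len(canon) < len(leaves) - 1:
            target[nd] = canon
    counts = {nd: 0 for nd in target}

    rng = np.random.default_rng(seed)
    enc = np.stack([np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows])
    g = ord(GAP)
    res = enc != g
    n = msa.n
    L = msa.width
    cap = 1.0 - math.exp(-d_max)
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        sub = enc[:, idx]
        subres = res[:, idx]
        m = np.zeros((n, n))
        for i in range(n):
            shared = subres[i] & subres[i + 1 :]
            ns = shared.sum(axis=1)
            mm = ((sub[i] != sub[i + 1 :]) & shared).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(ns > 0, mm / np.maximum(ns, 1), 1.0)
            dvals = np.where(p >= cap, d_max, -np.log1p(-np.minimum(p, cap)))
            m[i, i + 1 :] = dvals
            m[i + 1 :, i] = dvals
        rep = nj_tree(DistanceMatrix(list(msa.ids), m))
        rep_splits = unrooted_splits(rep)
        for nd, canon in target.items():
            if canon in rep_splits:
                counts[nd] += 1

    for nd, canon in target.items():
        nd.label = str(round(100.0 * counts[nd] / n_replicates))
    return point


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_at_outgroup(
    tree: dendropy.Tree, outgroup_taxa: set[str] | list[str]
) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    When no single edge separates the outgroup exactly, the edge with maximal
    Jaccard overlap between one of its sides and the outgroup is used and the
    tree is flagged (`tree.outgroup_monophyletic = False`).  Edge length is
    split evenly at the new root.  The unrooted split set is unchanged.
    """
    og = frozenset(outgroup_taxa)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if not og:
        raise ValueError("empty outgroup")
    if not og <= leaves:
        raise ValueError(f"outgroup taxa missing from tree: {sorted(og - leaves)}")
    if og == leaves:
        raise ValueError("outgroup cannot be the entire taxon set")

    best_edge = None
    best_purity = -1.0
    best_key = None
    exact = None
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        for s in (side, leaves - side):
            if s == og:
                exact = nd.edge
                break
            purity = len(s & og) / len(s | og)
            key = tuple(sorted(s))
            if purity > best_purity or (purity == best_purity and key < best_key):
                best_purity, best_edge, best_key = purity, nd.edge, key
        if exact is not None:
            break

    edge = exact if exact is not None else best_edge
    tree.outgroup_monophyletic = exact is not None
    if not tree.outgroup_monophyletic:
        warnings.warn(
            "outgroup not separable by a single edge; rooting on the edge "
            "with maximal outgroup purity",
            stacklevel=2,
        )
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    tree.is_rooted = True
    return tree
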