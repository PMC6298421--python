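"""Timing gene duplications against whole-genome duplications.

A gene-tree node is a *duplication* when its two child clades share at least
one species (species-overlap rule); otherwise it is a speciation.  Each
duplication maps to the species-tree branch above the most recent common
ancestor of the species spanned by the node.  If that branch is annotated
with the vertebrate tetraploidizations the event is classed ``1R2R`` (the two
basal rounds are deliberately merged: trees cannot tell them apart), if with
the teleost tetraploidization it is ``3R``, otherwise ``lineage_specific``.

Species trees are newick with branch annotations in comments, e.g.::

    (outgroup:0.3,(tetrapods...,(gar,teleosts)[&WGD=3R])vertebrata:0.1[&WGD=1R,2R]);

The annotation attaches to the branch *above* the node it follows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

EVENT_1R2R = "1R2R"
EVENT_3R = "3R"
EVENT_LOCAL = "lineage_specific"

_WGD_COMMENT = re.compile(r"\[&WGD=([^\]]+)\]")


def _scan_wgd_comments(newick: str) -> list[tuple[frozenset[str], list[str]]]:
    """Map each [&WGD=...] comment to the leaf set of the subtree (or leaf)
    whose text immediately precedes it."""
    out: list[tuple[frozenset[str], list[str]]] = []
    stack: list[list[str]] = [[]]
    last: list[str] = []
    i = 0
    n = len(newick)
    token = ""
    after_close = False

    def flush_token() -> None:
        nonlocal token, last
        if token:
            if not after_close:  # leaf name
                stack[-1].append(token)
                last = [token]
            token = ""

    while i < n:
        c = newick[i]
        if c == "(":
            flush_token()
            stack.append([])
            after_close = False
        elif c == ",":
            flush_token()
            after_close = False
        elif c == ")":
            flush_token()
            grp = stack.pop()
            stack[-1].extend(grp)
            last = grp
            after_close = True
        elif c == ":":
            flush_token()
            i += 1
            while i < n and (newick[i].isdigit() or newick[i] in ".eE+-"):
                i += 1
            continue
        elif c == "[":
            flush_token()
            j = newick.index("]", i)
            m = _WGD_COMMENT.fullmatch(newick[i : j + 1])
            if m:
                events = [e.strip() for e in m.group(1).split(",") if e.strip()]
                out.append((frozenset(last), events))
            i = j + 1
            continue
        elif c == ";":
            flush_token()
        elif c.isspace():
            flush_token()
        else:
            token += c
        i += 1
    return out


class SpeciesTree:
    """A rooted species tree whose branches may carry WGD annotations."""

    def __init__(self, tree: dendropy.Tree, wgd_by_node: dict | None = None):
        self.tree = tree
        self.tree.is_rooted = True
        self.wgd: dict[dendropy.Node, list[str]] = wgd_by_node or {}
        seen: list[str] = []
        for evs in self.wgd.values():
            for e in evs:
                if e in seen:
                    raise ValueError(f"duplicate WGD annotation {e!r}")
                seen.append(e)
        self._leafsets: dict[dendropy.Node, frozenset[str]] = {}
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                self._leafsets[nd] = frozenset([nd.taxon.label])
            else:
                s: frozenset[str] = frozenset()
                for ch in nd.child_nodes():
                    s |= self._leafsets[ch]
                self._leafsets[nd] = s

    @classmethod
    def from_newick(cls, source: str | Path) -> "SpeciesTree":
        text = str(source)
        if "(" not in text:  # a path, not newick text
            text = Path(source).read_text()
        tagged = _scan_wgd_comments(text)
        clean = _WGD_COMMENT.sub("", text)
        tree = dendropy.Tree.get(data=clean, schema="newick")
        tree.is_rooted = True
        st = cls(tree)
        for leafset, events in tagged:
            nd = st.mrca(leafset)
            st.wgd.setdefault(nd, []).extend(events)
        return cls(tree, st.wgd)

    @property
    def species(self) -> frozenset[str]:
        return self._leafsets[self.tree.seed_node]

    def mrca(self, species: set[str] | frozenset[str]) -> dendropy.Node:
        species = frozenset(species)
        unknown = species - self.species
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        best = None
        for nd in self.tree.postorder_node_iter():
            if species <= self._leafsets[nd]:
                best = nd
                break
        return best

    def events_above(self, node: dendropy.Node) -> list[str]:
        return list(self.wgd.get(node, []))

    def node_label(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        if node.label:
            return node.label
        return "+".join(sorted(self._leafsets[node]))

    def node_by_label(self, label: str) -> dendropy.Node:
        for nd in self.tree.preorder_node_iter():
            if self.node_label(nd) == label:
                return nd
        raise KeyError(label)

    def leafset(self, node: dendropy.Node) -> frozenset[str]:
        return self._leafsets[node]

    def depth(self, node: dendropy.Node) -> int:
        d = 0
        while node.parent_node is not None:
            node = node.parent_node
            d += 1
        return d

    def mrca_nodes(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = a.parent_node
            da -= 1
        while db > da:
            b = b.parent_node
            db -= 1
        while a is not b:
            a, b = a.parent_node, b.parent_node
        return a


@dataclass
class DuplicationCall:
    """One duplication node of a gene tree, timed against the species tree."""

    node_id: str
    family_id: str
    left_species: frozenset[str]
    right_species: frozenset[str]
    mapped_branch: str
    event_class: str
    support: float | None = None
    weak: bool = False

    @property
    def union_species(self) -> frozenset[str]:
        return self.left_species | self.right_species


@dataclass
class OhnologGroup:
    """Genes descending from one post-WGD copy of a family (paths between any
    two members cross no WGD-classed duplication node)."""

    family_id: str
    genes: frozenset[str]
    species: frozenset[str] = field(default_factory=frozenset)


def label_nodes(
    gene_tree: dendropy.Tree, leaf_species_map: dict[str, str]
) -> dendropy.Tree:
    """Annotate each node with `species_set` and `event` (speciation or
    duplication under the species-overlap rule).  Leaves get `event=None`."""
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            gid = nd.taxon.label
            if gid not in leaf_species_map:
                raise ValueError(f"leaf {gid!r} has no species mapping")
            nd.species_set = frozenset([leaf_species_map[gid]])
            nd.event = None
        else:
            children = nd.child_nodes()
            nd.species_set = frozenset().union(*(c.species_set for c in children))
            overlap = False
            for i in range(len(children)):
                for j in range(i + 1, len(children)):
                    if children[i].species_set & children[j].species_set:
                        overlap = True
            nd.event = "duplication" if overlap else "speciation"
    return gene_tree


def classify_event(
    union_species: frozenset[str] | set[str], species_tree: SpeciesTree
) -> tuple[str, str]:
    """(event_class, mapped branch label) for a duplication spanning the given
    species set."""
    mrca = species_tree.mrca(frozenset(union_species))
    events = species_tree.events_above(mrca)
    if "1R" in events or "2R" in events:
        cls = EVENT_1R2R
    elif "3R" in events:
        cls = EVENT_3R
    else:
        cls = EVENT_LOCAL
    return cls, species_tree.node_label(mrca)


def classify_tree(
    gene_tree: dendropy.Tree,
    species_tree: SpeciesTree,
    leaf_species_map: dict[str, str],
    family_id: str = "",
    support_threshold: float = 50.0,
) -> list[DuplicationCall]:
    """Label a rooted gene tree and time every duplication node.

    Duplications whose bootstrap support (numeric internal node label) is
    below `support_threshold` are flagged weak, never dropped.
    """
    label_nodes(gene_tree, leaf_species_map)
    calls: list[DuplicationCall] = []
    counter = 0
    for nd in gene_tree.preorder_node_iter():
        if nd.is_leaf() or nd.event != "duplication":
            continue
        children = nd.child_nodes()
        left, right = children[0].species_set, children[1].species_set
        cls, branch = classify_event(nd.species_set, species_tree)
        support = None
        if nd.label is not None:
            try:
                support = float(nd.label)
            except ValueError:
                support = None
        call = DuplicationCall(
            node_id=f"{family_id}:d{counter}",
            family_id=family_id,
            left_species=left,
            right_species=right,
            mapped_branch=branch,
            event_class=cls,
            support=support,
            weak=(support is not None and support < support_threshold),
        )
        nd.call = call
        calls.append(call)
        counter += 1
    return calls


def duplication_loss_cost(
    gene_tree: dendropy.Tree,
    species_tree: SpeciesTree,
    leaf_species_map: dict[str, str],
) -> int:
    """Duplication + loss parsimony cost of the rooted gene tree under LCA
    reconciliation with the species tree."""
    mapping: dict[dendropy.Node, dendropy.Node] = {}
    dups = losses = 0
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            mapping[nd] = species_tree.mrca({leaf_species_map[nd.taxon.label]})
            continue
        children = nd.child_nodes()
        m = mapping[children[0]]
        for ch in children[1:]:
            m = species_tree.mrca_nodes(m, mapping[ch])
        mapping[nd] = m
        is_dup = any(mapping[ch] is m for ch in children)
        if is_dup:
            dups += 1
        dm = species_tree.depth(m)
        for ch in children:
            k = species_tree.depth(mapping[ch]) - dm
            losses += k if is_dup else max(k - 1, 0)
    return dups + losses


def reconcile_nni(
    gene_tree: dendropy.Tree,
    species_tree: SpeciesTree,
    leaf_species_map: dict[str, str],
    max_edge_length: float = 0.02,
    max_rounds: int = 25,
) -> int:
    """Species-tree-aware correction of weakly determined gene-tree edges.

    Distance trees occasionally misplace a lineage across a short internal
    edge (the sequence signal over such an edge is a handful of
    substitutions).  This pass tries the two nearest-neighbour interchanges
    across every internal edge not longer than `max_edge_length` and accepts
    a move only when it strictly lowers the duplication+loss reconciliation
    cost.  Long edges — e.g. the deep splits between ohnolog clades — are
    never touched, so genuine duplications with heavy loss patterns cannot
    be explained away.  Returns the number of accepted moves; rearranged
    edges lose their support label.
    """
    accepted = 0
    for _ in range(max_rounds):
        best = None
        base_cost = duplication_loss_cost(gene_tree, species_tree, leaf_species_map)
        for v in list(gene_tree.preorder_node_iter()):
            u = v.parent_node
            if u is None or v.is_leaf():
                continue
            if (v.edge.length or 0.0) > max_edge_length:
                continue
            siblings = [s for s in u.child_nodes() if s is not v]
            if len(siblings) != 1:
                continue
            s = siblings[0]
            for ci, c in enumerate(v.child_nodes()):
                # swap c with the sibling s across edge (u, v)
                _swap(u, s, v, c)
                cost = duplication_loss_cost(
                    gene_tree, species_tree, leaf_species_map
                )
                _swap(u, c, v, s)  # undo
                if cost < base_cost and (best is None or cost < best[0]):
                    best = (cost, u, s, v, c)
        if best is None:
            break
        _, u, s, v, c = best
        _swap(u, s, v, c)
        v.label = None
        accepted += 1
    return accepted


def _swap(u: dendropy.Node, s: dendropy.Node, v: dendropy.Node, c: dendropy.Node):
    """Exchange child s of u with child c of v (u is v's parent)."""
    s_len, c_len = s.edge.length, c.edge.length
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)
    c.edge.length, s.edge.length = c_len, s_len


def reclassify_tandem_duplications(
    gene_tree: dendropy.Tree,
    gene_positions: dict[str, tuple[str, str, int]],
    tandem_bp: int = 100_000,
) -> list[DuplicationCall]:
    """Downgrade WGD-classed duplications whose copies are chromosomal
    neighbours to lineage-specific (tandem) duplications.

    A tandem duplication on the same species-tree branch as a
    tetraploidization leaves both copies in every descendant species, so by
    species distribution alone it is indistinguishable from an ohnolog pair.
    The chromosomal signature separates them: tandem copies sit next to each
    other on one chromosome, ohnologs sit on different paralogon members.
    For each duplication node, if in a majority of the species carrying both
    copies the closest copy pair is within `tandem_bp` on one chromosome,
    the call becomes lineage_specific with a `tandem` note.

    `gene_positions` maps gene_id -> (species, chrom, start).  Returns the
    calls that were reclassified.
    """
    changed: list[DuplicationCall] = []
    for nd in gene_tree.preorder_node_iter():
        call = getattr(nd, "call", None)
        if call is None or call.event_class not in (EVENT_1R2R, EVENT_3R):
            continue
        children = nd.child_nodes()
        left = [l.taxon.label for l in children[0].leaf_iter()]
        right = [l.taxon.label for l in children[1].leaf_iter()]
        shared = call.left_species & call.right_species
        if not shared:
            continue
        n_adjacent = 0
        for sp in shared:
            best = None
            for g1 in left:
                s1, c1, p1 = gene_positions[g1]
                if s1 != sp:
                    continue
                for g2 in right:
                    s2, c2, p2 = gene_positions[g2]
                    if s2 != sp or c1 != c2:
                        continue
                    d = abs(p1 - p2)
                    best = d if best is None else min(best, d)
            if best is not None and best <= tandem_bp:
                n_adjacent += 1
        if n_adjacent * 2 > len(shared):
            call.event_class = EVENT_LOCAL
            call.mapped_branch += " (tandem)"
            changed.append(call)
    return changed


def ohnolog_groups(
    gene_tree: dendropy.Tree,
    leaf_species_map: dict[str, str],
    family_id: str = "",
) -> list[OhnologGroup]:
    """Partition the leaves by cutting the tree at every WGD-classed
    duplication node (requires `classify_tree` to have run)."""
    group_of: dict[dendropy.Node, int] = {gene_tree.seed_node: 0}
    nxt = 1
    for nd in gene_tree.preorder_node_iter():
        if nd is gene_tree.seed_node:
            gid = 0
        else:
            gid = group_of[nd]
        is_wgd_dup = (
            not nd.is_leaf()
            and getattr(nd, "event", None) == "duplication"
            and getattr(nd, "call", None) is not None
            and nd.call.event_class in (EVENT_1R2R, EVENT_3R)
        )
        for ch in nd.child_nodes():
            if is_wgd_dup:
                group_of[ch] = nxt
                nxt += 1
            else:
                group_of[ch] = gid
    buckets: dict[int, list[str]] = {}
    for nd in gene_tree.leaf_node_iter():
        buckets.setdefault(group_of[nd], []).append(nd.taxon.label)
    groups = []
    for _, genes in sorted(buckets.items(), key=lambda kv: sorted(kv[1])):
        groups.append(
            OhnologGroup(
                family_id=family_id,
                genes=frozenset(genes),
                species=frozenset(leaf_species_map[g] for g in genes),
            )
        )
    return groups


def ohnolog_pair_classes(gene_tree: dendropy.Tree) -> dict[frozenset[str], str]:
    """For every pair of leaves whose gene-tree LCA is a classified
    duplication, the event class of that duplication."""
    out: dict[frozenset[str], str] = {}
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf() or getattr(nd, "event", None) != "duplication":
            continue
        call = getattr(nd, "call", None)
        if call is None:
            continue
        children = nd.child_nodes()
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                for a in children[i].leaf_iter():
                    for b in children[j].leaf_iter():
                        out[frozenset([a.taxon.label, b.taxon.label])] = (
                            call.event_class
                        )
    return out


def build_duplication_scheme(
    family_results: dict[str, tuple[dendropy.Tree, list[DuplicationCall], list[OhnologGroup]]],
    species_tree: SpeciesTree,
    teleost_marker: str = "3R",
) -> pd.DataFrame:
    """Per-family event table: WGD epochs, surviving copy counts, per-species
    retained counts, and species in which the family was not identified.

    A species lacking a gene is reported as "not identified" (column
    `not_identified_in`), never as a confirmed loss.
    """
    teleosts: frozenset[str] = frozenset()
    vertebrates: frozenset[str] = frozenset()
    for nd, evs in species_tree.wgd.items():
        if teleost_marker in evs:
            teleosts |= species_tree.leafset(nd)
        if "1R" in evs or "2R" in evs:
            vertebrates |= species_tree.leafset(nd)
    if not vertebrates:
        vertebrates = species_tree.species
    rows = []
    for fam in sorted(family_results):
        tree, calls, groups = family_results[fam]
        species_counts: dict[str, int] = {s: 0 for s in sorted(species_tree.species)}
        for leaf in tree.leaf_node_iter():
            sp = next(iter(leaf.species_set))
            if sp in species_counts:
                species_counts[sp] += 1
        n12 = sum(1 for c in calls if c.event_class == EVENT_1R2R)
        n3 = sum(1 for c in calls if c.event_class == EVENT_3R)
        nloc = sum(1 for c in calls if c.event_class == EVENT_LOCAL)
        post2r = sum(1 for g in groups if g.species & (vertebrates - teleosts))
        post3r = sum(1 for g in groups if g.species and g.species <= teleosts)
        missing = [s for s, c in species_counts.items() if c == 0]
        row = {
            "family_id": fam,
            "n_1R2R_events": n12,
            "n_3R_events": n3,
            "n_lineage_specific_events": nloc,
            "post2R_copies": post2r,
            "post3R_copies": post3r,
            "not_identified_in": ",".join(missing),
        }
        row.update({f"n_{s}": c for s, c in species_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)
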