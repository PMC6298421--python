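"""Protein alignment, region masking, and percent identity.

Pairwise alignment is global Needleman-Wunsch with affine gaps.  The same
dynamic-programming engine aligns sequence-to-sequence and profile-to-profile;
the progressive multiple aligner builds a neighbour-joining guide tree from
pairwise p-distances and merges profiles bottom-up.

Scores are handled internally as integers (substitution scores and gap
penalties are scaled by a fixed factor and rounded), which makes the
deterministic tie-breaking rules exact: on equal scores the traceback prefers
the diagonal move, then the vertical (gap in the second sequence), then the
horizontal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
GAP = "-"

_NEG = np.int64(-(2**40))

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

#: integer scaling applied to substitution scores / gap penalties so that the
#: default half-point gap-extension penalty stays exact.
_PAIR_SCALE = 2
#: finer scaling for profile-profile expected scores (which are averages).
_PROFILE_SCALE = 32


def _blosum62_array() -> np.ndarray:
    """BLOSUM62 as a dense matrix over AA_ALPHABET."""
    m = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    out = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = int(m[a][b])
    return out

BLOSUM62 = _blosum62_array()

_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}


def encode_protein(seq: str) -> np.ndarray:
    """Map a protein string to alphabet indices; reject illegal characters."""
    try:
        return np.array([_AA_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"illegal amino-acid character {exc.args[0]!r}") from None


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences (gapped strings of equal length)."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass
class MSA:
    """A multiple alignment: equal-length gapped rows keyed by sequence id."""

    ids: list[str]
    rows: list[str]
    _colmaps: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in MSA")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("ragged MSA")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column_map(self, seq_id: str) -> np.ndarray:
        """For each residue of `seq_id` (in sequence order), its alignment column."""
        if seq_id not in self._colmaps:
            r = np.frombuffer(self.row(seq_id).encode(), dtype=np.uint8)
            self._colmaps[seq_id] = np.nonzero(r != ord(GAP))[0]
        return self._colmaps[seq_id]

    def column_of(self, seq_id: str, residue_index: int) -> int:
        cm = self.column_map(seq_id)
        if residue_index < 0 or residue_index >= cm.size:
            raise IndexError(f"residue {residue_index} outside {seq_id}")
        return int(cm[residue_index])


@dataclass
class RegionMask:
    """A set of alignment columns obtained by projecting named residue ranges
    of one reference sequence onto the alignment.

    `mode="include"` keeps the projected columns, `mode="exclude"` keeps the
    complement within [0, width).
    """

    columns: np.ndarray
    mode: str
    named_ranges: dict[str, tuple[int, int]]
    reference: str
    width: int


# ---------------------------------------------------------------------------
# DP engine
# ---------------------------------------------------------------------------

def _nw_core(score: np.ndarray, gap_open: int, gap_extend: int):
    """Integer affine-gap global alignment over a precomputed (n1 x n2) score
    matrix.  Returns (best score, list of (i, j) index pairs with -1 for gap).

    States: M (diagonal), Y (vertical: consumes a row), X (horizontal:
    consumes a column).  Tie order M > Y > X throughout.
    """
    n1, n2 = score.shape
    go, ge = np.int64(gap_open), np.int64(gap_extend)

    M = np.full((n1 + 1, n2 + 1), _NEG, dtype=np.int64)
    X = np.full((n1 + 1, n2 + 1), _NEG, dtype=np.int64)
    Y = np.full((n1 + 1, n2 + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    if n2 > 0:
        X[0, 1:] = -go - ge * np.arange(n2, dtype=np.int64)
    if n1 > 0:
        Y[1:, 0] = -go - ge * np.arange(n1, dtype=np.int64)

    js = np.arange(n2, dtype=np.int64)
    for i in range(1, n1 + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        # M: diagonal from any state at (i-1, j-1)
        diag = np.maximum(np.maximum(prevM[:-1], prevY[:-1]), prevX[:-1])
        M[i, 1:] = diag + score[i - 1]
        # Y: vertical from row i-1, same column
        Y[i] = np.maximum(np.maximum(prevM - go, prevY - ge), prevX - go)
        Y[i, 0] = -go - ge * np.int64(i - 1)
        # X: horizontal within row i.  X[i,j] = max_k<=j-1 (B[k] - go - (j-1-k) ge),
        # computed exactly with a running max in integers.
        B = np.maximum(M[i], Y[i])  # opening a horizontal gap after M or Y
        base = B[:-1] + ge * js  # k = 0..n2-1
        runmax = np.maximum.accumulate(base)
        X[i, 1:] = runmax - go - ge * js

    finals = (M[n1, n2], Y[n1, n2], X[n1, n2])
    state = int(np.argmax(finals))  # argmax returns first max: M > Y > X
    best = int(finals[state])

    # traceback by re-deriving each cell's source; integer arithmetic makes
    # the equality tests exact, and the comparison order realizes the
    # diagonal > up > left tie-break.
    i, j = n1, n2
    path: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == 0:
            want = M[i, j] - score[i - 1, j - 1]
            if M[i - 1, j - 1] == want:
                src = 0
            elif Y[i - 1, j - 1] == want:
                src = 1
            else:
                src = 2
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == 1:
            if i == 1 and j == 0:
                src = 0
            elif M[i - 1, j] - go == Y[i, j]:
                src = 0
            elif Y[i - 1, j] - ge == Y[i, j]:
                src = 1
            else:
                src = 2
            path.append((i - 1, -1))
            i -= 1
        else:
            open_val = max(M[i, j - 1], Y[i, j - 1]) - go
            if open_val == X[i, j]:
                src = 0 if M[i, j - 1] >= Y[i, j - 1] else 1
            else:
                src = 2
            path.append((-1, j - 1))
            j -= 1
        state = src
    path.reverse()
    return best, path


def global_align(
    a: str,
    b: str,
    sub_matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences (affine gaps).

    Defaults: BLOSUM62, gap open 10, gap extend 0.5.  Gap penalties are
    quantized to halves.  Ties resolve diagonal > up > left.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    sub = BLOSUM62 if sub_matrix is None else np.asarray(sub_matrix, dtype=np.int64)
    ea, eb = encode_protein(a), encode_protein(b)
    score = sub[np.ix_(ea, eb)] * _PAIR_SCALE
    go = int(round(gap_open * _PAIR_SCALE))
    ge = int(round(gap_extend * _PAIR_SCALE))
    best, path = _nw_core(score, go, ge)
    ga = "".join(a[i] if i >= 0 else GAP for i, _ in path)
    gb = "".join(b[j] if j >= 0 else GAP for _, j in path)
    return PairwiseAlignment(id_a, id_b, ga, gb, best / _PAIR_SCALE)


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------

def percent_identity(
    aln: PairwiseAlignment | MSA,
    pair: tuple[str, str] | None = None,
    mask: RegionMask | None = None,
) -> float:
    """Percent identity of a sequence pair over the (optionally masked) columns.

    Denominator: columns (within the mask) where at least one of the two
    sequences has a residue; numerator: columns where both have the same
    residue.  Columns gapped in both sequences never count.
    """
    if isinstance(aln, MSA):
        if pair is None:
            if aln.n != 2:
                raise ValueError("pair required for an MSA with more than 2 rows")
            ra, rb = aln.rows
        else:
            ra, rb = aln.row(pair[0]), aln.row(pair[1])
    else:
        ra, rb = aln.aligned_a, aln.aligned_b
    xa = np.frombuffer(ra.encode(), dtype=np.uint8)
    xb = np.frombuffer(rb.encode(), dtype=np.uint8)
    keep = np.ones(xa.size, dtype=bool)
    if mask is not None:
        if mask.width != xa.size:
            raise ValueError("mask width does not match alignment width")
        keep[:] = False
        keep[mask.columns] = True
    g = ord(GAP)
    eligible = keep & ((xa != g) | (xb != g))
    n = int(eligible.sum())
    if n == 0:
        raise ValueError("mask selects no eligible columns; identity undefined")
    ident = int((eligible & (xa == xb) & (xa != g)).sum())
    return 100.0 * ident / n


def mask_from_regions(
    msa: MSA,
    reference_seq_id: str,
    named_ranges: dict[str, tuple[int, int]],
    mode: str = "include",
) -> RegionMask:
    """Project named residue ranges (0-based half-open, on the ungapped
    reference sequence) to alignment columns."""
    if mode not in ("include", "exclude"):
        raise ValueError("mode must be include or exclude")
    cm = msa.column_map(reference_seq_id)
    cols: set[int] = set()
    for name, (start, end) in named_ranges.items():
        if start < 0 or end > cm.size or start > end:
            raise ValueError(
                f"region {name!r} [{start},{end}) outside reference of length {cm.size}"
            )
        cols.update(int(c) for c in cm[start:end])
    if mode == "exclude":
        cols = set(range(msa.width)) - cols
    return RegionMask(
        columns=np.array(sorted(cols), dtype=np.int64),
        mode=mode,
        named_ranges=dict(named_ranges),
        reference=reference_seq_id,
        width=msa.width,
    )


def read_region_file(path) -> dict[str, tuple[int, int]]:
    """Region TSV `name<TAB>start<TAB>end`, 1-based inclusive on the reference
    protein; converted here to 0-based half-open."""
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            name, s, e = parts
            out[name] = (int(s) - 1, int(e))
    return out


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def _guide_aligner():
    """C-backed pairwise aligner with the package's default scoring, used
    only to compute guide-tree p-distances (same optimum as global_align)."""
    from Bio import Align

    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -DEFAULT_GAP_OPEN
    al.extend_gap_score = -DEFAULT_GAP_EXTEND
    al.mode = "global"
    return al


_GUIDE_ALIGNER = None


def _guide_distance(a: str, b: str, self_a: float, self_b: float) -> float:
    """Score-based dissimilarity for the guide tree:
    max(S(a,a), S(b,b)) - S(a,b).  Zero for identical sequences, grows with
    divergence; only relative magnitudes matter for guide-tree shape."""
    global _GUIDE_ALIGNER
    if _GUIDE_ALIGNER is None:
        _GUIDE_ALIGNER = _guide_aligner()
    return max(self_a, self_b) - _GUIDE_ALIGNER.score(a, b)


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(width x |alphabet|) residue counts; gaps contribute nothing."""
    w = len(rows[0])
    counts = np.zeros((w, len(AA_ALPHABET)), dtype=np.int64)
    for r in rows:
        x = np.frombuffer(r.encode(), dtype=np.uint8)
        for i, c in enumerate(AA_ALPHABET):
            counts[:, i] += x == ord(c)
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    # expected substitution score between columns, averaged over residue pairs
    raw = ca @ BLOSUM62.astype(np.float64) @ cb.T / float(na * nb)
    score = np.rint(raw * _PROFILE_SCALE).astype(np.int64)
    go = int(round(gap_open * _PROFILE_SCALE))
    ge = int(round(gap_extend * _PROFILE_SCALE))
    _, path = _nw_core(score, go, ge)
    out_a = ["".join(r[i] if i >= 0 else GAP for i, _ in path) for r in rows_a]
    out_b = ["".join(r[j] if j >= 0 else GAP for _, j in path) for r in rows_b]
    return out_a, out_b


def build_msa(
    seqs: dict[str, str] | list[tuple[str, str]],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MSA:
    """Progressive multiple alignment.

    Guide tree: neighbour joining on pairwise p-distances (UPGMA-free, matches
    the tree module's NJ); profiles are merged in guide-tree postorder.  A
    single input sequence is returned unchanged with a warning.  Deterministic
    given the inputs.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(items) == 0:
        raise ValueError("no sequences")
    if len(items) == 1:
        warnings.warn("single sequence: returning 1-row MSA", stacklevel=2)
        return MSA([items[0][0]], [items[0][1]])
    if len(items) == 2:
        aln = global_align(
            items[0][1], items[1][1], gap_open=gap_open, gap_extend=gap_extend
        )
        return MSA(ids, [aln.aligned_a, aln.aligned_b])

    n = len(items)
    selfs = [
        float(np.sum(BLOSUM62[e, e])) for e in (encode_protein(s) for _, s in items)
    ]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _guide_distance(
                items[i][1], items[j][1], selfs[i], selfs[j]
            )

    order = _guide_merge_order(dm)
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [items[i][1]]) for i in range(n)
    }
    nxt = n
    for a, b in order:
        ids_a, rows_a = profiles.pop(a)
        ids_b, rows_b = profiles.pop(b)
        new_a, new_b = _align_profiles(rows_a, rows_b, gap_open, gap_extend)
        profiles[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (final_ids, final_rows), = profiles.values()
    # restore input order
    lookup = dict(zip(final_ids, final_rows))
    return MSA(ids, [lookup[i] for i in ids])


def _guide_merge_order(dm: np.ndarray) -> list[tuple[int, int]]:
    """Neighbour-joining agglomeration order on a distance matrix.

    Returns the sequence of (cluster_a, cluster_b) merges with new clusters
    numbered n, n+1, ...; ties break on the smallest (i, j) pair.
    """
    n = dm.shape[0]
    active = list(range(n))
    d = {(i, j): dm[i, j] for i in range(n) for j in range(n) if i != j}
    nxt = n
    merges: list[tuple[int, int]] = []
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[(i, j)] for j in active if j != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[(i, j)] - r[i] - r[j]
                if best_q is None or q < best_q:
                    best_q, best = q, (i, j)
        i, j = best
        for k in active:
            if k in (i, j):
                continue
            nd = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
            d[(nxt, k)] = d[(k, nxt)] = nd
        active = [k for k in active if k not in (i, j)] + [nxt]
        merges.append((i, j))
        nxt += 1
    merges.append((active[0], active[1]))
    return merges
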