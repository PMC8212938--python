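"""Multiple alignment, distance computation, and neighbor-joining trees.

This module is the phylogenetic engine used to resolve homeologous gene
copies in an allohexaploid proteome: pairwise affine-gap global alignment
(Needleman-Wunsch/Gotoh), guide-tree progressive multiple alignment,
p-distance / Poisson distances with pairwise gap deletion, neighbor joining
with deterministic tie-breaking, and non-parametric bootstrap supports from
column resampling.

All stochastic steps (bootstrap resampling) are driven by a single integer
seed; everything else is deterministic for a fixed input.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "pairwise_global_align",
    "progressive_msa",
    "distance_from_alignment",
    "neighbor_joining",
    "bootstrap_support",
    "leaf_distances",
    "tree_splits",
]

_NEG = -1.0e30
_TRACE_ATOL = 1e-7

_DEFAULT_MATRIX = substitution_matrices.load("BLOSUM62")


class PhyloError(ValueError):
    """Raised for invalid phylogenetic inputs (too few taxa, incomparable pairs)."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A gapped multiple alignment: equal-length rows, one per input sequence."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise PhyloError("names and rows differ in length")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise PhyloError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    names: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.names)
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match names")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0.0):
            raise PhyloError("distance matrix diagonal is not zero")
        if np.any(self.d < 0.0):
            raise PhyloError("distance matrix has negative entries")


@dataclass
class TreeNode:
    """A (sub)tree node; leaves carry labels, edges carry lengths to the parent.

    Unrooted NJ results are represented with a trifurcating root whose own
    ``length`` is ``None``.  ``support`` holds an integer bootstrap percentage
    on internal nodes once computed.
    """

    label: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> list[str]:
        return [lf.label for lf in self.leaves()]

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self


def leaf_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Patristic (path-length) distances between all leaf pairs.

    Edges with ``length is None`` count as zero.
    """
    names = tree.leaf_names()
    index = {nm: i for i, nm in enumerate(names)}
    if len(index) != len(names):
        raise PhyloError("duplicate leaf labels")
    n = len(names)
    d = np.zeros((n, n))

    def rec(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.label: 0.0}
        maps = []
        for c in node.children:
            sub = rec(c)
            ln = c.length or 0.0
            maps.append({k: v + ln for k, v in sub.items()})
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for a, da in maps[i].items():
                    for b, db in maps[j].items():
                        d[index[a], index[b]] = d[index[b], index[a]] = da + db
        merged: dict[str, float] = {}
        for m in maps:
            merged.update(m)
        return merged

    rec(tree)
    return names, d


def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions, canonicalized to the side that excludes
    the alphabetically first leaf."""
    full = frozenset(tree.leaf_names())
    ref = min(full)
    out: set[frozenset] = set()

    def rec(node: TreeNode) -> None:
        for c in node.children:
            if not c.is_leaf:
                side = frozenset(c.leaf_names())
                if ref in side:
                    side = full - side
                if 2 <= len(side) <= len(full) - 2:
                    out.add(side)
                rec(c)

    rec(tree)
    return out


# ---------------------------------------------------------------------------
# pairwise alignment (Gotoh affine-gap global alignment)
# ---------------------------------------------------------------------------


def _matrix_arrays(sub_matrix) -> tuple[dict[str, int], np.ndarray]:
    m = _DEFAULT_MATRIX if sub_matrix is None else sub_matrix
    alphabet = str(m.alphabet)
    return {c: i for i, c in enumerate(alphabet)}, np.asarray(m, dtype=float)


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    try:
        return np.array([index[c] for c in seq], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise PhyloError(f"residue {exc} not in substitution matrix alphabet") from exc


def _gotoh_fill(S: np.ndarray, go: float, ge: float):
    """Fill Gotoh matrices for column-score matrix ``S`` of shape (m, n).

    A gap run of length L costs ``go + (L - 1) * ge``; adjacent gap runs in
    opposite sequences each pay their own opening cost.
    """
    m, n = S.shape
    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)  # gap in the second sequence (move up)
    Iy = np.full((m + 1, n + 1), _NEG)  # gap in the first sequence (move left)
    M[0, 0] = 0.0
    if m:
        Ix[1:, 0] = go + ge * np.arange(m)
    if n:
        Iy[0, 1:] = go + ge * np.arange(n)
    jj = ge * np.arange(n)
    for i in range(1, m + 1):
        prev = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = S[i - 1, :] + prev
        Ix[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + go,
                               Ix[i - 1, 1:] + ge)
        # within-row scan for Iy: max over k<j of (max(M, Ix)[i, k] + go + (j-1-k) ge)
        t = np.maximum(M[i, :-1], Ix[i, :-1]) + go - jj
        Iy[i, 1:] = np.maximum.accumulate(t) + jj
    return M, Ix, Iy


def _pick_state(candidates: Sequence[tuple[str, float]], target: float) -> str:
    for state, value in candidates:
        if abs(value - target) <= _TRACE_ATOL:
            return state
    # numerically closest as a fallback; should not trigger for exact fills
    return max(candidates, key=lambda sv: sv[1])[0]


def _gotoh(S: np.ndarray, go: float, ge: float) -> tuple[float, list[str]]:
    """Optimal global alignment score and move list ('D', 'U', 'L').

    Ties are broken preferring diagonal, then up, then left.
    """
    m, n = S.shape
    M, Ix, Iy = _gotoh_fill(S, go, ge)
    score = max(M[m, n], Ix[m, n], Iy[m, n])
    state = _pick_state([("M", M[m, n]), ("X", Ix[m, n]), ("Y", Iy[m, n])], score)
    moves: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i == 0:
            moves.append("L")
            j -= 1
            continue
        if j == 0:
            moves.append("U")
            i -= 1
            continue
        if state == "M":
            moves.append("D")
            target = M[i, j] - S[i - 1, j - 1]
            state = _pick_state(
                [("M", M[i - 1, j - 1]), ("X", Ix[i - 1, j - 1]), ("Y", Iy[i - 1, j - 1])],
                target,
            )
            i -= 1
            j -= 1
        elif state == "X":
            moves.append("U")
            state = _pick_state(
                [("M", M[i - 1, j] + go), ("X", Ix[i - 1, j] + ge), ("Y", Iy[i - 1, j] + go)],
                Ix[i, j],
            )
            i -= 1
        else:
            moves.append("L")
            state = _pick_state(
                [("M", M[i, j - 1] + go), ("X", Ix[i, j - 1] + ge), ("Y", Iy[i, j - 1] + go)],
                Iy[i, j],
            )
            j -= 1
    moves.reverse()
    return float(score), moves


def pairwise_global_align(
    a: str,
    b: str,
    sub_matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> tuple[float, tuple[str, str]]:
    """Optimal affine-gap global alignment of two protein sequences.

    Returns ``(score, (aligned_a, aligned_b))``.  Gap runs of length L cost
    ``gap_open + (L - 1) * gap_extend``.  Traceback is deterministic: on ties
    the diagonal move is preferred, then up (gap in ``b``), then left.
    """
    index, mat = _matrix_arrays(sub_matrix)
    ia, ib = _encode(a, index), _encode(b, index)
    S = mat[np.ix_(ia, ib)] if len(a) and len(b) else np.zeros((len(a), len(b)))
    score, moves = _gotoh(S, float(gap_open), float(gap_extend))
    ra, rb = [], []
    i = j = 0
    for mv in moves:
        if mv == "D":
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif mv == "U":
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    return score, ("".join(ra), "".join(rb))


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------


def _kmer_vector(seq: str, k: int) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def _kmer_cosine(a: Counter, b: Counter) -> float:
    if not a and not b:
        return 0.0
    if not a or not b:
        return 1.0
    dot = sum(v * b[key] for key, v in a.items())
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    return 1.0 - dot / (na * nb)


def _profile_freq(rows: list[str], index: dict[str, int], n_letters: int) -> np.ndarray:
    """Column frequency vectors; gaps carry zero mass (gap pairs score 0)."""
    L = len(rows[0])
    F = np.zeros((L, n_letters))
    for row in rows:
        for pos, c in enumerate(row):
            if c != "-":
                F[pos, index[c]] += 1.0
    return F / len(rows)


def progressive_msa(
    sequences: Sequence[str],
    names: Sequence[str] | None = None,
    sub_matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    k: int = 3,
) -> Alignment:
    """Guide-tree progressive multiple alignment.

    The guide tree is UPGMA on k-mer (default k=3) cosine distances; profiles
    are merged by affine-gap profile-profile alignment scored with the
    mean-of-pairs substitution score (gap pairs contribute 0).  Output rows
    are returned in input order; degapping row i recovers input sequence i.
    """
    seqs = list(sequences)
    if not seqs:
        raise PhyloError("no sequences to align")
    if names is None:
        names = [f"s{i + 1}" for i in range(len(seqs))]
    names = list(names)
    if len(names) != len(seqs):
        raise PhyloError("names and sequences differ in length")
    if len(seqs) == 1:
        return Alignment(names, [seqs[0]])

    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    index, mat = _matrix_arrays(sub_matrix)
    n = len(seqs)
    vecs = [_kmer_vector(s, k) for s in seqs]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_cosine(vecs[i], vecs[j])
    Z = linkage(squareform(D, checks=False), method="average")

    # cluster id -> (row indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    nl = mat.shape[0]
    go, ge = float(gap_open), float(gap_extend)
    for step, (ca, cb, _, _) in enumerate(Z):
        ia_idx, rows_a = clusters.pop(int(ca))
        ib_idx, rows_b = clusters.pop(int(cb))
        Fa = _profile_freq(rows_a, index, nl)
        Fb = _profile_freq(rows_b, index, nl)
        S = Fa @ mat @ Fb.T
        _, moves = _gotoh(S, go, ge)
        new_a = [[] for _ in rows_a]
        new_b = [[] for _ in rows_b]
        i = j = 0
        for mv in moves:
            if mv == "D":
                for r, row in zip(new_a, rows_a):
                    r.append(row[i])
                for r, row in zip(new_b, rows_b):
                    r.append(row[j])
                i += 1
                j += 1
            elif mv == "U":
                for r, row in zip(new_a, rows_a):
                    r.append(row[i])
                for r in new_b:
                    r.append("-")
                i += 1
            else:
                for r in new_a:
                    r.append("-")
                for r, row in zip(new_b, rows_b):
                    r.append(row[j])
                j += 1
        clusters[n + step] = (
            ia_idx + ib_idx,
            ["".join(r) for r in new_a] + ["".join(r) for r in new_b],
        )
    (indices, rows), = clusters.values()
    order = np.argsort(indices)
    return Alignment([names[indices[o]] for o in order], [rows[o] for o in order])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

_CODE_ALPHABET = "ACDEFGHIKLMNPQRSTVWYXBZU*"


def _encode_alignment(aln: Alignment) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(_CODE_ALPHABET):
        lut[ord(c)] = i
    arr = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8)
    codes = lut[arr].reshape(len(aln.rows), aln.n_columns)
    return codes


def distance_from_alignment(aln: Alignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances from a multiple alignment.

    ``p_distance`` is mismatches over compared columns with pairwise deletion
    of gap columns; ``poisson`` is the corrected distance ``-ln(1 - p)``.
    """
    if len(aln.rows) < 2:
        raise PhyloError("need at least two rows")
    if model not in ("p_distance", "poisson"):
        raise PhyloError(f"unknown distance model: {model!r}")
    codes = _encode_alignment(aln)
    n = len(aln.rows)
    d = np.zeros((n, n))
    for i in range(n):
        vi = codes[i]
        block = codes[i + 1:]
        valid = (vi >= 0)[None, :] & (block >= 0)
        comp = valid.sum(axis=1)
        if np.any(comp == 0):
            j = i + 1 + int(np.argmax(comp == 0))
            raise PhyloError(
                f"no comparable columns between {aln.names[i]!r} and {aln.names[j]!r}"
            )
        mism = ((block != vi[None, :]) & valid).sum(axis=1)
        p = mism / comp
        if model == "poisson":
            if np.any(p >= 1.0):
                j = i + 1 + int(np.argmax(p >= 1.0))
                raise PhyloError(
                    f"poisson distance undefined (p = 1) for {aln.names[i]!r} "
                    f"and {aln.names[j]!r}"
                )
            p = -np.log1p(-p)
        d[i, i + 1:] = p
        d[i + 1:, i] = p
    return DistanceMatrix(list(aln.names), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix, trace: list | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i, j) = (n-2) d(i, j) - R_i - R_j is
    joined; ties are broken by the smallest (i, j) index pair in the current
    matrix (the merged node is appended at the end).  Negative branch-length
    estimates are clamped to zero with the deficit transferred to the sister
    branch.  The result carries a trifurcating root.  If ``trace`` is a list,
    the chosen (i, j) of every agglomeration step is appended to it.
    """
    if len(dm.names) < 3:
        raise PhyloError("neighbor joining needs at least three taxa")
    items: list[TreeNode] = [TreeNode(label=nm) for nm in dm.names]
    D = dm.d.copy()
    while len(items) > 3:
        n = len(items)
        R = D.sum(axis=1)
        Q = (n - 2.0) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # ties (within float noise) broken by the smallest (i, j) pair
        qmin = Q.min()
        tol = 1e-9 * max(1.0, abs(qmin))
        i, j = (int(x) for x in np.argwhere(Q <= qmin + tol)[0])
        if i > j:
            i, j = j, i
        if trace is not None:
            trace.append((i, j))
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (n - 2.0))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        items[i].length = li
        items[j].length = lj
        parent = TreeNode(children=[items[i], items[j]])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [x for x in range(n) if x not in (i, j)]
        row = dnew[keep]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = row
        D2[:-1, -1] = row
        D = D2
        items = [items[x] for x in keep] + [parent]
    dxy, dxz, dyz = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (dxy + dxz - dyz),
        0.5 * (dxy + dyz - dxz),
        0.5 * (dxz + dyz - dxy),
    ]
    for node, ln in zip(items, lengths):
        node.length = max(ln, 0.0)
    return TreeNode(children=items)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    sequences: Sequence[str],
    n_reps: int = 100,
    seed: int = 0,
    names: Sequence[str] | None = None,
    model: str = "p_distance",
    sub_matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> TreeNode:
    """NJ tree with bootstrap supports from alignment-column resampling.

    Columns are resampled with replacement ``n_reps`` times; the support of an
    internal edge is the percentage of replicate trees containing the same
    leaf bipartition.  Reproducible for a fixed ``seed``.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    aln = progressive_msa(sequences, names=names, sub_matrix=sub_matrix,
                          gap_open=gap_open, gap_extend=gap_extend)
    tree = neighbor_joining(distance_from_alignment(aln, model))
    L = aln.n_columns
    grid = np.array([list(r) for r in aln.rows])
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = Alignment(list(aln.names), ["".join(row[cols]) for row in grid])
        counts.update(tree_splits(neighbor_joining(distance_from_alignment(rep, model))))

    full = frozenset(aln.names)
    ref = min(full)

    def annotate(node: TreeNode) -> None:
        for c in node.children:
            if not c.is_leaf:
                side = frozenset(c.leaf_names())
                if ref in side:
                    side = full - side
                if 2 <= len(side) <= len(full) - 2:
                    c.support = round(100.0 * counts[side] / n_reps)
                annotate(c)

    annotate(tree)
    return tree
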