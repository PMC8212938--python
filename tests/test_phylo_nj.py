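"""Neighbor joining: closed-form checks, additive recovery, Q-argmin oracle,
independent-library cross-check, and bootstrap behaviour."""
from __future__ import annotations

import numpy as np
import pytest

from familymap.phylo import (
    DistanceMatrix,
    PhyloError,
    TreeNode,
    bootstrap_support,
    leaf_distances,
    neighbor_joining,
    tree_splits,
)


# ---------------------------------------------------------------------------
# oracles (independent of the package implementation)
# ---------------------------------------------------------------------------


def random_additive_tree(n: int, rng: np.random.Generator):
    """A random unrooted binary tree as (edge list, leaf labels); edge
    lengths uniform in [0.05, 1]."""
    labels = [f"L{i}" for i in range(n)]
    nodes = list(range(n))
    edges = []
    nxt = n
    while len(nodes) > 3 if n > 3 else len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        edges.append((a, nxt, rng.uniform(0.05, 1.0)))
        edges.append((b, nxt, rng.uniform(0.05, 1.0)))
        nxt += 1
    hub = nxt
    for a in nodes:
        edges.append((a, hub, rng.uniform(0.05, 1.0)))
    return edges, labels


def path_length_matrix(edges, labels):
    """All-pairs leaf distances by breadth-first traversal of the edge list."""
    adj = {}
    for a, b, w in edges:
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j in range(n):
            d[i, j] = dist[j]
    return d


def edge_splits(edges, labels):
    """Non-trivial bipartitions of the true tree, canonicalized as in
    tree_splits (side excluding the alphabetically first leaf)."""
    adj = {}
    for a, b, w in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    leaf_ids = set(range(len(labels)))
    full = frozenset(labels)
    ref = min(full)
    splits = set()
    for a, b, _ in edges:
        # leaves on the a-side of edge (a, b)
        seen = {a, b}
        stack = [a]
        side = set()
        while stack:
            u = stack.pop()
            if u in leaf_ids:
                side.add(labels[u])
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        fs = frozenset(side)
        if ref in fs:
            fs = full - fs
        if 2 <= len(fs) <= len(full) - 2:
            splits.add(fs)
    return splits


def nj_steps_oracle(d0: np.ndarray):
    """Exhaustive-scan NJ join order: at each step scan all (i, j) pairs in
    lexicographic order for the strict Q minimum, then update the matrix with
    the merged node appended at the end."""
    D = d0.copy()
    steps = []
    n = D.shape[0]
    while n > 3:
        R = D.sum(axis=1)
        qs = {
            (i, j): (n - 2) * D[i, j] - R[i] - R[j]
            for i in range(n)
            for j in range(i + 1, n)
        }
        qmin = min(qs.values())
        tol = 1e-9 * max(1.0, abs(qmin))
        i, j = min(p for p, q in qs.items() if q <= qmin + tol)
        steps.append((i, j))
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        row = dnew[keep]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = row
        D2[:-1, -1] = row
        D = D2
        n -= 1
    return steps


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def test_three_taxon_closed_form():
    d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
    lengths = {c.label: c.length for c in tree.children}
    assert lengths == {"a": 0.5, "b": 1.5, "c": 2.5}


def test_fewer_than_three_taxa_is_an_error():
    d = np.array([[0, 1], [1, 0]], float)
    with pytest.raises(PhyloError):
        neighbor_joining(DistanceMatrix(["a", "b"], d))


def test_nj_recovers_random_additive_trees_exactly():
    """On additive matrices NJ must reproduce the generating topology and the
    full path-length matrix to 1e-9 (30 random trees, n <= 8)."""
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = int(rng.integers(4, 9))
        edges, labels = random_additive_tree(n, rng)
        d_true = path_length_matrix(edges, labels)
        tree = neighbor_joining(DistanceMatrix(labels, d_true))
        names, d_est = leaf_distances(tree)
        order = [names.index(l) for l in labels]
        assert np.abs(d_est[order][:, order] - d_true).max() < 1e-9
        assert tree_splits(tree) == edge_splits(edges, labels)


def test_nj_pair_choice_matches_exhaustive_q_argmin():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        edges, labels = random_additive_tree(n, rng)
        d = path_length_matrix(edges, labels)
        trace: list = []
        neighbor_joining(DistanceMatrix(labels, d), trace=trace)
        assert trace == nj_steps_oracle(d)


def test_nj_topology_agrees_with_scikit_bio():
    import skbio

    rng = np.random.default_rng(99)
    for _ in range(5):
        n = int(rng.integers(5, 9))
        edges, labels = random_additive_tree(n, rng)
        d = path_length_matrix(edges, labels)
        d = 0.5 * (d + d.T)  # exact symmetry for skbio's strict validation
        ours = neighbor_joining(DistanceMatrix(labels, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        full = frozenset(labels)
        anchor = min(full)
        ref_splits = set()
        for node in ref.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = full - side
            if 2 <= len(side) <= len(full) - 2:
                ref_splits.add(side)
        assert tree_splits(ours) == ref_splits


def test_negative_branch_estimates_are_clamped_with_transfer():
    # a non-additive matrix known to produce a negative two-point estimate
    d = np.array(
        [
            [0.0, 0.1, 0.6, 0.65],
            [0.1, 0.0, 0.6, 0.05],
            [0.6, 0.6, 0.0, 0.7],
            [0.65, 0.05, 0.7, 0.0],
        ]
    )
    tree = neighbor_joining(DistanceMatrix(list("abcd"), d))
    for node in tree.postorder():
        if node.length is not None:
            assert node.length >= 0.0


def _two_clade_sequences():
    rng = np.random.default_rng(3)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    base1 = "".join(rng.choice(aa, size=40))
    base2 = "".join(rng.choice(aa, size=40))
    seqs, names = [], []
    for k in range(4):
        s = list(base1)
        s[k] = "W" if s[k] != "W" else "Y"
        seqs.append("".join(s))
        names.append(f"one{k}")
    for k in range(4):
        s = list(base2)
        s[k] = "W" if s[k] != "W" else "Y"
        seqs.append("".join(s))
        names.append(f"two{k}")
    return seqs, names


@pytest.mark.parametrize("seed", [0, 12345])
def test_two_separated_clades_get_full_support(seed):
    seqs, names = _two_clade_sequences()
    tree = bootstrap_support(seqs, n_reps=100, seed=seed, names=names)
    split = frozenset(n for n in names if n.startswith("two"))
    supports = {
        frozenset(c.leaf_names())
        if "one0" not in c.leaf_names()
        else frozenset(tree.leaf_names()) - frozenset(c.leaf_names()): c.support
        for c in tree.postorder()
        if not c.is_leaf and c is not tree
    }
    assert supports.get(split) == 100


def test_single_replicate_supports_are_all_or_nothing():
    seqs, names = _two_clade_sequences()
    tree = bootstrap_support(seqs, n_reps=1, seed=4, names=names)
    sup = [c.support for c in tree.postorder() if not c.is_leaf and c.support is not None]
    assert sup and all(s in (0, 100) for s in sup)


def test_bootstrap_is_reproducible_for_a_fixed_seed():
    seqs, names = _two_clade_sequences()
    t1 = bootstrap_support(seqs, n_reps=25, seed=8, names=names)
    t2 = bootstrap_support(seqs, n_reps=25, seed=8, names=names)

    def dump(t):
        return sorted(
            (tuple(sorted(c.leaf_names())), c.support)
            for c in t.postorder()
            if not c.is_leaf
        )

    assert dump(t1) == dump(t2)
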