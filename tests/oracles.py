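"""Independent brute-force oracles used only by the test suite.

These re-derive expected values by the most literal method available —
single-base neighbor enumeration for synonymous/nonsynonymous counting
(translation via Bio.Seq, not the package's code table), and exhaustive
tree-topology enumeration with unconstrained least-squares branch lengths
for distance-tree checks. They deliberately share no code with mlsakit.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_stop(codon: str) -> bool:
    return _aa(codon) == "*"


def ng_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts by neighbor enumeration."""
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if not _is_stop(mut) and _aa(mut) == _aa(codon):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def ng_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Observed syn/nonsyn differences averaged over minimal mutation
    pathways that avoid stop codons (all pathways if none avoid them)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    all_paths = []
    clean_paths = []
    for order in itertools.permutations(positions):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            if _is_stop(nxt):
                blocked = True
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            clean_paths.append(steps)
    paths = clean_paths or all_paths
    syn = nonsyn = 0.0
    for steps in paths:
        for a, b in steps:
            if not _is_stop(a) and not _is_stop(b) and _aa(a) == _aa(b):
                syn += 1.0
            else:
                nonsyn += 1.0
    return syn / len(paths), nonsyn / len(paths)


def ng_pairwise(seq1: str, seq2: str) -> tuple[float, float]:
    """(dN, dS) for one in-frame pair of coding sequences."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for k in range(len(seq1) // 3):
        a, b = seq1[3 * k:3 * k + 3], seq2[3 * k:3 * k + 3]
        if _is_stop(a) or _is_stop(b):
            continue
        s1, n1 = ng_site_counts(a)
        s2, n2 = ng_site_counts(b)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = ng_diff_counts(a, b)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N
    assert pS < 0.75 and pN < 0.75, "oracle input saturated"
    dS = -0.75 * math.log(1.0 - 4.0 * pS / 3.0)
    dN = -0.75 * math.log(1.0 - 4.0 * pN / 3.0)
    return dN, dS


# ---------------------------------------------------------------------------
# Exhaustive topology search

def enumerate_topologies(n_leaves: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies over leaves 0..n-1 as edge lists.

    Internal nodes are numbered from n upward. Built by inserting each
    successive leaf into every edge of every smaller topology (yields
    1, 3, 15, 105 trees for 4..6 leaves... starting from the single
    3-leaf star)."""
    assert 3 <= n_leaves <= 6
    star = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    trees = [(star, n_leaves + 1)]
    for leaf in range(3, n_leaves):
        nxt = []
        for edges, next_id in trees:
            for k, (u, v) in enumerate(edges):
                new_edges = edges[:k] + edges[k + 1:]
                w = next_id
                new_edges = new_edges + [(u, w), (w, v), (leaf, w)]
                nxt.append((new_edges, next_id + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _paths(edges: list[tuple[int, int]], n_leaves: int):
    """For each leaf pair, the set of edge indices on the path."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path(src: int, dst: int) -> list[int]:
        stack = [(src, -1, [])]
        while stack:
            node, parent, used = stack.pop()
            if node == dst:
                return used
            for nbr, eidx in adj[node]:
                if nbr != parent:
                    stack.append((nbr, node, used + [eidx]))
        raise AssertionError("disconnected topology")

    out = {}
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            out[(i, j)] = path(i, j)
    return out


def ls_fit_rss(edges, n_leaves: int, dist: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares branch lengths for one topology; returns (RSS, b)."""
    pairs = _paths(edges, n_leaves)
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for row, ((i, j), eidxs) in enumerate(pairs.items()):
        A[row, eidxs] = 1.0
        d[row] = dist[i, j]
    b, *_ = np.linalg.lstsq(A, d, rcond=None)
    rss = float(np.sum((A @ b - d) ** 2))
    return rss, b


def topology_bipartitions(edges, n_leaves: int) -> set[frozenset[int]]:
    """Non-trivial leaf bipartitions of a topology (smaller-side canonical:
    the side not containing leaf 0)."""
    out = set()
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    for cut, (u, v) in enumerate(edges):
        # leaves reachable from u without crossing the cut edge
        seen = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nbr, eidx in adj[node]:
                if eidx != cut and nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        side = frozenset(x for x in seen if x < n_leaves)
        if len(side) < 2 or n_leaves - len(side) < 2:
            continue
        out.add(side if 0 not in side else
                frozenset(range(n_leaves)) - side)
    return out


def best_ls_topology(dist: np.ndarray) -> set[frozenset[int]]:
    """Bipartition set of the minimum-RSS topology for a distance matrix."""
    n = dist.shape[0]
    best_rss, best_edges = None, None
    for edges in enumerate_topologies(n):
        rss, _ = ls_fit_rss(edges, n, dist)
        if best_rss is None or rss < best_rss:
            best_rss, best_edges = rss, edges
    return topology_bipartitions(best_edges, n)


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, set[frozenset[int]]]:
    """Random binary tree over n leaves -> (path-length matrix, true
    bipartitions). Internal edges kept well away from zero."""
    edges = enumerate_topologies(n)[rng.integers(len(enumerate_topologies(n)))]
    lengths = {}
    for e in edges:
        is_external = min(e) < n
        lengths[e] = rng.uniform(0.5, 2.0) if is_external else \
            rng.uniform(0.3, 1.5)
    dist = np.zeros((n, n))
    paths = _paths(edges, n)
    for (i, j), eidxs in paths.items():
        d = sum(lengths[edges[k]] for k in eidxs)
        dist[i, j] = dist[j, i] = d
    return dist, topology_bipartitions(edges, n)
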