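"""Distance-based trees and threshold clustering.

Builds neighbor-joining trees from similarity matrices (branch lengths in
substitutions-per-site units), attaches nonparametric bootstrap supports by
column resampling of the concatenated alignment, and extracts clades by
single-linkage clustering at a similarity threshold.

The NJ rules are pinned for reproducibility: ties in the Q criterion break
toward the lowest index pair, and a negative estimated branch length is
clamped to zero with the deficit transferred to its sibling edge so the
joined pair's distance is preserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Sequence

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import diversity
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    MatrixShapeError,
    SaturationError,
    SerializationError,
)
from .seqio import GeneAlignment, SimilarityMatrix

__all__ = [
    "Node",
    "PhyloTree",
    "DistanceMatrix",
    "Partition",
    "to_distance",
    "nj_tree",
    "bootstrap_supports",
    "clades_at_threshold",
    "tree_from_newick",
]

#: internal edges at or below this length are treated as unresolved
#: (star-like) and carry no bootstrap support
ZERO_EDGE = 1e-12


@dataclass
class Node:
    """A tree node: leaves carry ``name``; internal nodes may carry an
    integer bootstrap ``support`` (percent)."""

    name: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name] if self.name is not None else [None]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


@dataclass
class PhyloTree:
    """Unrooted tree (represented with a basal multifurcation) over a
    strain set, with branch lengths and optional supports."""

    root: Node

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(self.root.leaf_names())

    def to_newick(self) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                if not node.name:
                    raise SerializationError("unnamed leaf cannot be written")
                s = node.name
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.support is not None:
                    s += str(int(node.support))
            if node.length is not None:
                s += f":{_fmt_len(node.length)}"
            return s

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner});" if self.root.children else f"{self.root.name};"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as canonical leaf sets (the side not
        containing the lexicographically smallest leaf)."""
        all_leaves = frozenset(self.leaves)
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            out.add(side if ref not in side else all_leaves - side)
        return out

    def path_lengths(self) -> "DistanceMatrix":
        """Leaf-to-leaf path length matrix (tree additivity check)."""
        leaves = sorted(self.leaves)
        index = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        dist = np.zeros((n, n))

        def below(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: node.length or 0.0}
            groups = [below(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            d = da + db
                            dist[index[a], index[b]] = d
                            dist[index[b], index[a]] = d
            merged: dict[str, float] = {}
            for g in groups:
                merged.update(g)
            return {a: d + (node.length or 0.0) for a, d in merged.items()}

        below(self.root)
        return DistanceMatrix(tuple(leaves), dist)


@dataclass
class DistanceMatrix:
    """Square distance matrix with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixShapeError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise MatrixShapeError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise MatrixShapeError("distance matrix diagonal must be zero")


@dataclass(frozen=True)
class Partition:
    """Disjoint clusters covering all strains exactly once."""

    clusters: tuple[frozenset[str], ...]
    method: str


# ---------------------------------------------------------------------------

def to_distance(
    m: SimilarityMatrix, correction: str = "none"
) -> DistanceMatrix:
    """Convert percent identity to evolutionary distance.

    ``none``: d = 1 - sim/100. ``jukes-cantor``: the standard multiple-hit
    correction; similarities at or below 25% are saturated and rejected.
    """
    if m.metric != "identity":
        raise InvalidParameterError(
            f"distances require an identity matrix, got {m.metric!r}"
        )
    p = 1.0 - m.values / 100.0
    if correction == "none":
        d = p
    elif correction == "jukes-cantor":
        if np.any(p >= 0.75 - np.finfo(float).eps):
            raise SaturationError(
                "similarity <= 25% cannot be Jukes-Cantor corrected"
            )
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
    else:
        raise InvalidParameterError(f"unknown correction {correction!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(m.strain_ids, d)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, shifting the deficit onto the
    sibling so li + lj is preserved; a still-negative sibling is floored."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining agglomeration (Saitou & Nei / Studier-Keppler Q
    criterion) with deterministic tie-breaking."""
    n = len(dm.ids)
    if n < 2:
        raise InsufficientDataError("nj_tree needs >= 2 taxa")
    if n == 2:
        d = float(dm.values[0, 1])
        return PhyloTree(
            Node(children=[
                Node(name=dm.ids[0], length=d / 2.0),
                Node(name=dm.ids[1], length=d / 2.0),
            ])
        )

    nodes: list[Node] = [Node(name=s) for s in dm.ids]
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index pair among ties
        qmin = Q.min()
        ti, tj = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))[0]
        if ti > tj:
            ti, tj = tj, ti
        i, j = active[ti], active[tj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ti] - r[tj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = Node(children=[child_i, child_j])
        # distances from new node to remaining actives
        rest = [a for a in active if a not in (i, j)]
        u = len(D)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in rest:
            D[u, k] = D[k, u] = max(0.5 * (D[i, k] + D[j, k] - dij), 0.0)
        nodes.append(new)
        active = rest + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return PhyloTree(Node(children=[nodes[a], nodes[b], nodes[c]]))


# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def bootstrap_supports(
    alignments: Sequence[GeneAlignment],
    n_reps: int = 1000,
    seed: int = 0,
    gap_policy: str = "pairwise-deletion",
    correction: str = "none",
) -> PhyloTree:
    """NJ tree of the concatenation with bootstrap supports.

    Columns of the concatenated alignment are resampled with replacement
    ``n_reps`` times; each replicate is run through identity -> distance ->
    NJ and the support of each original internal edge is the percentage of
    replicates containing its bipartition. Deterministic given ``seed``.
    Internal edges of (numerically) zero length carry no support, so a
    signal-free alignment cannot be reported as strongly resolved.
    """
    from . import mlsa  # local import: mlsa does not import phylo

    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    concat = mlsa.concatenate(list(alignments))
    base_sim = diversity.pairwise_identity(concat, gap_policy)
    tree = nj_tree(to_distance(base_sim, correction))

    arr = concat.to_array()
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    ids = concat.strain_ids
    nstrain, ncol = arr.shape
    pair_idx = [(i, j) for i in range(nstrain) for j in range(i + 1, nstrain)]
    eq = np.stack([(arr[i] == arr[j]) & valid[i] & valid[j]
                   for i, j in pair_idx])
    ok = np.stack([valid[i] & valid[j] for i, j in pair_idx])

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    target = tree.bipartitions()
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        matches = eq[:, cols].sum(axis=1)
        comp = ok[:, cols].sum(axis=1)
        # a pair with no sampled comparable columns scores 0 matches of 1
        comp = np.maximum(comp, 1)
        sim = np.full((nstrain, nstrain), 100.0)
        for (i, j), mt, cp in zip(pair_idx, matches, comp):
            sim[i, j] = sim[j, i] = 100.0 * mt / cp
        rep_tree = nj_tree(
            to_distance(SimilarityMatrix(ids, sim, "identity"), correction)
        )
        for bp in rep_tree.bipartitions() & target:
            counts[bp] = counts.get(bp, 0) + 1

    all_leaves = frozenset(ids)
    ref = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if node.length is not None and node.length <= ZERO_EDGE:
            node.support = None
            continue
        bp = side if ref not in side else all_leaves - side
        node.support = _round_half_up(100.0 * counts.get(bp, 0) / n_reps)
    return tree


def clades_at_threshold(
    m: SimilarityMatrix, threshold: float, linkage: str = "single"
) -> Partition:
    """Single-linkage clusters: strains co-cluster iff connected by a chain
    of pairs with similarity >= threshold."""
    if linkage != "single":
        raise InvalidParameterError(f"unsupported linkage {linkage!r}")
    if not (0.0 < threshold <= 100.0):
        raise InvalidParameterError(
            f"threshold {threshold} outside (0, 100]"
        )
    adj = (m.values >= threshold).astype(np.int8)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = []
    for k in range(n_comp):
        clusters.append(
            frozenset(s for s, lab in zip(m.strain_ids, labels) if lab == k)
        )
    clusters.sort(key=lambda c: min(c))
    return Partition(
        clusters=tuple(clusters),
        method=f"single-linkage at {threshold}% {m.metric}",
    )


# ---------------------------------------------------------------------------
# Newick parsing (via dendropy; serialisation is PhyloTree.to_newick)

def tree_from_newick(newick: str) -> PhyloTree:
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(
                name=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length,
            )
        support = None
        if dnode.label is not None:
            try:
                support = int(float(dnode.label))
            except ValueError:
                support = None
        return Node(
            length=dnode.edge.length,
            support=support,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dtree.seed_node)
    root.length = None
    return PhyloTree(root)
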