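"""Distance trees: neighbor joining, UPGMA, bootstrap support and
majority-rule consensus, with Newick I/O via scikit-bio's TreeNode.

Determinism: agglomeration ties are broken by the smallest (i, j) index pair
under stable ordering, so a given matrix always yields the same tree.
Negative NJ branch lengths are clamped to 0 (no redistribution).
"""

from __future__ import annotations

import math
import warnings
from io import StringIO
from typing import Callable

import numpy as np
from skbio import TreeNode

from .alignment import Alignment
from .distances import DistanceError, DistanceMatrix, SaturationError, distance_matrix
from .partition import Partition

__all__ = [
    "nj",
    "upgma",
    "bootstrap_support",
    "majority_consensus",
    "bipartitions",
    "is_monophyletic",
    "is_ultrametric",
    "tip_distance_matrix",
    "read_newick",
    "write_newick",
]


def _check_matrix(dm: DistanceMatrix) -> np.ndarray:
    if np.isnan(dm.d).any():
        raise DistanceError("tree construction requires all distances defined")
    return dm.d.astype(float, copy=True)


def nj(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining (Q-matrix criterion).

    Returns an unrooted tree represented with a trifurcating root for n >= 3
    (a two-child root for n = 2); tip-to-tip path lengths reproduce an
    additive input matrix exactly.
    """
    D = _check_matrix(dm)
    nodes = [TreeNode(name=s) for s in dm.sample_ids]
    active = list(range(len(nodes)))

    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best, best_q = None, math.inf
        for a in range(n):
            for b in range(a + 1, n):
                q = (n - 2) * sub[a, b] - r[a] - r[b]
                if q < best_q - 1e-15:
                    best, best_q = (a, b), q
        a, b = best
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (n - 2))
        lj = sub[a, b] - li
        parent = TreeNode()
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent.append(nodes[i])
        parent.append(nodes[j])
        # distances from the new node to the remaining actives
        new_row = 0.5 * (D[i, active] + D[j, active] - D[i, j])
        k = i  # reuse slot i for the merged node
        D[k, active] = new_row
        D[active, k] = new_row
        D[k, k] = 0.0
        nodes[k] = parent
        active.remove(j)

    root = TreeNode()
    if len(active) == 2:
        i, j = active
        d = D[i, j]
        nodes[i].length = d / 2.0
        nodes[j].length = d / 2.0
        root.append(nodes[i])
        root.append(nodes[j])
    else:
        i, j, k = active
        li = (D[i, j] + D[i, k] - D[j, k]) / 2.0
        lj = (D[i, j] + D[j, k] - D[i, k]) / 2.0
        lk = (D[i, k] + D[j, k] - D[i, j]) / 2.0
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            nodes[idx].length = max(0.0, ln)
            root.append(nodes[idx])
    return root


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration producing a rooted ultrametric tree."""
    D = _check_matrix(dm)
    nodes = [TreeNode(name=s) for s in dm.sample_ids]
    heights = [0.0] * len(nodes)
    sizes = [1] * len(nodes)
    active = list(range(len(nodes)))

    while len(active) > 1:
        best, best_d = None, math.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                d = D[active[ai], active[bi]]
                if d < best_d - 1e-15:
                    best, best_d = (ai, bi), d
        ai, bi = best
        i, j = active[ai], active[bi]
        h = best_d / 2.0
        parent = TreeNode()
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        parent.append(nodes[i])
        parent.append(nodes[j])
        wi = sizes[i] / (sizes[i] + sizes[j])
        new_row = wi * D[i, active] + (1 - wi) * D[j, active]
        D[i, active] = new_row
        D[active, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        heights[i] = h
        sizes[i] = sizes[i] + sizes[j]
        active.remove(j)
    return nodes[active[0]]


def tip_distance_matrix(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Tip-to-tip path lengths (sums of branch lengths)."""
    sk = tree.tip_tip_distances()
    ids = list(sk.ids)
    return ids, np.asarray(sk.data, dtype=float)


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = []
    for tip in tree.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depths.append(d)
    return max(depths) - min(depths) <= tol


def _clade_sets(tree: TreeNode) -> dict[int, frozenset[str]]:
    out = {}
    for node in tree.postorder():
        if node.is_tip():
            out[id(node)] = frozenset([node.name])
        else:
            s = frozenset().union(*(out[id(c)] for c in node.children))
            out[id(node)] = s
    return out


def _canonical(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    comp = leaves - side
    return min(side, comp, key=lambda s: (len(s), tuple(sorted(s))))


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each as its canonical (smaller) side."""
    clades = _clade_sets(tree)
    leaves = clades[id(tree)]
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = clades[id(node)]
        if 1 < len(side) < len(leaves) - 1:
            out.add(_canonical(side, leaves))
    return out


def is_monophyletic(tree: TreeNode, group) -> bool:
    """Whether the group forms a clade on the unrooted topology."""
    group = frozenset(group)
    clades = _clade_sets(tree)
    leaves = clades[id(tree)]
    if len(group) in (1, len(leaves)):
        return True
    sides = set(clades.values())
    return group in sides or (leaves - group) in sides


_BUILDERS: dict[str, Callable[[DistanceMatrix], TreeNode]] = {}


def _resolve_builder(builder) -> Callable[[DistanceMatrix], TreeNode]:
    if callable(builder):
        return builder
    return {"nj": nj, "upgma": upgma}[builder]


def bootstrap_support(
    aln: Alignment,
    model: str = "K2P",
    builder="nj",
    b: int = 100,
    seed: int = 0,
    deletion: str = "pairwise",
) -> tuple[TreeNode, int]:
    """Column-resampling bootstrap; annotates the original tree with supports.

    Columns are resampled with replacement (globally, not per locus), the
    tree is rebuilt, and bipartition frequencies are counted on the original
    topology.  Replicates with saturated distances are dropped with a warning
    and counted.  Supports are written as internal-node labels (0-100) and as
    a ``support`` attribute.  Returns (tree, n_dropped).
    """
    if b < 1:
        raise ValueError("need B >= 1 replicates")
    build = _resolve_builder(builder)
    dm = distance_matrix(aln, model=model, deletion=deletion)
    tree = build(dm)
    original = bipartitions(tree)
    counts = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    dropped = 0
    effective = 0
    for _ in range(b):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_aln = aln.take_columns(cols)
        try:
            rep_dm = distance_matrix(rep_aln, model=model, deletion=deletion)
        except (SaturationError, DistanceError):
            dropped += 1
            continue
        effective += 1
        rep_bps = bipartitions(build(rep_dm))
        for bp in original & rep_bps:
            counts[bp] += 1
    if dropped:
        warnings.warn(f"dropped {dropped}/{b} saturated bootstrap replicate(s)")
    if effective == 0:
        raise DistanceError("every bootstrap replicate was saturated")
    clades = _clade_sets(tree)
    leaves = clades[id(tree)]
    for node in tree.non_tips(include_self=False):
        side = clades[id(node)]
        if 1 < len(side) < len(leaves) - 1:
            pct = 100.0 * counts[_canonical(side, leaves)] / effective
            node.support = pct
            node.name = f"{pct:g}"
    return tree, dropped


def majority_consensus(trees: list[TreeNode], threshold: float = 0.75) -> TreeNode:
    """Majority-rule consensus: bipartitions at frequency >= threshold kept.

    Internal nodes are labelled with the bipartition frequency (0-100).
    Bipartitions incompatible with higher-frequency ones are skipped (only
    possible for thresholds <= 0.5).
    """
    if not trees:
        raise ValueError("need at least one tree")
    leaf_sets = [frozenset(t.name for t in tr.tips()) for tr in trees]
    leaves = leaf_sets[0]
    if any(ls != leaves for ls in leaf_sets):
        raise ValueError("trees must share the same leaf set")
    counts: dict[frozenset[str], int] = {}
    for tr in trees:
        for bp in bipartitions(tr):
            counts[bp] = counts.get(bp, 0) + 1
    ref = min(leaves)  # orient clusters away from a reference leaf
    selected: list[tuple[frozenset[str], float]] = []
    for bp, c in sorted(
        counts.items(), key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0])))
    ):
        freq = c / len(trees)
        if freq < threshold:
            continue
        cluster = bp if ref not in bp else leaves - bp
        ok = all(
            cluster <= other or other <= cluster or not (cluster & other)
            for other, _ in selected
        )
        if ok:
            selected.append((cluster, freq))

    root = TreeNode()
    node_of: dict[frozenset[str], TreeNode] = {leaves: root}
    for cluster, freq in sorted(selected, key=lambda cf: -len(cf[0])):
        parent_set = min(
            (s for s in node_of if cluster < s), key=len
        )
        node = TreeNode(name=f"{100.0 * freq:g}")
        node.support = 100.0 * freq
        node_of[parent_set].append(node)
        node_of[cluster] = node
    for leaf in sorted(leaves):
        parent_set = min(
            (s for s in node_of if leaf in s), key=len
        )
        node_of[parent_set].append(TreeNode(name=leaf))
    return root


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(source) -> TreeNode:
    if isinstance(source, str) and "(" in source:
        return TreeNode.read(StringIO(source), format="newick")
    return TreeNode.read(str(source), format="newick")
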