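"""Haplotype collapsing and median-joining networks with MP pruning.

Edge weights are mutation steps (Hamming distance over the analyzed columns;
indel/ambiguous columns are expected to have been masked upstream).  Median
vectors are column-wise majority consensus sequences of connected triplets,
added only when they reduce the total connection cost; no quasi-median
expansion is performed (the chief divergence risk relative to the original
median-joining software, whose defaults this mirrors with epsilon = 0).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .alignment import Alignment, SampleRecord
from .partition import Partition

__all__ = [
    "Haplotype",
    "HaplotypeNetwork",
    "collapse_haplotypes",
    "median_joining",
    "mp_prune",
    "cluster_separation",
]


@dataclass
class Haplotype:
    """One observed haplotype: sequence, members and geography counts."""

    hap_id: str
    sequence: str
    members: list[str]
    geography: Counter = field(default_factory=Counter)

    @property
    def multiplicity(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    """Graph over observed haplotypes and median vectors.

    ``graph`` is an undirected networkx Graph; node attributes: ``seq``,
    ``kind`` ('observed' | 'median'), ``multiplicity``, ``members``,
    ``geography``; edge attribute ``weight`` = mutation steps.
    """

    graph: nx.Graph
    epsilon: int = 0

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def total_edge_weight(self) -> float:
        return sum(w for _, _, w in self.graph.edges(data="weight"))

    def connection_cost(self) -> float:
        """Minimum-spanning-tree weight over the current node set."""
        seqs = [self.graph.nodes[n]["seq"] for n in self.graph.nodes]
        return _mst_cost(_hamming_matrix(seqs))

    def shortest_paths(self) -> dict[str, dict[str, float]]:
        return dict(nx.all_pairs_dijkstra_path_length(self.graph, weight="weight"))

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(
                n,
                seq=d["seq"],
                kind=d["kind"],
                multiplicity=d["multiplicity"],
                members=";".join(d["members"]),
                geography=";".join(f"{k}:{v}" for k, v in sorted(d["geography"].items())),
            )
        for u, v, w in self.graph.edges(data="weight"):
            g.add_edge(u, v, weight=int(w))
        nx.write_graphml(g, str(path))

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node1\tnode2\tsteps\n")
            for u, v, w in sorted(self.graph.edges(data="weight")):
                fh.write(f"{u}\t{v}\t{int(w)}\n")


def collapse_haplotypes(
    aln: Alignment, metadata: dict[str, SampleRecord] | None = None
) -> list[Haplotype]:
    """Merge identical rows into haplotypes, numbered by first occurrence."""
    seen: dict[str, Haplotype] = {}
    for sid, row in zip(aln.sample_ids, aln.rows):
        if row not in seen:
            seen[row] = Haplotype(f"H{len(seen) + 1}", row, [])
        h = seen[row]
        h.members.append(sid)
        if metadata and sid in metadata and metadata[sid].geography:
            h.geography[metadata[sid].geography] += 1
    return list(seen.values())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _hamming_matrix(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    n = len(seqs)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        out[i] = (arr != arr[i]).sum(axis=1)
    return out


def _mst_cost(d: np.ndarray) -> float:
    if d.shape[0] < 2:
        return 0.0
    return float(minimum_spanning_tree(d).sum())


def _bottleneck(d: np.ndarray) -> np.ndarray:
    """Minimax path weight between all node pairs (max edge on the MST path)."""
    n = d.shape[0]
    mst = minimum_spanning_tree(d).toarray()
    mst = np.maximum(mst, mst.T)
    g = nx.from_numpy_array(mst)
    bn = np.zeros((n, n))
    for src in range(n):
        # DFS down the MST carrying the running max edge weight
        stack = [(src, -1, 0.0)]
        while stack:
            node, prev, running = stack.pop()
            bn[src, node] = running
            for nb in g.neighbors(node):
                if nb != prev and mst[node, nb] > 0:
                    stack.append((nb, node, max(running, mst[node, nb])))
    return bn


def _msn_edges(d: np.ndarray, epsilon: int) -> list[tuple[int, int]]:
    """Minimum-spanning-network edges: weight within epsilon of the bottleneck."""
    bn = _bottleneck(d)
    n = d.shape[0]
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= bn[i, j] + epsilon
    ]


def _majority_median(a: str, b: str, c: str) -> str | None:
    """Column-wise majority sequence of a triplet; None when any column has
    three distinct states (no majority; quasi-medians are not generated)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            return None
    return "".join(out)


def median_joining(haplos: list[Haplotype], epsilon: int = 0) -> HaplotypeNetwork:
    """Median-joining network over observed haplotypes.

    Iterates {build the minimum spanning network within tolerance epsilon;
    propose majority medians of connected triplets; add the median that most
    reduces the total connection cost} until stable.  The integer connection
    cost strictly decreases at every addition, so the loop terminates.
    """
    if not haplos:
        raise ValueError("need at least one haplotype")
    seqs = [h.sequence for h in haplos]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("haplotypes must share one alignment length")

    node_seqs = list(seqs)
    n_obs = len(seqs)
    while True:
        d = _hamming_matrix(node_seqs)
        edges = _msn_edges(d, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(node_seqs))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: set[str] = set()
        for u in range(len(node_seqs)):
            for v, w in combinations(sorted(adj[u]), 2):
                med = _majority_median(node_seqs[u], node_seqs[v], node_seqs[w])
                if med is not None and med not in node_seqs:
                    candidates.add(med)
        if not candidates:
            break
        base_cost = _mst_cost(d)
        best_seq, best_gain = None, 0.0
        for med in sorted(candidates):
            cost = _mst_cost(_hamming_matrix(node_seqs + [med]))
            gain = base_cost - cost
            if gain > best_gain + 1e-9:
                best_seq, best_gain = med, gain
        if best_seq is None:
            break
        node_seqs.append(best_seq)

    d = _hamming_matrix(node_seqs)
    g = nx.Graph()
    for k, seq in enumerate(node_seqs):
        if k < n_obs:
            h = haplos[k]
            g.add_node(
                h.hap_id,
                seq=seq,
                kind="observed",
                multiplicity=h.multiplicity,
                members=list(h.members),
                geography=Counter(h.geography),
            )
        else:
            g.add_node(
                f"mv{k - n_obs + 1}",
                seq=seq,
                kind="median",
                multiplicity=0,
                members=[],
                geography=Counter(),
            )
    names = list(g.nodes)
    for i, j in _msn_edges(d, epsilon):
        g.add_edge(names[i], names[j], weight=int(d[i, j]))
    return HaplotypeNetwork(g, epsilon)


def mp_prune(net: HaplotypeNetwork) -> HaplotypeNetwork:
    """Remove median vectors and links on no minimal-cost observed-pair path.

    Keeps exactly the edges lying on at least one shortest path between a
    pair of observed haplotypes; all observed-pair shortest-path lengths are
    unchanged.  Idempotent.
    """
    g = net.graph
    observed = net.observed
    sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    keep_edges = set()
    for u, v, w in g.edges(data="weight"):
        on_path = False
        for a, b in combinations(observed, 2):
            if (
                abs(sp[a][u] + w + sp[v][b] - sp[a][b]) < 1e-9
                or abs(sp[a][v] + w + sp[u][b] - sp[a][b]) < 1e-9
            ):
                on_path = True
                break
        if on_path:
            keep_edges.add((u, v))
    pruned = nx.Graph()
    for n, data in g.nodes(data=True):
        if data["kind"] == "observed":
            pruned.add_node(n, **data)
    for u, v in keep_edges:
        for n in (u, v):
            if n not in pruned:
                pruned.add_node(n, **g.nodes[n])
        pruned.add_edge(u, v, weight=g[u][v]["weight"])
    # drop medians that ended up isolated
    for n in [x for x in pruned.nodes if pruned.nodes[x]["kind"] == "median"]:
        if pruned.degree(n) == 0:
            pruned.remove_node(n)
    return HaplotypeNetwork(pruned, net.epsilon)


def cluster_separation(net: HaplotypeNetwork, part: Partition) -> tuple[list[str], np.ndarray]:
    """Minimum mutation steps between groups (network shortest paths).

    Every observed haplotype's members must map to a single group; a
    haplotype spanning two groups contradicts the partition and raises.
    Within-group entries are 0 by convention.
    """
    group_of: dict[str, str] = {}
    for n in net.observed:
        members = net.graph.nodes[n]["members"]
        gs = {part.group_of(s) for s in members}
        if len(gs) != 1:
            raise ValueError(f"haplotype {n} spans groups {sorted(gs)}")
        group_of[n] = gs.pop()
    groups = sorted(set(group_of.values()))
    sp = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
    k = len(groups)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            ha = [n for n, g in group_of.items() if g == groups[a]]
            hb = [n for n, g in group_of.items() if g == groups[b]]
            m = min(sp[x][y] for x in ha for y in hb)
            out[a, b] = out[b, a] = m
    return groups, out
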