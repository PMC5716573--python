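"""Haplotype collapsing, median-joining networks, MP pruning, separations."""

from collections import Counter
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from barcodekit.alignment import Alignment, SampleRecord
from barcodekit.network import (
    Haplotype,
    HaplotypeNetwork,
    cluster_separation,
    collapse_haplotypes,
    median_joining,
    mp_prune,
)
from barcodekit.partition import Partition


def _haplos(seqs):
    return [Haplotype(f"H{i+1}", s, [f"x{i}"]) for i, s in enumerate(seqs)]


def test_collapse_merges_identical_rows():
    aln = Alignment(
        "x", [f"s{i}" for i in range(5)],
        ["AAT", "AAT", "ATA", "AAT", "ATA"],
    )
    meta = {
        f"s{i}": SampleRecord(f"s{i}", "A", None, geo)
        for i, geo in enumerate(["PL", "PL", "DE", "UK", "DE"])
    }
    haplos = collapse_haplotypes(aln, meta)
    assert len(haplos) == 2
    assert sum(h.multiplicity for h in haplos) == 5
    assert haplos[0].hap_id == "H1" and haplos[0].multiplicity == 3
    assert haplos[0].geography == Counter({"PL": 2, "UK": 1})


def test_collapse_all_distinct_and_order_invariance(rng):
    rows = ["AATT", "ATAT", "TTAA", "TATA"]
    aln = Alignment("x", list("abcd"), rows)
    assert len(collapse_haplotypes(aln)) == 4
    perm = rng.permutation(4)
    aln2 = Alignment("x", [aln.sample_ids[i] for i in perm],
                     [rows[i] for i in perm])
    h1 = {h.sequence: h.multiplicity for h in collapse_haplotypes(aln)}
    h2 = {h.sequence: h.multiplicity for h in collapse_haplotypes(aln2)}
    assert h1 == h2


def test_median_joining_star_triplet():
    """{AAT, ATA, TAA} -> median AAA, star of three weight-1 edges, cost 3."""
    net = median_joining(_haplos(["AAT", "ATA", "TAA"]))
    assert len(net.medians) == 1
    mv = net.medians[0]
    assert net.graph.nodes[mv]["seq"] == "AAA"
    assert net.total_edge_weight() == 3
    assert all(net.graph[mv][h]["weight"] == 1 for h in net.observed)


def test_median_joining_two_and_one_haplotypes():
    net2 = median_joining(_haplos(["AAAA", "AGTA"]))  # 2 steps apart
    assert len(net2.medians) == 0
    assert list(net2.graph.edges(data="weight")) == [("H1", "H2", 2)]
    net1 = median_joining(_haplos(["AAAA"]))
    assert net1.graph.number_of_nodes() == 1
    assert net1.graph.number_of_edges() == 0


def test_median_never_increases_connection_cost(rng):
    from barcodekit.network import _hamming_matrix, _mst_cost

    for _ in range(20):
        seqs = list({"".join(rng.choice(list("ACGT"), 6)) for _ in range(6)})
        net = median_joining(_haplos(seqs))
        observed_cost = _mst_cost(_hamming_matrix(seqs))
        assert net.connection_cost() <= observed_cost + 1e-9


def test_star_center_recovered_when_absent(rng):
    """Haplotypes one step from a common unsampled center -> center inferred."""
    center = "ACGTACGT"
    ring = []
    for k in range(4):
        s = list(center)
        s[2 * k] = {"A": "G", "C": "T", "G": "A", "T": "C"}[s[2 * k]]
        ring.append("".join(s))
    net = median_joining(_haplos(ring))
    median_seqs = {net.graph.nodes[m]["seq"] for m in net.medians}
    assert center in median_seqs


def _random_network(rng) -> HaplotypeNetwork:
    n = int(rng.integers(4, 8))
    seqs = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(list("ACGT"), 8)))
    return median_joining(_haplos(sorted(seqs)))


def test_mp_prune_preserves_observed_shortest_paths(rng):
    for _ in range(100):
        net = _random_network(rng)
        before = net.shortest_paths()
        pruned = mp_prune(net)
        after = pruned.shortest_paths()
        for a, b in combinations(net.observed, 2):
            assert after[a][b] == pytest.approx(before[a][b])


def test_mp_prune_idempotent_and_removes_dead_end_median(rng):
    net = _random_network(rng)
    once = mp_prune(net)
    twice = mp_prune(once)
    assert set(once.graph.nodes) == set(twice.graph.nodes)
    assert set(map(frozenset, once.graph.edges)) == set(
        map(frozenset, twice.graph.edges)
    )
    # manually attach a dead-end median: must be removed
    g = once.graph.copy()
    g.add_node("mv_dead", seq="X" * 8, kind="median", multiplicity=0,
               members=[], geography=Counter())
    g.add_edge("mv_dead", once.observed[0], weight=3)
    repruned = mp_prune(HaplotypeNetwork(g))
    assert "mv_dead" not in repruned.graph


def test_mp_prune_keeps_star_median():
    net = mp_prune(median_joining(_haplos(["AAT", "ATA", "TAA"])))
    assert len(net.medians) == 1  # center lies on all shortest paths


def test_cluster_separation_single_path():
    # two clusters joined through one median chain of total weight 15
    g = nx.Graph()
    for node, kind in [("H1", "observed"), ("H2", "observed"), ("m", "median")]:
        g.add_node(node, seq="", kind=kind,
                   multiplicity=1 if kind == "observed" else 0,
                   members=["s1"] if node == "H1" else
                           (["s2"] if node == "H2" else []),
                   geography=Counter())
    g.add_edge("H1", "m", weight=7)
    g.add_edge("m", "H2", weight=8)
    net = HaplotypeNetwork(g)
    part = Partition({"s1": "A", "s2": "B"})
    groups, sep = cluster_separation(net, part)
    assert groups == ["A", "B"]
    assert sep[0, 1] == 15 and sep[0, 0] == 0


def test_cluster_separation_matches_bruteforce(rng):
    net = _random_network(rng)
    obs = net.observed
    labels = {h: ("G1" if i < len(obs) // 2 else "G2") for i, h in enumerate(obs)}
    part = Partition(
        {net.graph.nodes[h]["members"][0]: g for h, g in labels.items()}
    )
    groups, sep = cluster_separation(net, part)
    sp = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
    expect = min(
        sp[a][b]
        for a in obs if labels[a] == "G1"
        for b in obs if labels[b] == "G2"
    )
    assert sep[0, 1] == pytest.approx(expect)


def test_cluster_separation_spanning_haplotype_errors():
    aln = Alignment("x", ["s1", "s2"], ["AAA", "AAA"])
    net = median_joining(collapse_haplotypes(aln))
    part = Partition({"s1": "A", "s2": "B"})
    with pytest.raises(ValueError):
        cluster_separation(net, part)


def test_graphml_export_round_trip(tmp_path, rng):
    net = _random_network(rng)
    path = tmp_path / "net.graphml"
    net.write_graphml(path)
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == net.graph.number_of_nodes()
    assert back.number_of_edges() == net.graph.number_of_edges()
    net.write_edgelist(tmp_path / "edges.tsv")
    assert (tmp_path / "edges.tsv").read_text().startswith("node1\tnode2\tsteps")
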