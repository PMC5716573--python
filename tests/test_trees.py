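"""NJ / UPGMA construction, bootstrap, consensus and Newick round-trips."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from barcodekit.alignment import Alignment
from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.trees import (
    bipartitions,
    bootstrap_support,
    is_monophyletic,
    is_ultrametric,
    majority_consensus,
    nj,
    read_newick,
    tip_distance_matrix,
    upgma,
    write_newick,
)


def _dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.ones(d.shape, int), "K2P")


def _path_matrix(tree, ids):
    tids, td = tip_distance_matrix(tree)
    order = [tids.index(x) for x in ids]
    return td[np.ix_(order, order)]


def test_nj_two_taxa_single_edge():
    tree = nj(_dm("ab", [[0, 0.1], [0.1, 0]]))
    assert _path_matrix(tree, list("ab"))[0, 1] == pytest.approx(0.1)


def test_nj_three_taxa_closed_form():
    d = [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]
    tree = nj(_dm("abc", d))
    # star lengths (d_ab + d_ac - d_bc)/2 etc.
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((a:1,b:2):1,(c:3,d:4)) -> pairwise path lengths
    ids = list("abcd")
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = nj(_dm(ids, D))
    assert np.abs(_path_matrix(tree, ids) - D).max() < 1e-9
    assert bipartitions(tree) == {frozenset("ab")}


def _random_additive(rng, n):
    """Random binary tree with random lengths -> (ids, additive matrix, splits)."""
    nodes = [(f"t{i}",) for i in range(n)]
    children: dict = {}
    lengths: dict = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = a + b
        children[parent] = (a, b)
        lengths[a] = rng.uniform(0.5, 3.0)
        lengths[b] = rng.uniform(0.5, 3.0)
        nodes.append(parent)
    root = nodes[0]
    ids = sorted(root)

    # tip-to-tip distance = depth of both leaves below their lowest common
    # ancestor, found by descending the nested-tuple structure
    def leaf_depths(node, depth, out):
        if len(node) == 1:
            out[node[0]] = depth
            return
        for ch in children[node]:
            leaf_depths(ch, depth + lengths[ch], out)

    def pair_dist(x, y):
        node = root
        while len(node) > 1:
            a, b = children[node]
            if x in a and y in a:
                node = a
            elif x in b and y in b:
                node = b
            else:
                break
        out: dict = {}
        leaf_depths(node, 0.0, out)
        return out[x] + out[y]

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pair_dist(ids[i], ids[j])
    splits = {
        frozenset(k)
        for k in children
        if 1 < len(k) < n - 1
    }
    return ids, D, splits


def test_nj_recovers_additive_six_taxon_tree(rng):
    ids, D, splits = _random_additive(rng, 6)
    tree = nj(_dm(ids, D))
    assert np.abs(_path_matrix(tree, ids) - D).max() < 1e-9
    leaves = frozenset(ids)
    canon = {min(s, leaves - s, key=lambda t: (len(t), tuple(sorted(t))))
             for s in splits}
    assert bipartitions(tree) == canon


def test_upgma_two_taxa_and_ultrametric_invariant(rng):
    tree = upgma(_dm("ab", [[0, 0.2], [0.2, 0]]))
    for t in tree.tips():
        assert t.length == pytest.approx(0.1)  # root at d/2
    n = 9
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    t = upgma(_dm([f"s{i}" for i in range(n)], m))
    assert is_ultrametric(t)


def test_upgma_matches_scipy_average_linkage(rng):
    """Cophenetic distances equal scipy's average-linkage heights."""
    n = 8
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    ids = [f"s{i}" for i in range(n)]
    tree = upgma(_dm(ids, m))
    coph = squareform(cophenet(linkage(squareform(m), method="average")))
    assert np.abs(_path_matrix(tree, ids) - coph).max() < 1e-9


def test_upgma_exact_recovery_of_ultrametric_input(rng):
    base = upgma(_dm([f"s{i}" for i in range(6)],
                     (lambda x: (x + x.T) / 2)(rng.random((6, 6)))
                     * (1 - np.eye(6))))
    ids, D = tip_distance_matrix(base)
    tree2 = upgma(_dm(ids, D))
    assert np.abs(_path_matrix(tree2, ids) - D).max() < 1e-9


def test_newick_round_trip(tmp_path):
    ids = list("abcde")
    rng = np.random.default_rng(1)
    m = rng.random((5, 5))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    tree = nj(_dm(ids, m))
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(str(path))
    assert bipartitions(back) == bipartitions(tree)
    assert np.abs(_path_matrix(back, ids) - _path_matrix(tree, ids)).max() < 1e-9


def _synapomorphy_alignment():
    """Clade {a,b} vs {c,d,e} supported by 200 clean shared substitutions."""
    rng = np.random.default_rng(7)
    base = "".join("ACGT"[k] for k in rng.integers(0, 4, 600))
    derived = list(base)
    for pos in rng.choice(600, 200, replace=False):
        derived[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[derived[pos]]
    derived = "".join(derived)

    def jitter(s, k, seed):
        r = np.random.default_rng(seed)
        out = list(s)
        for pos in r.choice(600, k, replace=False):
            out[pos] = "ACGT"[(("ACGT".index(out[pos])) + 1) % 4]
        return "".join(out)

    rows = [jitter(derived, 3, 1), jitter(derived, 3, 2),
            jitter(base, 3, 3), jitter(base, 3, 4), jitter(base, 3, 5)]
    return Alignment("syn", list("abcde"), rows)


def test_bootstrap_clean_synapomorphies_and_determinism():
    aln = _synapomorphy_alignment()
    tree, dropped = bootstrap_support(aln, b=50, seed=9)
    assert dropped == 0
    supports = {
        frozenset(t.name for t in node.tips()): node.support
        for node in tree.non_tips(include_self=False)
        if hasattr(node, "support")
    }
    found = [v for k, v in supports.items() if k in (frozenset("ab"), frozenset("cde"))]
    assert found and found[0] >= 99.0
    tree2, _ = bootstrap_support(aln, b=50, seed=9)
    assert str(tree) == str(tree2)  # fixed seed -> identical supports


def test_bootstrap_single_replicate_supports_binary():
    aln = _synapomorphy_alignment()
    tree, _ = bootstrap_support(aln, b=1, seed=0)
    vals = {node.support for node in tree.non_tips(include_self=False)
            if hasattr(node, "support")}
    assert vals <= {0.0, 100.0}


def test_majority_consensus_rules():
    t_ab = read_newick("((a,b),c,d);")
    t_ab2 = read_newick("((a,b),c,d);")
    t_cd = read_newick("((c,d),a,b);")  # same unrooted bipartition ab|cd
    t_ac = read_newick("((a,c),b,d);")
    same = majority_consensus([t_ab, t_ab2], threshold=0.75)
    assert bipartitions(same) == bipartitions(t_ab)
    # clade in 2 of 3 trees: kept at 0.5, collapsed at 0.75
    trees = [t_ab, t_cd, t_ac]  # ab|cd appears 2/3, ac|bd 1/3
    kept = majority_consensus(trees, threshold=0.5)
    assert bipartitions(kept) == {frozenset("ab")}
    collapsed = majority_consensus(trees, threshold=0.75)
    assert bipartitions(collapsed) == set()  # star
    # conflicting bipartitions both below 75% -> star
    star = majority_consensus([t_ab, t_ac], threshold=0.75)
    assert bipartitions(star) == set()


def test_monophyly_check_on_synthetic_species(default_dataset):
    from barcodekit.alignment import concatenate, mask_columns

    cp, _ = concatenate(default_dataset.plastid_loci())
    dm = distance_matrix(mask_columns(cp))
    tree = nj(dm)
    for members in default_dataset.species_partition.groups().values():
        assert is_monophyletic(tree, members)
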