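"""Barcoding-gap statistics: pair partitioning, summaries, overlaps, folds, U test."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from barcodekit.distances import DistanceMatrix
from barcodekit.gapstats import (
    DistStats,
    fold_ratio,
    gap_present,
    gap_summary,
    histogram_data,
    mann_whitney,
    overlap_stats,
    partition_pairs,
    summarize,
)
from barcodekit.partition import Partition


def _stats(**kw) -> DistStats:
    base = dict(n=1, mean=0, median=0, min=0, max=0, p5=0, p10=0, p90=0, p95=0)
    base.update(kw)
    return DistStats(**base)


def _random_dm(rng, n=10):
    d = rng.random((n, n)) * 0.05
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    ids = [f"s{i}" for i in range(n)]
    return DistanceMatrix(ids, d, np.ones((n, n), int), "p")


def test_partition_pairs_counts():
    d = np.full((4, 4), 0.04)
    np.fill_diagonal(d, 0)
    dm = DistanceMatrix(list("abcd"), d, np.ones((4, 4), int), "p")
    part = Partition({"a": "X", "b": "X", "c": "Y", "d": "Y"})
    intra, inter = partition_pairs(dm, part)
    assert len(intra) == 2 and len(inter) == 4
    assert len(intra) + len(inter) == 6  # C(4,2)


def test_partition_pairs_single_group_and_exclusion(rng):
    dm = _random_dm(rng, 6)
    one = Partition({s: "X" for s in dm.sample_ids})
    intra, inter = partition_pairs(dm, one)
    assert len(inter) == 0 and len(intra) == 15
    # excluding a singleton group removes exactly n-1 inter pairs
    part = Partition(
        {s: ("SOLO" if s == "s0" else "X") for s in dm.sample_ids}
    )
    i1, e1 = partition_pairs(dm, part)
    i2, e2 = partition_pairs(dm, part, exclude_groups=("SOLO",))
    assert len(e1) - len(e2) == 5
    assert len(i1) == len(i2)


def test_partition_pairs_matches_bruteforce(rng):
    dm = _random_dm(rng, 9)
    labels = rng.choice(["A", "B", "C"], size=9)
    part = Partition(dict(zip(dm.sample_ids, labels)))
    intra, inter = partition_pairs(dm, part)
    bi, be = [], []
    for a, b in combinations(dm.sample_ids, 2):
        (bi if part.group_of(a) == part.group_of(b) else be).append(dm.pair(a, b))
    assert sorted(intra) == pytest.approx(sorted(bi))
    assert sorted(inter) == pytest.approx(sorted(be))


def test_summarize_basics():
    st = summarize([0.01, 0.02, 0.03, 0.04])  # % scale output
    assert st.median == pytest.approx(2.5)
    assert st.mean == pytest.approx(2.5)
    const = summarize([0.02] * 5)
    assert const.min == const.max == const.p90 == const.median == pytest.approx(2.0)
    with pytest.raises(ValueError):
        summarize([])


def test_summarize_percentile_monte_carlo(rng):
    v = rng.random(1000)
    st = summarize(v, percent=False)
    # P90 of U(0,1) = 0.9; CI half-width ~ 3*sqrt(0.9*0.1/1000)
    assert abs(st.p90 - 0.9) < 0.03
    assert st.p5 <= st.p10 <= st.median <= st.p90 <= st.p95


@pytest.mark.parametrize(
    "max_intra, min_inter, expect",
    [
        (0.99, 0.86, 0.13),   # overlapping distributions
        (0.49, 0.66, 0.0),    # negative -> truncated to 0
        (3.91, 0.88, 3.03),
        (1.40, 1.14, 0.26),
    ],
)
def test_overlap1_from_summaries(max_intra, min_inter, expect):
    ov = overlap_stats(_stats(max=max_intra), _stats(min=min_inter))
    assert ov.overlap1 == pytest.approx(expect)
    assert ov.signed1 == pytest.approx(max_intra - min_inter)


def test_overlap_reorder_invariance(rng):
    intra = rng.random(50) * 0.01
    inter = rng.random(80) * 0.05 + 0.01
    a = overlap_stats(summarize(intra), summarize(inter))
    b = overlap_stats(
        summarize(rng.permutation(intra)), summarize(rng.permutation(inter))
    )
    assert (a.overlap1, a.overlap2, a.overlap3) == (b.overlap1, b.overlap2, b.overlap3)


def test_fold_ratio_examples_and_zero_denominator():
    fr = fold_ratio(4.96, 0.14, 5.60, 0.05)
    assert fr.fold_mean == pytest.approx(35.4286, abs=1e-3)
    assert fr.display == "35.4x"
    assert fr.fold_median == pytest.approx(112.0)
    assert fr.ten_fold_rule
    assert fold_ratio(4.78, 0.31).fold_mean == pytest.approx(15.419, abs=1e-3)
    zero = fold_ratio(1.0, 0.0)
    assert math.isinf(zero.fold_mean) and zero.ten_fold_rule


def test_mann_whitney_exact_small_example():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme


def test_mann_whitney_identical_samples_p_near_one():
    _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
    assert p == pytest.approx(1.0)


def test_mann_whitney_exact_matches_enumeration_oracle(rng):
    """Exact path equals full-factorial enumeration for all n1, n2 <= 6."""
    for n1 in range(1, 7):
        for n2 in range(1, 7):
            x = rng.integers(0, 5, size=n1).astype(float)  # ties likely
            y = rng.integers(0, 5, size=n2).astype(float)
            u_obs, p = mann_whitney(x, y)
            pooled = np.concatenate([x, y])
            ranks = sps.rankdata(pooled)
            mu = n1 * n2 / 2
            offset = n1 * (n1 + 1) / 2
            devs = [
                abs(ranks[list(c)].sum() - offset - mu)
                for c in combinations(range(n1 + n2), n1)
            ]
            expect = np.mean(
                [dv >= abs(u_obs - mu) - 1e-12 for dv in devs]
            )
            assert p == pytest.approx(expect)
            assert u_obs + (n1 * n2 - u_obs) == n1 * n2


def test_mann_whitney_large_shifted_samples(rng):
    x = rng.normal(0.0, 1.0, 200)
    y = rng.normal(3.0, 1.0, 200)
    _, p = mann_whitney(x, y)
    assert p < 1e-6


def test_gap_present_cases(rng):
    # disjoint distributions -> classical gap
    diag = gap_present(rng.random(30) * 0.003, 0.03 + rng.random(30) * 0.01)
    assert diag.present
    # overlapping -> no gap
    diag2 = gap_present([0.001, 0.0099], [0.0086, 0.05])
    assert not diag2.present
    assert diag2.overlaps.overlap1 == pytest.approx(0.13)


def test_gap_summary_end_to_end(rng):
    n = 12
    ids = [f"s{i}" for i in range(n)]
    part = Partition({s: ("A" if i < 6 else "B") for i, s in enumerate(ids)})
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        same = (i < 6) == (j < 6)
        d[i, j] = d[j, i] = (
            rng.uniform(0, 0.004) if same else rng.uniform(0.03, 0.05)
        )
    dm = DistanceMatrix(ids, d, np.ones((n, n), int), "K2P")
    gs = gap_summary(dm, part, locus="toy")
    assert gs.gap_present
    assert gs.fold.fold_mean > 10
    assert gs.p_value < 1e-6
    assert gs.intra.n == 30 and gs.inter.n == 36
    row = gs.to_row()
    assert row["locus"] == "toy" and row["ten_fold_rule"]
    hist = histogram_data(*partition_pairs(dm, part))
    assert hist["intra"].sum() == 30 and hist["inter"].sum() == 36
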