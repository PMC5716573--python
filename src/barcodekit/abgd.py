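"""Automatic barcode-gap discovery: prior scan, gap detection, single-linkage
grouping, initial and recursive partitions.

For each prior intraspecific divergence P (geometric progression from Pmin to
Pmax) the sorted pairwise distances are scanned for the first gap that is
wide relative to the local spacing of distances; samples are then grouped by
single linkage at the gap midpoint.  Distances strictly below the prior are
treated as guaranteed-intraspecific and never proposed as the gap.  The same
search is re-applied inside each group (recursive partition) until no group
splits.

The gap-significance rule: a consecutive gap ``g = d[i+1] - d[i]`` qualifies
when its upper endpoint reaches the prior and ``g > X * s`` where ``s`` is
the mean of the W preceding consecutive gaps (zero-width gaps included),
``W = max(10, ceil(0.05 * n_pairs))``.  X is the relative gap width
(default 1.5; per-locus overrides such as 1.2 are supported).  The widest
qualifying gap is taken as the barcode gap, so the initial partition splits
at the most prominent divergence scale and finer (subgroup) gaps are found
by the recursive pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix, jc69_distance  # noqa: F401  (re-export)
from .partition import Partition

__all__ = [
    "AbgdConfig",
    "AbgdResult",
    "PriorResult",
    "prior_sequence",
    "find_gap_threshold",
    "single_linkage",
    "abgd",
    "jc69_distance",
]


@dataclass(frozen=True)
class AbgdConfig:
    """Prior bounds, step count, relative gap width and distance model."""

    pmin: float = 0.001
    pmax: float = 0.1
    n_steps: int = 10
    X: float = 1.5
    model: str = "K2P"

    def __post_init__(self) -> None:
        if not (0.0 < self.pmin < self.pmax < 1.0):
            raise ValueError("need 0 < Pmin < Pmax < 1")
        if self.n_steps < 2:
            raise ValueError("need n_steps >= 2")
        if self.X <= 1.0:
            raise ValueError("need relative gap width X > 1")


def prior_sequence(cfg: AbgdConfig) -> np.ndarray:
    """Geometric progression of priors from Pmin to Pmax inclusive."""
    return np.geomspace(cfg.pmin, cfg.pmax, cfg.n_steps)


def find_gap_threshold(
    sorted_distances, prior: float, X: float, n_pairs: int | None = None
) -> float | None:
    """Locate the barcode gap in an ascending distance list.

    A consecutive gap qualifies when its upper endpoint is at or above the
    prior and its width exceeds ``X`` times the local gap scale (mean of the
    preceding W consecutive gaps, zero-width gaps included).  Among the
    qualifying gaps the WIDEST one is taken as the barcode gap (ties go to
    the lowest), so that the initial partition splits at the most prominent
    divergence gap and finer structure is left to the recursive pass; the
    midpoint of that gap is returned, or ``None`` when no gap qualifies.
    The very first gap has no local scale and is never proposed.
    """
    d = np.asarray(sorted_distances, dtype=float)
    if d.size < 2:
        raise ValueError("need >=2 distances to search for a gap")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be sorted ascending")
    n = n_pairs if n_pairs is not None else d.size
    W = max(10, math.ceil(0.05 * n))
    gaps = np.diff(d)
    best_i, best_g = None, 0.0
    for i, g in enumerate(gaps):
        if d[i + 1] < prior:
            continue  # gap entirely in the guaranteed-intraspecific zone
        if g <= 0.0:
            continue
        if i == 0:
            continue  # no preceding gaps to estimate the local scale
        local = gaps[max(0, i - W): i]
        if g > X * float(local.mean()) and g > best_g + 1e-15:
            best_i, best_g = i, float(g)
    if best_i is None:
        return None
    return float((d[best_i] + d[best_i + 1]) / 2.0)


def single_linkage(dm: DistanceMatrix, threshold: float) -> Partition:
    """Groups = connected components of the graph with edges where d <= threshold.

    Group labels are assigned in order of each group's first sample, so the
    partition is deterministic and invariant to input reordering up to labels.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = (dm.d <= threshold) & ~np.isnan(dm.d)
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    seen: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for sid, lab in zip(dm.sample_ids, labels):
        if lab not in seen:
            seen[lab] = f"G{len(seen) + 1}"
        assignment[sid] = seen[lab]
    return Partition(assignment)


@dataclass
class PriorResult:
    prior: float
    threshold: float | None
    initial: Partition
    recursive: Partition

    @property
    def n_groups_initial(self) -> int:
        return self.initial.n_groups

    @property
    def n_groups_recursive(self) -> int:
        return self.recursive.n_groups


@dataclass
class AbgdResult:
    config: AbgdConfig
    by_prior: list[PriorResult] = field(default_factory=list)

    def at_prior(self, prior: float) -> PriorResult:
        best = min(self.by_prior, key=lambda r: abs(r.prior - prior))
        return best


def _one_group(dm: DistanceMatrix) -> Partition:
    return Partition({s: "G1" for s in dm.sample_ids})


def _split_once(dm: DistanceMatrix, prior: float, X: float) -> Partition | None:
    """One gap search + single-linkage split; None when no gap is found."""
    dist = np.sort(dm.condensed())
    dist = dist[~np.isnan(dist)]
    if dist.size < 2:
        return None
    thr = find_gap_threshold(dist, prior, X, n_pairs=dist.size)
    if thr is None:
        return None
    part = single_linkage(dm, thr)
    return part if part.n_groups > 1 else None


def _recursive_partition(dm: DistanceMatrix, initial: Partition,
                         prior: float, X: float) -> Partition:
    """Re-apply the gap search within each group until no group splits."""
    final: dict[str, str] = {}
    counter = 0
    stack = [members for members in initial.groups().values()]
    while stack:
        members = stack.pop()
        if len(members) >= 3:
            sub = dm.submatrix(members)
            part = _split_once(sub, prior, X)
            if part is not None:
                stack.extend(part.groups().values())
                continue
        counter += 1
        label = f"R{counter}"
        for s in members:
            final[s] = label
    return Partition(final)


def abgd(dm: DistanceMatrix, cfg: AbgdConfig | None = None) -> AbgdResult:
    """Run the full prior scan: initial and recursive partitions per prior.

    The initial partition comes from one global gap search; with no
    qualifying gap all samples form a single group.  Deterministic for a
    fixed input.
    """
    cfg = cfg or AbgdConfig()
    result = AbgdResult(cfg)
    for prior in prior_sequence(cfg):
        dist = np.sort(dm.condensed())
        dist = dist[~np.isnan(dist)]
        thr = (
            find_gap_threshold(dist, prior, cfg.X, n_pairs=dist.size)
            if dist.size >= 2
            else None
        )
        initial = single_linkage(dm, thr) if thr is not None else _one_group(dm)
        recursive = _recursive_partition(dm, initial, prior, cfg.X)
        result.by_prior.append(PriorResult(float(prior), thr, initial, recursive))
    return result


def write_result(result: AbgdResult, prefix) -> None:
    """TSV exports: per-prior group counts and per-sample memberships."""
    import pandas as pd

    rows = [
        {
            "prior": r.prior,
            "n_groups_initial": r.n_groups_initial,
            "n_groups_recursive": r.n_groups_recursive,
            "threshold": "" if r.threshold is None else r.threshold,
        }
        for r in result.by_prior
    ]
    pd.DataFrame(rows).to_csv(f"{prefix}_groups.tsv", sep="\t", index=False)
    mem = []
    for r in result.by_prior:
        for s in r.initial.samples:
            mem.append(
                {
                    "sample_id": s,
                    "prior": r.prior,
                    "group_initial": r.initial.group_of(s),
                    "group_recursive": r.recursive.group_of(s),
                }
            )
    pd.DataFrame(mem).to_csv(f"{prefix}_membership.tsv", sep="\t", index=False)
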