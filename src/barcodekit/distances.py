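"""Pairwise genetic distances and group divergence summaries.

Distances are stored internally as proportions (substitutions/site); report
writers multiply by 100, once, matching how divergence tables print
percentages.  Transitions are A<->G and C<->T; every other change among the
four bases is a transversion.

Models
------
p      uncorrected p-distance, mismatches / usable sites.
K2P    Kimura two-parameter, d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)
       with P, Q the transition/transversion fractions.
JC69   Jukes-Cantor, d = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import UNUSABLE, Alignment
from .partition import Partition

__all__ = [
    "DistanceError",
    "SaturationError",
    "DistanceMatrix",
    "GroupDivergence",
    "k2p_distance",
    "p_distance",
    "jc69_distance",
    "distance_matrix",
    "group_divergence",
]

#: sentinel printed for a within-group mean that cannot be computed
#: (singleton group)
NOT_COMPUTABLE = "n/c"


class DistanceError(ValueError):
    pass


class SaturationError(DistanceError):
    """The distance formula's logarithm argument is non-positive."""


def _encode(seq: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([table.get(c, 255) for c in seq.upper().replace("U", "T")],
                    dtype=np.uint8)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(usable sites, transitions, transversions) for two coded rows."""
    usable = (a != UNUSABLE) & (b != UNUSABLE)
    n = int(usable.sum())
    if n == 0:
        return 0, 0, 0
    x, y = a[usable], b[usable]
    diff = x != y
    ts = int((diff & ((x ^ y) == 2)).sum())  # A<->G (0^2), C<->T (1^3 -> 2)
    tv = int(diff.sum()) - ts
    return n, ts, tv


def _as_codes(s) -> np.ndarray:
    return s if isinstance(s, np.ndarray) else _encode(s)


def p_distance(s1, s2) -> tuple[float, int]:
    """Uncorrected p-distance and the number of usable sites."""
    a, b = _as_codes(s1), _as_codes(s2)
    if len(a) != len(b):
        raise DistanceError("sequences of unequal length")
    n, ts, tv = _pair_counts(a, b)
    if n == 0:
        raise DistanceError("no usable sites shared by the pair")
    return (ts + tv) / n, n


def k2p_distance(s1, s2) -> tuple[float, int]:
    """Kimura 2-parameter distance and the number of usable sites.

    Raises :class:`SaturationError` when ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0`` (distance undefined).
    """
    a, b = _as_codes(s1), _as_codes(s2)
    if len(a) != len(b):
        raise DistanceError("sequences of unequal length")
    n, ts, tv = _pair_counts(a, b)
    if n == 0:
        raise DistanceError("no usable sites shared by the pair")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P saturated (P={P:.4f}, Q={Q:.4f})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), n


def jc69_distance(s1, s2) -> tuple[float, int]:
    """Jukes-Cantor distance; saturates at p >= 0.75."""
    p, n = p_distance(s1, s2)
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0.0:
        raise SaturationError(f"JC69 saturated (p={p:.4f})")
    return -0.75 * math.log(w), n


_MODEL_FUNCS = {"p": p_distance, "K2P": k2p_distance, "JC69": jc69_distance}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair usable-site counts."""

    sample_ids: list[str]
    d: np.ndarray
    used_sites: np.ndarray
    model: str

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.d = np.asarray(self.d, dtype=float)
        self.used_sites = np.asarray(self.used_sites)
        if self.d.shape != (n, n) or self.used_sites.shape != (n, n):
            raise DistanceError("matrix shape does not match sample count")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise DistanceError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise DistanceError("non-zero diagonal")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in row-major pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def pair(self, s1: str, s2: str) -> float:
        i, j = self.sample_ids.index(s1), self.sample_ids.index(s2)
        return float(self.d[i, j])

    def submatrix(self, samples: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return DistanceMatrix(
            list(samples), self.d[np.ix_(idx, idx)],
            self.used_sites[np.ix_(idx, idx)], self.model,
        )

    def write_tsv(self, path: str | Path, percent: bool = True) -> None:
        scale = 100.0 if percent else 1.0
        pd.DataFrame(self.d * scale, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for sid, row in zip(self.sample_ids, self.d):
                fh.write(sid + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")


def distance_matrix(
    aln: Alignment,
    model: str = "K2P",
    deletion: str = "pairwise",
    on_saturation: str = "error",
) -> DistanceMatrix:
    """Full pairwise distance matrix for an alignment.

    ``deletion='complete'`` first restricts to columns usable in every row;
    ``'pairwise'`` (default) drops unusable sites per pair.  A saturated pair
    raises by default (``on_saturation='error'``, listing the offenders);
    ``'drop'`` records NaN for the pair with a warning.
    """
    if aln.n_samples < 2:
        raise DistanceError("need >=2 sequences")
    if model not in _MODEL_FUNCS:
        raise DistanceError(f"unknown model {model!r}")
    codes = aln.codes()
    if deletion == "complete":
        usable = (codes != UNUSABLE).all(axis=0)
        if not usable.any():
            raise DistanceError("complete deletion removed every column")
        codes = codes[:, usable]
    elif deletion != "pairwise":
        raise DistanceError(f"unknown deletion policy {deletion!r}")

    n = aln.n_samples
    func = _MODEL_FUNCS[model]
    d = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    used[np.diag_indices(n)] = codes.shape[1]
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij, nij = func(codes[i], codes[j])
            except SaturationError:
                saturated.append((aln.sample_ids[i], aln.sample_ids[j]))
                dij, nij = math.nan, 0
            d[i, j] = d[j, i] = dij
            used[i, j] = used[j, i] = nij
    if saturated and on_saturation == "error":
        raise SaturationError(f"saturated pairs: {saturated}")
    if saturated:
        import warnings

        warnings.warn(f"dropped {len(saturated)} saturated pair(s)")
    return DistanceMatrix(list(aln.sample_ids), d, used, model)


@dataclass
class GroupDivergence:
    """Mean within- and between-group distances (arithmetic means over pairs)."""

    groups: list[str]
    within: dict[str, float | None]          # None = singleton group (n/c)
    between: dict[tuple[str, str], float]    # keys sorted pairs
    n_within: dict[str, int]
    n_between: dict[tuple[str, str], int]

    def between_of(self, g: str, h: str) -> float:
        return self.between[tuple(sorted((g, h)))]

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        df = pd.DataFrame(index=self.groups, columns=self.groups, dtype=object)
        for g in self.groups:
            w = self.within[g]
            df.loc[g, g] = NOT_COMPUTABLE if w is None else w * scale
        for (g, h), v in self.between.items():
            df.loc[g, h] = v * scale
            df.loc[h, g] = v * scale
        return df


def group_divergence(dm: DistanceMatrix, part: Partition) -> GroupDivergence:
    """Average divergence within and between the groups of a partition.

    A singleton group's within-mean is undefined and stored as ``None``
    (printed as ``n/c``).  Every sample in the matrix must be assigned.
    """
    unassigned = [s for s in dm.sample_ids if s not in part.assignment]
    if unassigned:
        raise DistanceError(f"unassigned samples: {unassigned}")
    members = part.restrict(dm.sample_ids).groups()
    order = sorted(members)
    idx = {s: i for i, s in enumerate(dm.sample_ids)}
    within: dict[str, float | None] = {}
    n_within: dict[str, int] = {}
    for g in order:
        ids = [idx[s] for s in members[g]]
        if len(ids) < 2:
            within[g], n_within[g] = None, 0
            continue
        sub = dm.d[np.ix_(ids, ids)]
        vals = sub[np.triu_indices(len(ids), k=1)]
        within[g] = float(np.mean(vals))
        n_within[g] = vals.size
    between: dict[tuple[str, str], float] = {}
    n_between: dict[tuple[str, str], int] = {}
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            g, h = order[a], order[b]
            ig = [idx[s] for s in members[g]]
            ih = [idx[s] for s in members[h]]
            block = dm.d[np.ix_(ig, ih)]
            between[(g, h)] = float(block.mean())
            n_between[(g, h)] = block.size
    return GroupDivergence(order, within, between, n_within, n_between)


def divergence_table(
    dm_k2p: DistanceMatrix, dm_p: DistanceMatrix, part: Partition
) -> pd.DataFrame:
    """Combined table: K2P means below the diagonal, p-distance means above."""
    gk = group_divergence(dm_k2p, part)
    gp = group_divergence(dm_p, part)
    df = pd.DataFrame(index=gk.groups, columns=gk.groups, dtype=object)
    for g in gk.groups:
        df.loc[g, g] = "***"
    for (g, h), v in gk.between.items():
        df.loc[h, g] = v * 100.0
        df.loc[g, h] = gp.between[(g, h)] * 100.0
    return df
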