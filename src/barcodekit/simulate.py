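"""Synthetic multilocus cryptic-species data.

The generator plants K cryptic species on a fixed two-clade species tree with
star-like within-species sampling, so that the statistical structure the
downstream analyses assume (ordered divergence scales
intra < lineage < inter < deep-clade, linked plastid loci plus a
faster-evolving nuclear locus, lineage subgroups inside some species) is
present by construction.  Sequences evolve under the Kimura 2-parameter
process (transition rate = kappa x each transversion rate), using the exact
per-site substitution probabilities for each branch length.

Branch depths are calibrated so that the EXPECTED mean intraspecific and mean
interspecific K2P divergences hit the configured targets; realized values
fluctuate around them with finite sequence length.  This is deliberately not
a coalescent simulator; within-species genealogies are stars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from .alignment import Alignment, SampleRecord, write_alignment, write_metadata
from .distances import DistanceMatrix
from .partition import Partition

__all__ = [
    "LocusSpec",
    "SyntheticConfig",
    "SimulatedDataset",
    "evolve",
    "simulate",
    "make_planted_matrix",
    "random_clonal_alignment",
]

_BASES = "ACGT"
_REGIONS = ["lowland", "montane", "coastal", "mire", "riparian"]
_HABITATS = ["limestone humus", "clay soil", "peat bog", "wet rock", "sandy soil"]


@dataclass(frozen=True)
class LocusSpec:
    """One simulated locus: name, aligned length, genome class, rate multiplier."""

    name: str
    length: int
    kind: str = "plastid"  # or "nuclear"
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError("locus length must be >= 100")
        if self.kind not in ("plastid", "nuclear"):
            raise ValueError(f"unknown locus kind {self.kind!r}")


def _default_loci() -> tuple[LocusSpec, ...]:
    # five plastid loci + one fast nuclear locus (rate x2.5, the typical
    # ITS-vs-plastid spread)
    return (
        LocusSpec("cpA", 800, "plastid", 1.2),
        LocusSpec("cpB", 620, "plastid", 0.6),
        LocusSpec("cpC", 760, "plastid", 0.9),
        LocusSpec("cpD", 550, "plastid", 1.1),
        LocusSpec("cpE", 800, "plastid", 1.0),
        LocusSpec("nrITS", 750, "nuclear", 2.5),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted cryptic-species structure and divergence targets.

    Divergences are proportions (substitutions/site).  Defaults: 5 species of
    8 samples, mean intraspecific divergence 0.2%, mean interspecific 4%, two
    deep clades 4.2% apart, two species carrying 2 lineages 0.5% apart,
    kappa = 2.
    """

    n_species: int = 5
    samples_per_species: int = 8
    lineages: dict = field(default_factory=lambda: {0: 2, 1: 2})
    lineage_divergence: float = 0.005
    deep_divergence: float = 0.042
    target_intra: float = 0.002
    target_inter: float = 0.04
    loci: tuple = field(default_factory=_default_loci)
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need K >= 1 species")
        if self.samples_per_species < 1:
            raise ValueError("need >= 1 sample per species")
        if self.n_species > 1 and not (
            self.target_intra
            < self.lineage_divergence
            < self.target_inter
            < self.deep_divergence
        ):
            raise ValueError(
                "divergences must satisfy intra < lineage < inter < deep"
            )

    def species_label(self, i: int) -> str:
        return chr(ord("A") + i)

    def clade_of(self, i: int) -> int:
        """Species -> deep clade (1 or 2); first ceil(K/2) species in clade 1."""
        return 1 if i < math.ceil(self.n_species / 2) else 2


def _k2p_probs(branch_length: float, kappa: float) -> tuple[float, float]:
    """(P transition, P each transversion) after a branch of the given
    expected substitutions/site under the K2P process."""
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    bt = branch_length / (kappa + 2.0)  # beta * t
    at = kappa * bt
    e1 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 * (1.0 - e1)
    return p_ts, p_tv


def evolve(seq, branch_length: float, kappa: float, rng: np.random.Generator):
    """Evolve a sequence along one branch under the exact K2P kernel.

    ``seq`` may be a string over ACGT or a uint8 code array (A,C,G,T ->
    0..3); the same type is returned.  ``branch_length`` is the expected
    number of substitutions per site.
    """
    as_str = isinstance(seq, str)
    codes = (
        np.frombuffer(seq.translate(str.maketrans("ACGT", "\0\1\2\3")).encode(),
                      dtype=np.uint8).copy()
        if as_str
        else np.asarray(seq, dtype=np.uint8).copy()
    )
    p_ts, p_tv = _k2p_probs(branch_length, kappa)
    u = rng.random(codes.size)
    # transition partner = code ^ 2; transversion partners = code ^ 1, ^ 3
    codes[u < p_ts] ^= 2
    codes[(u >= p_ts) & (u < p_ts + p_tv)] ^= 1
    codes[(u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)] ^= 3
    if as_str:
        return "".join(_BASES[c] for c in codes)
    return codes


def _lineage_sizes(m: int, n_lineages: int) -> list[int]:
    base = m // n_lineages
    sizes = [base + (1 if k < m % n_lineages else 0) for k in range(n_lineages)]
    return sizes


def _calibrate(cfg: SyntheticConfig) -> dict:
    """Solve tree depths from the divergence targets.

    Within each deep clade the species sit on a ladder (caterpillar) tree
    whose split depths are spread evenly between a solved lower separation
    c_lo and 0.9 x the deep divergence, so the interspecific distances form
    a quasi-continuum up to the cross-clade scale (as in real multispecies
    barcode data) rather than two isolated values; c_lo is solved linearly
    so the expected mean interspecific divergence hits the target.

    Returns tip depth h_l, lineage-split depth h_g, the clade map and the
    per-clade ladder separations, on the substitutions/site scale of a
    rate-1 locus.
    """
    m = cfg.samples_per_species
    n_within = n_cross = 0
    for i in range(cfg.n_species):
        sizes = _lineage_sizes(m, cfg.lineages.get(i, 1))
        w = sum(s * (s - 1) // 2 for s in sizes)
        n_within += w
        n_cross += m * (m - 1) // 2 - w
    n_intra = n_within + n_cross
    if n_intra > 0:
        two_hl = cfg.target_intra - cfg.lineage_divergence * n_cross / n_intra
        if two_hl <= 0:
            raise ValueError(
                "target intra divergence too small for the lineage structure"
            )
        h_l = two_hl / 2.0
    else:
        h_l = cfg.target_intra / 2.0
    h_g = h_l + cfg.lineage_divergence / 2.0

    clades: dict[int, list[int]] = {}
    for i in range(cfg.n_species):
        clades.setdefault(cfg.clade_of(i), []).append(i)
    deep = cfg.deep_divergence
    separations: dict[int, list[float]] = {c: [] for c in clades}
    if cfg.n_species > 1:
        # one ladder slot per within-clade split, round-robin over clades so
        # each clade's depths stay increasing
        slot_owner: list[int] = []
        remaining = {c: len(v) - 1 for c, v in clades.items()}
        while any(remaining.values()):
            for c in sorted(remaining, key=lambda c: -len(clades[c])):
                if remaining[c]:
                    slot_owner.append(c)
                    remaining[c] -= 1
        n_slots = len(slot_owner)
        c_hi = 0.9 * deep if n_slots > 1 else cfg.target_inter
        fracs = (
            [s / (n_slots - 1) for s in range(n_slots)] if n_slots > 1 else [0.0]
        )
        # weight of a slot = (number of species pairs split there) * m^2
        pos = {c: 0 for c in clades}
        weights = []
        for c in slot_owner:
            pos[c] += 1
            weights.append(pos[c] * m * m)
        p_total = cfg.n_species * (cfg.n_species - 1) // 2 * m * m
        p_x = p_total - sum(weights)
        if n_slots == 0:
            c_lo = deep  # every pair is cross-clade
        else:
            # sum_s w_s (c_lo + f_s (c_hi - c_lo)) + p_x deep = target p_total
            const = sum(w * f * c_hi for w, f in zip(weights, fracs))
            coef = sum(w * (1.0 - f) for w, f in zip(weights, fracs))
            c_lo = (cfg.target_inter * p_total - p_x * deep - const) / coef
            if not (cfg.lineage_divergence < c_lo <= c_hi):
                raise ValueError(
                    "inter/deep targets incompatible: lowest species "
                    f"separation solves to {c_lo:.4g}"
                )
            if h_g > c_lo / 2.0:
                raise ValueError("lineage split deeper than the species split")
        for c, f in zip(slot_owner, fracs):
            separations[c].append(c_lo + f * (c_hi - c_lo))
    return {
        "h_l": h_l,
        "h_g": h_g,
        "deep": deep,
        "clades": clades,
        "separations": separations,
    }


@dataclass
class SimulatedDataset:
    config: SyntheticConfig
    alignments: dict  # locus name -> Alignment
    metadata: dict    # sample_id -> SampleRecord
    species_partition: Partition
    lineage_partition: Partition
    clade_of_sample: dict

    def plastid_loci(self) -> list[Alignment]:
        return [
            self.alignments[l.name]
            for l in self.config.loci
            if l.kind == "plastid"
        ]

    def nuclear_loci(self) -> list[Alignment]:
        return [
            self.alignments[l.name]
            for l in self.config.loci
            if l.kind == "nuclear"
        ]

    def write(self, outdir: str | Path) -> None:
        """FASTA per locus + metadata TSV + truth TSV + config echo (YAML)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, aln in self.alignments.items():
            write_alignment(aln, outdir / f"{name}.fasta")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("sample_id\tspecies\tlineage\tclade\n")
            for s in self.species_partition.samples:
                fh.write(
                    f"{s}\t{self.species_partition.group_of(s)}"
                    f"\t{self.lineage_partition.group_of(s)}"
                    f"\t{self.clade_of_sample[s]}\n"
                )
        cfg = asdict(self.config)
        cfg["loci"] = [asdict(l) for l in self.config.loci]
        cfg["lineages"] = {int(k): int(v) for k, v in self.config.lineages.items()}
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def simulate(cfg: SyntheticConfig | None = None) -> SimulatedDataset:
    """Generate per-locus alignments plus metadata and truth labels.

    All plastid loci share one genealogy (the fixed species tree); the
    nuclear loci evolve on an independent, congruent genealogy (same tree,
    independent substitutions).  Deterministic for a fixed seed.
    """
    cfg = cfg or SyntheticConfig()
    cal = _calibrate(cfg)
    h_l, h_g, deep = cal["h_l"], cal["h_g"], cal["deep"]
    clades, separations = cal["clades"], cal["separations"]

    # sample bookkeeping
    metadata: dict[str, SampleRecord] = {}
    species_assign: dict[str, str] = {}
    lineage_assign: dict[str, str] = {}
    clade_assign: dict[str, int] = {}
    structure: list[tuple[int, list[list[str]]]] = []  # species -> lineages -> ids
    for i in range(cfg.n_species):
        label = cfg.species_label(i)
        sizes = _lineage_sizes(cfg.samples_per_species, cfg.lineages.get(i, 1))
        lineage_ids: list[list[str]] = []
        k = 0
        for li, size in enumerate(sizes):
            lineage_label = f"{label}{li + 1}" if len(sizes) > 1 else label
            ids = []
            for _ in range(size):
                k += 1
                sid = f"{label}_{k:02d}"
                ids.append(sid)
                species_assign[sid] = label
                lineage_assign[sid] = lineage_label
                clade_assign[sid] = cfg.clade_of(i)
                metadata[sid] = SampleRecord(
                    sid,
                    species=label,
                    lineage=lineage_label if len(sizes) > 1 else None,
                    geography=_REGIONS[(i * 2 + li) % len(_REGIONS)],
                    habitat=_HABITATS[i % len(_HABITATS)],
                )
            lineage_ids.append(ids)
        structure.append((i, lineage_ids))

    alignments: dict[str, Alignment] = {}
    for locus_idx, locus in enumerate(cfg.loci):
        rng = np.random.default_rng([cfg.seed % (2**31), locus_idx])
        r = locus.rate
        root = rng.integers(0, 4, size=locus.length).astype(np.uint8)
        rows: dict[str, str] = {}

        def emit_species(i: int, ancestor: np.ndarray, depth: float) -> None:
            """Species ancestor branch, then lineage nodes and star tips."""
            _, lineage_ids = structure[i]
            n_lin = len(lineage_ids)
            h_sp = h_g if n_lin > 1 else h_l
            sp_seq = evolve(ancestor, max(0.0, depth - h_sp) * r, cfg.kappa, rng)
            for ids in lineage_ids:
                lin_seq = (
                    evolve(sp_seq, (h_g - h_l) * r, cfg.kappa, rng)
                    if n_lin > 1
                    else sp_seq
                )
                for sid in ids:
                    tip = evolve(lin_seq, h_l * r, cfg.kappa, rng)
                    rows[sid] = "".join(_BASES[c] for c in tip)

        for clade_id, members in sorted(clades.items()):
            if cfg.n_species == 1:
                emit_species(members[0], root, h_g if cfg.lineages.get(members[0], 1) > 1 else h_l)
                continue
            if len(members) == 1:
                emit_species(members[0], root, deep / 2.0)
                continue
            # caterpillar down the clade ladder: species members[j] joins at
            # depth seps[j-1]/2 (ascending), members[0] at the shallowest node
            node_depths = [s / 2.0 for s in separations[clade_id]]
            current = evolve(
                root, (deep / 2.0 - node_depths[-1]) * r, cfg.kappa, rng
            )
            for j in range(len(members) - 1, 0, -1):
                emit_species(members[j], current, node_depths[j - 1])
                next_depth = node_depths[j - 2] if j >= 2 else None
                if next_depth is not None:
                    current = evolve(
                        current, (node_depths[j - 1] - next_depth) * r,
                        cfg.kappa, rng,
                    )
            emit_species(members[0], current, node_depths[0])
        ordered = list(species_assign)
        alignments[locus.name] = Alignment(
            locus.name, ordered, [rows[s] for s in ordered]
        )
    return SimulatedDataset(
        cfg,
        alignments,
        metadata,
        Partition(species_assign),
        Partition(lineage_assign),
        clade_assign,
    )


def make_planted_matrix(
    n_groups: int = 5,
    samples_per_group: int = 8,
    intra_max: float = 0.003,
    inter_low: float = 0.03,
    inter_high: float = 0.05,
    seed: int = 0,
) -> tuple[DistanceMatrix, Partition]:
    """Distance matrix with planted groups, drawn directly.

    Intra-group distances ~ U(0, intra_max); inter-group ~ U(inter_low,
    inter_high); requires ``intra_max < inter_low``.  The matrix is
    symmetric with a zero diagonal; the triangle inequality is not enforced
    (single linkage is robust to this).  Fast path for delimitation tests.
    """
    if not intra_max < inter_low <= inter_high:
        raise ValueError("need intra_max < inter_low <= inter_high")
    rng = np.random.default_rng(seed)
    ids, group = [], {}
    for g in range(n_groups):
        label = chr(ord("A") + g)
        for k in range(samples_per_group):
            sid = f"{label}_{k + 1:02d}"
            ids.append(sid)
            group[sid] = label
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        same = group[ids[i]] == group[ids[j]]
        v = (
            rng.uniform(0.0, intra_max)
            if same
            else rng.uniform(inter_low, inter_high)
        )
        d[i, j] = d[j, i] = v
    used = np.ones((n, n), dtype=int)
    return DistanceMatrix(ids, d, used, "planted"), Partition(group)


def _random_topology(ids: list[str], rng: np.random.Generator):
    """Random bifurcating rooted topology as nested tuples."""
    nodes: list = list(ids)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def random_clonal_alignment(
    n_taxa: int,
    length: int,
    height: float,
    kappa: float = 2.0,
    rng: np.random.Generator | None = None,
    ids: list[str] | None = None,
    name: str = "clonal",
) -> Alignment:
    """Alignment evolved on one random tree (no recombination).

    The topology is a random bifurcation history; node depths shrink
    geometrically from the root height.  Useful as the clonal null for the
    PHI test.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    ids = ids or [f"t{i + 1}" for i in range(n_taxa)]
    topo = _random_topology(list(ids), rng)
    root = rng.integers(0, 4, size=length).astype(np.uint8)
    rows: dict[str, str] = {}

    def walk(node, seq, depth):
        if isinstance(node, str):
            tip = evolve(seq, depth, kappa, rng)
            rows[node] = "".join(_BASES[c] for c in tip)
            return
        child_depth = depth * rng.uniform(0.3, 0.8)
        for child in node:
            walk(child, evolve(seq, depth - child_depth, kappa, rng), child_depth)

    walk(topo, root, height)
    return Alignment(name, list(ids), [rows[s] for s in ids])
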