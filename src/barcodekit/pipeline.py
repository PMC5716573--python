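"""Full-analysis orchestration: per-locus, two-locus combinations and the
combined dataset, emitting site-classification, divergence, barcoding-gap,
ABGD, tree, network and PHI reports plus a run manifest.

Machine outputs are unrounded; display rounding is applied only in
human-readable columns.  Every stage failure is isolated and logged; the run
raises at the end if any stage failed.
"""

from __future__ import annotations

import json
import logging
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abgd import AbgdConfig, abgd, write_result
from .alignment import (
    Alignment,
    concatenate,
    mask_columns,
    classify_sites,
    read_alignment,
    read_metadata,
    write_locus_map,
)
from .distances import distance_matrix, divergence_table, group_divergence
from .gapstats import gap_summary, histogram_data, partition_pairs
from .network import collapse_haplotypes, cluster_separation, median_joining, mp_prune
from .partition import Partition
from .phi import phi_permutation_test
from .trees import bootstrap_support, upgma, write_newick

log = logging.getLogger("barcodekit")

__all__ = ["RunConfig", "run_pipeline", "barcode_discrimination", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Inputs and knobs for one full run.

    ``loci`` maps locus name -> aligned FASTA path; ``nuclear`` names the loci
    to PHI-test; ``combinations`` lists two-locus concatenations.
    """

    loci: dict
    metadata: str
    outdir: str
    nuclear: list = field(default_factory=list)
    combinations: list = field(default_factory=list)  # e.g. [["matK", "rbcL"]]
    deletion: str = "pairwise"
    models: list = field(default_factory=lambda: ["K2P", "p"])
    abgd: dict = field(default_factory=dict)  # locus name -> AbgdConfig kwargs
    bootstrap: int = 100
    consensus_threshold: float = 0.75
    phi_window: int = 100
    phi_permutations: int = 1000
    exclude_groups: list = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def barcode_discrimination(part_true: Partition, part_inferred: Partition):
    """Per-species resolution report.

    A true group is resolved when some inferred group has identical
    membership.  Returns (per-group dict, overall percent resolved).
    """
    if set(part_true.samples) != set(part_inferred.samples):
        raise ValueError("partitions cover different sample sets")
    inferred_sets = part_inferred.member_sets()
    report = {
        g: frozenset(members) in inferred_sets
        for g, members in part_true.groups().items()
    }
    pct = 100.0 * sum(report.values()) / len(report)
    return report, pct


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _analyze_unit(
    name: str,
    aln: Alignment,
    part: Partition,
    cfg: RunConfig,
    outdir: Path,
    metadata,
    is_nuclear: bool,
) -> dict:
    unit_dir = outdir / name
    unit_dir.mkdir(parents=True, exist_ok=True)
    info: dict = {"name": name, "n_samples": aln.n_samples, "stages": {}}

    masked = mask_columns(aln)
    info["alignment_length"] = aln.length
    info["analyzed_length"] = masked.length

    def stage(label, fn):
        try:
            fn()
            info["stages"][label] = "ok"
        except Exception as exc:  # isolated per-stage failure
            log.exception("stage %s/%s failed", name, label)
            info["stages"][label] = f"failed: {exc}"

    def site_classes():
        sc = classify_sites(masked)
        pd.DataFrame(
            [
                {
                    "length": sc.length,
                    "conserved": sc.conserved,
                    "variable": sc.variable,
                    "parsimony_informative": sc.parsimony_informative,
                    "singleton": sc.singleton,
                    "percent_informative": sc.percent_informative,
                }
            ]
        ).to_csv(unit_dir / "site_classes.tsv", sep="\t", index=False)

    stage("site_classes", site_classes)

    dms = {}

    def dists():
        for model in cfg.models:
            dm = distance_matrix(masked, model=model, deletion=cfg.deletion)
            dm.write_tsv(unit_dir / f"distances_{model}.tsv")
            dm.write_phylip(unit_dir / f"distances_{model}.phy")
            dms[model] = dm

    stage("distances", dists)
    if "K2P" not in dms:
        info["stages"]["remaining"] = "skipped: no K2P matrix"
        return info
    dm = dms["K2P"]

    def divergences():
        gd = group_divergence(dm, part)
        gd.to_frame().to_csv(unit_dir / "group_divergence_K2P.tsv", sep="\t")
        if "p" in dms:
            divergence_table(dm, dms["p"], part).to_csv(
                unit_dir / "divergence_table.tsv", sep="\t"
            )

    stage("group_divergence", divergences)

    def gap():
        gs = gap_summary(dm, part, locus=name,
                         exclude_groups=tuple(cfg.exclude_groups))
        pd.DataFrame([gs.to_row()]).to_csv(
            unit_dir / "gap_summary.tsv", sep="\t", index=False
        )
        intra, inter = partition_pairs(dm, part, tuple(cfg.exclude_groups))
        histogram_data(intra, inter).to_csv(
            unit_dir / "gap_histogram.tsv", sep="\t", index=False
        )
        info["gap_present"] = bool(gs.gap_present)
        info["fold_mean"] = gs.fold.fold_mean

    stage("gap_stats", gap)

    def delimit():
        kwargs = cfg.abgd.get(name, {})
        result = abgd(dm, AbgdConfig(**kwargs) if kwargs else AbgdConfig())
        write_result(result, str(unit_dir / "abgd"))
        info["abgd_initial_groups"] = [
            r.n_groups_initial for r in result.by_prior
        ]

    stage("abgd", delimit)

    def build_trees():
        tree, _ = bootstrap_support(
            masked, model="K2P", builder="nj", b=cfg.bootstrap, seed=cfg.seed
        )
        write_newick(tree, unit_dir / "nj_K2P.nwk")
        write_newick(upgma(dm), unit_dir / "upgma_K2P.nwk")

    stage("trees", build_trees)

    def net():
        haplos = collapse_haplotypes(masked, metadata)
        network = mp_prune(median_joining(haplos))
        network.write_graphml(unit_dir / "haplotype_network.graphml")
        network.write_edgelist(unit_dir / "haplotype_network_edges.tsv")
        info["n_haplotypes"] = len(haplos)
        groups, sep = cluster_separation(network, part)
        pd.DataFrame(sep, index=groups, columns=groups).to_csv(
            unit_dir / "cluster_separation_steps.tsv", sep="\t"
        )

    stage("haplotype_network", net)

    if is_nuclear:

        def phi():
            res = phi_permutation_test(
                masked, w=cfg.phi_window, n_perm=cfg.phi_permutations,
                seed=cfg.seed,
            )
            res.write_tsv(unit_dir / "phi.tsv")
            info["phi_p"] = res.p_value

        stage("phi", phi)
    return info


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured unit and write the manifest; returns the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata = read_metadata(cfg.metadata)

    alns = {
        name: read_alignment(path, name) for name, path in cfg.loci.items()
    }
    units: list[tuple[str, Alignment, bool]] = [
        (name, aln, name in cfg.nuclear) for name, aln in alns.items()
    ]
    for combo in cfg.combinations:
        combined, _ = concatenate([alns[n] for n in combo], name="+".join(combo))
        units.append((combined.locus_name, combined, False))
    plastid = [a for n, a in alns.items() if n not in cfg.nuclear]
    if len(plastid) > 1:
        cp, _ = concatenate(plastid, name="combined_cp")
        units.append(("combined_cp", cp, False))
    if len(alns) > 1:
        allc, spans = concatenate(list(alns.values()), name="combined_all")
        write_locus_map(spans, outdir / "combined_locus_map.tsv")
        units.append(("combined_all", allc, False))

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "deletion": cfg.deletion,
        "inputs": {n: _digest(Path(p)) for n, p in cfg.loci.items()},
        "units": [],
    }
    failures = []
    for name, aln, is_nuc in units:
        part = Partition(
            {
                s: metadata[s].species or "unassigned"
                for s in aln.sample_ids
            }
        )
        info = _analyze_unit(name, aln, part, cfg, outdir, metadata, is_nuc)
        manifest["units"].append(info)
        failures.extend(
            f"{name}/{k}" for k, v in info["stages"].items()
            if str(v).startswith("failed")
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if failures:
        raise PipelineError(f"stages failed: {failures}")
    return manifest
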