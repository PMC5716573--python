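"""Median-joining haplotype network with MP pruning and mutation-step
separations between species clusters.
"""

from barcodekit import (
    SyntheticConfig,
    cluster_separation,
    collapse_haplotypes,
    concatenate,
    mask_columns,
    median_joining,
    mp_prune,
    simulate,
)

ds = simulate(SyntheticConfig(seed=1))
combined, _ = concatenate(ds.plastid_loci())
masked = mask_columns(combined)

haplos = collapse_haplotypes(masked, ds.metadata)
print(f"{len(haplos)} haplotypes from {masked.n_samples} samples")
for h in haplos[:5]:
    geo = ", ".join(f"{k}x{v}" for k, v in sorted(h.geography.items()))
    print(f"  {h.hap_id}: multiplicity {h.multiplicity}  ({geo})")

net = mp_prune(median_joining(haplos))
print(f"network: {len(net.observed)} observed nodes, "
      f"{len(net.medians)} median vectors, "
      f"{net.graph.number_of_edges()} links")

groups, sep = cluster_separation(net, ds.species_partition)
print("minimum mutation steps between species:")
print("    " + "  ".join(f"{g:>4s}" for g in groups))
for i, g in enumerate(groups):
    print(f"{g:>4s} " + "  ".join(f"{int(sep[i, j]):4d}" for j in range(len(groups))))
# Off-diagonal entries are the fewest mutation steps along the network
# between any two haplotypes of the two species - tens of steps between
# species vs a handful within.
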