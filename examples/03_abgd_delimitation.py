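"""Automatic barcode-gap discovery: delimit candidate species without a
priori hypotheses, across a scan of prior intraspecific divergences.

The initial partition splits at the most prominent distance gap; the
recursive pass re-applies the search inside each group and resolves the
finer lineage structure at small priors.
"""

from barcodekit import (
    AbgdConfig,
    SyntheticConfig,
    abgd,
    barcode_discrimination,
    concatenate,
    distance_matrix,
    mask_columns,
    simulate,
)

ds = simulate(SyntheticConfig(seed=1))
combined, _ = concatenate(ds.plastid_loci())
dm = distance_matrix(mask_columns(combined))

result = abgd(dm, AbgdConfig(pmin=0.001, pmax=0.1, n_steps=10, X=1.5))
print("prior     threshold  initial  recursive")
for r in result.by_prior:
    thr = f"{r.threshold:.4f}" if r.threshold is not None else "none"
    print(f"{r.prior:8.4f}  {thr:>9s}  {r.n_groups_initial:7d}  {r.n_groups_recursive:9d}")

mid = result.at_prior(0.01)
report, pct = barcode_discrimination(ds.species_partition, mid.initial)
print(f"\nat prior {mid.prior:.4f}: initial partition resolves {pct:.0f}% of the "
      f"true species ({sum(report.values())}/{len(report)})")
# Initial groups match the 5 planted species across the mid-prior range;
# the larger recursive counts at small priors are the planted lineages.
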