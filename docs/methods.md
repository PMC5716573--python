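# Methods

## Scope and data model

`barcodekit` delimits cryptic species from multilocus barcode alignments by
distance methods only: no likelihood or Bayesian tree inference, no model
selection, and no de novo multiple alignment (inputs must arrive aligned).
Distances are stored internally as proportions (substitutions/site) and
multiplied by 100 exactly once, in report writers; coordinates are 0-based
half-open internally and 1-based closed in report files.

## Distances

Transitions are A↔G and C↔T; all other changes among the four bases are
transversions. The three models are uncorrected *p* = mismatches/usable
sites, JC69 `d = -¾ ln(1 - 4p/3)` and K2P
`d = -½ ln(1-2P-Q) - ¼ ln(1-2Q)`. A non-positive logarithm argument
(saturation) raises a hard error by default: barcode-scale divergences
(< 20 %) cannot saturate, so silent capping would only hide corrupted
input. The matrix layer offers saturation-tolerant mode (`drop`) that
records NaN with a warning; tree construction refuses NaN.

Two deletion policies exist because per-sample missing data remain after
regions of ambiguous alignment have been masked: `pairwise` (default at the
matrix layer) drops unusable sites per pair; `complete` first removes every
column with a gap/ambiguity in any row. Alignment masking
(`mask_columns`, default `drop_incomplete`) is the complete-deletion
analogue at the alignment level and is the default front step of the
pipeline. Within-group means over a singleton group are undefined and
reported with the `n/c` sentinel.

## Barcoding-gap statistics

Intra/inter pair partitioning covers all C(n,2) pairs of the included
samples; whole groups can be excluded (the convention for a species
represented by a single specimen). Percentiles use linear interpolation
between closest ranks (type-7); the definition is recorded in output
metadata because published tables rarely state it. The overlap statistics
are truncated at zero for reporting, with signed values retained as
diagnostics. `gap_present` is the classical criterion: maximum
intraspecific < minimum interspecific (Overlap¹ = 0); the percentile
overlaps are relaxed diagnostics only. Fold ratios are reported unrounded
and displayed to one decimal. The Mann–Whitney U test enumerates all
C(n1+n2, n1) assignments exactly when both samples have ≤ 8 values
(midranks for ties) and otherwise uses the normal approximation with tie
correction; distance pairs are treated as independent observations,
replicating standard practice, and every report carries a pseudo-replication
caveat because the n(n-1)/2 pairs share n samples.

## Gap discovery and delimitation

For each prior P in a geometric progression (default 10 steps,
0.001 → 0.1), pairwise distances are sorted ascending and consecutive gaps
`g_i = d_{i+1} - d_i` scanned. A gap qualifies when its upper endpoint
reaches the prior (distances strictly below the prior are treated as
guaranteed-intraspecific) and `g_i > X · s_i`, where `s_i` is the mean of
the W preceding consecutive gaps (zero-width gaps included, ties kept by a
stable sort), `W = max(10, ⌈0.05 · n_pairs⌉)`, and X is the relative gap
width (default 1.5, per-locus overrides supported). Among qualifying gaps
the **widest** is taken as the barcode gap and its midpoint becomes the
threshold. Widest-gap selection (rather than the first qualifying gap) is
what makes the two-pass structure meaningful: the initial partition splits
at the most prominent divergence scale, and the recursive pass —
re-applying the search within each group until nothing splits — resolves
finer lineage structure at small priors. It also yields the expected
monotonicity: as the prior rises only lower gaps drop out of the scan, so
the threshold moves weakly upward and the initial group count weakly
decreases. The first gap of a sorted list has no preceding gaps, hence no
local scale, and is never proposed. Grouping at a threshold is single
linkage (connected components of the `d ≤ threshold` graph), so between-group
distances are not guaranteed to all exceed the threshold, but no
within-threshold edge crosses groups.

With no qualifying gap the data form one group. At priors below the maximum
intraspecific distance the scan enters the intraspecific cloud, where gaps
between uniform-ish draws are approximately exponential and spurious
qualifying gaps are common; recovery of a planted partition is therefore
guaranteed only for priors between the maximum intraspecific and minimum
interspecific distance, which is how the delimitation tests are scoped.

## Trees

NJ follows the Saitou–Nei Q-criterion with agglomeration ties broken at the
smallest (i, j) index pair, so trees are deterministic; negative branch
lengths are clamped to zero without redistribution. UPGMA uses
size-weighted average linkage and returns a rooted ultrametric tree
(root-to-tip spread ≤ 1e-9, cross-checked against scipy's average-linkage
cophenetic distances in the tests). Bootstrap resamples alignment columns
with replacement — globally for concatenated datasets, with per-locus
stratified resampling available as an option — rebuilds the tree and counts
bipartition frequencies on the original topology; replicates with saturated
distances are dropped, warned about, and excluded from the denominator.
Majority-rule consensus keeps bipartitions at frequency ≥ the threshold
(default 0.75) and skips lower-frequency bipartitions that conflict with
already-accepted ones (only possible for thresholds ≤ 0.5). Trees are
scikit-bio `TreeNode` objects; supports are written as internal node labels
in Newick.

## Haplotype networks

Identical rows collapse into haplotypes numbered by first occurrence, with
multiplicities and per-node geography counts retained. Median joining
iterates: build the minimum spanning network within tolerance ε (default 0;
an edge is kept when its weight is within ε of the minimax path weight),
propose column-wise majority medians of connected triplets, and add the
candidate that most reduces the total connection cost (minimum-spanning-tree
weight over the node set); integer costs strictly decrease, so the loop
terminates. Triplet columns with three distinct states have no majority and
such triplets generate no median — no quasi-median expansion is performed.
This restriction, together with ε = 0, is the chief behavioural divergence
risk relative to the original median-joining software; medians are also
confined to the sequence space generated by observed states per column.
Edge weights are Hamming distances over the analyzed columns; indel and
ambiguous columns are expected to have been masked upstream, so they carry
no weight. Because a minimum spanning *network* retains all tied minimum
edges, its literal edge-weight sum can exceed the MST sum when exact ties
exist; the "medians never increase cost" guarantee therefore applies to the
total connection cost, which the tests assert. MP pruning removes every
edge (and any median vector left isolated) that lies on no minimal-cost path
between a pair of observed haplotypes; observed-pair shortest-path lengths
are provably unchanged and pruning is idempotent. Cluster separation
reports the minimum shortest-path weight between the haplotypes of two
groups; a haplotype whose members span groups contradicts the partition and
is an error.

## PHI test

Informative sites are parsimony-informative columns (≥ 2 states each in
≥ 2 rows, counted over unambiguous bases); sites with a singleton minority
state are compatible with every other site and carry no signal. The
refined incompatibility of a site pair is the cycle rank
(edges − vertices + components) of the bipartite graph of observed joint
states, which is the minimum number of extra mutations any tree must pay
and is 0 exactly for compatible pairs; each score is normalized by its
maximum (k_i−1)(k_j−1) for the observed state counts, and pairs whose
maximum is 0 are excluded. Φ_w is the mean over informative-site pairs at
most w alignment columns apart (w = 100 by default, measured in alignment
columns, not informative-site index). The null permutes the assignment of
site patterns to column positions, destroying spatial clustering while
preserving per-site patterns; since recombination makes *nearby* sites more
compatible than distant ones, the one-sided tail is
`#{Φ_perm ≤ Φ_obs}` and `p = (1 + hits)/(1 + n_perm)` — stated explicitly
because sign conventions differ across descriptions of the method. The
analytic normal approximation of the original method is deliberately
omitted; the permutation test is assumption-free and the score matrix is
computed once, so permutations are cheap.

## Synthetic data generator

The generator is the package's stand-in for a real multi-population
sequencing study and defines the conditions under which the pipeline is
validated: K = 5 cryptic species with 8 samples each, target mean
intraspecific K2P divergence 0.2 %, target mean interspecific 4 %, two deep
clades (3 + 2 species) 4.2 % apart, two species carrying two internal
lineages 0.5 % apart, five "plastid" loci (550–800 bp, rate multipliers
0.6–1.2) plus one "nuclear" locus at rate ×2.5 (the typical ITS-vs-plastid
spread), transition/transversion ratio κ = 2. Sequences evolve by the exact
per-site K2P substitution kernel for each branch length.

Genealogies are fixed trees, not coalescent simulations: within species the
sampling is star-like (every sample hangs at the same tip depth), and
within each deep clade the species sit on a caterpillar ladder whose split
depths are spread evenly up to 0.9 × the deep divergence. The ladder
matters: with only a handful of species, per-species-pair distances form
tight clusters (pairs share their internal branches), and two isolated
separation scales would create a spurious dominant gap inside the
interspecific distribution; spreading the splits makes the interspecific
distances a quasi-continuum below the cross-clade scale, as in real
multispecies data, so the barcoding gap is the most prominent gap. The
lowest species separation is solved linearly so the expected mean
interspecific divergence hits its target, and the within-lineage tip depth
is solved so the mean intraspecific divergence (including cross-lineage
pairs) hits its target; infeasible combinations (e.g. an intra target too
small for the configured lineage divergence) raise at construction. A
consequence of this calibration is that the spread of interspecific
distances is narrower than in real data of ten species; the generator
reproduces the *scales* of variation, not their full dispersion. All
plastid loci share the one genealogy (complete linkage); the nuclear locus
evolves independently on a congruent genealogy. No indels are simulated by
default (masking is exercised with explicit fixtures); recombination is
never simulated — PHI power tests splice alignments from two conflicting
genealogies directly.

`make_planted_matrix` skips sequences entirely and draws distances directly
(intra ~ U(0, a), inter ~ U(b, c), a < b, symmetric with zero diagonal,
triangle inequality not enforced — single linkage does not require it) as a
fast path for delimitation tests.

What passing tests on these data do and do not show: they validate the
statistical machinery under clean, calibrated separation with complete
linkage and no rate heterogeneity across sites, lineage sorting, gene-tree
conflict, contamination or alignment error; performance on real data with
those features is not certified by the suite.

## Problem sizes and determinism

The test suite runs end to end in about a minute: delimitation calibration
uses 100 seeded planted matrices (40 samples each), PHI calibration 100
clonal and 50 recombinant alignments (10 taxa, 800 columns, 199
permutations), and the full-pipeline check one default simulated dataset
(40 samples × ~3.5 kb plastid + 750 bp nuclear). Every stochastic component
(simulation, bootstrap, permutation) takes an explicit seed and is
bit-reproducible; the pipeline manifest records all seeds and input digests.

## Known limitations

- ABGD-style gap significance uses the window-scaled rule described above;
  the original software's slope heuristic is not reproduced, so real-data
  group counts may differ in detail even though the planted-gap behaviour
  is the contract.
- Median-joining without quasi-medians and with ε = 0 can omit median
  vectors the original tool would add for highly reticulate data.
- The U test on distance pairs inherits the field's pseudo-replication
  caveat; p-values are anti-conservative for clustered pairs.
- UPGMA assumes rate constancy; it is provided because ultrametric trees
  are the conventional display for delimitation overlays, not because the
  assumption is endorsed.
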