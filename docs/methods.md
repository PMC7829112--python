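# Methods

This note describes the models and procedures implemented in `gutshift`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot establish about real 16S surveys.

## The community-overlap partition

Two sample groups (here labelled SD, a fiber-containing standard diet,
and WD, a fiber-free Western diet) are each summarized as a profile of
mean relative ASV abundances. Each sample column is first normalized to
proportions, then averaged across the group's samples with equal
weight. Equal weighting (rather than pooling raw counts) prevents
deeply sequenced samples from dominating the profile; pooling is the
other defensible convention, and `group_profile` is the single place
the choice lives.

For profiles `p_A`, `p_B` over the union of retained ASVs, each group's
abundance is partitioned into three non-negative components:

* **unique_g** = Σ `p_g(i)` over ASVs with zero mean abundance in the
  other group;
* **shared** = Σ `min(p_A(i), p_B(i))` over co-occurring ASVs (nonzero
  in both);
* **increased_g** = Σ `p_g(i) − min(p_A(i), p_B(i))` over co-occurring
  ASVs.

The minimum is the unique per-ASV definition that makes
`unique_g + shared + increased_g = 100%` hold exactly for each group
while keeping `shared` symmetric between groups; both properties are
enforced by tests. "Unique" means exactly zero mean abundance in the
other group after filtering — no pseudo-counts are added.

### Random-split permutation null

The no-difference reference for the shared percentage is built by
repeatedly splitting one group's samples into two pseudo-groups of five
(100 splits by default), recomputing the statistic between the
pseudo-groups, and collecting the distribution. Splits are drawn
uniformly and independently across iterations, so duplicate
configurations may occur (only 126 distinct 5/5 splits of 10 samples
exist); a `unique_splits` flag enforces distinctness when wanted. The
prevalence/abundance filter is re-applied within each split by default,
treating pseudo-groups exactly like real groups; `refilter=False`
filters once globally instead.

A known design artifact, quantified during development: with groups of
4 and 10, the between-group statistic is not exactly exchangeable with
the 5-vs-5 null draws (different profile sample sizes, and the
prevalence filter acts once on all 14 samples for the between
comparison but per-split inside the null). Empirically the
between-group shared percent for data simulated from a single
composition sits about one null SD above the null mean and falls inside
the null's central 95% band for roughly 9 of 10 random seeds. The null
is therefore a qualitative no-difference reference, not a calibrated
p-value machine — which is also how it is used: a genuine community
shift separates from the null by tens of SDs, not one.

## Filtering

Order is fixed: sample depth → taxonomy → prevalence/abundance.

* **Depth**: samples with fewer than 1000 reads are removed; the bound
  is strict, so exactly 1000 reads is retained.
* **Taxonomy**: an ASV is removed if any lineage rank matches, case
  insensitively, one of {uncharacterized, Mitochondria, Chloroplast,
  Eukaryota}; ASVs absent from the taxonomy count as uncharacterized.
* **Prevalence/abundance**: an ASV is kept if it is observed (count
  > 0) in ≥ 2 samples overall **and** reaches ≥ 1% group-mean relative
  abundance in at least one of the two compared groups. Two readings of
  this rule are defensible; both are exposed: the AND/OR combination is
  `prevalence_abundance_logic`, and "1% across all samples of a group"
  is interpreted as the group-*mean* abundance (a per-sample-minimum
  reading removes nearly everything at n = 10 and is not offered).

Filters only drop rows/columns; retained counts are never modified.
Re-applying the chain is idempotent in the realistic regime where the
removed ASVs carry little read mass; it is not a theorem for arbitrary
tables (dropping ASVs lowers column sums, which could in principle push
a sample below the depth floor on a second pass).

## Synthetic communities

`simulate_community` draws a two-group ASV table with known ground
truth in place of unavailable raw data. Defaults describe the emulated
design: 120 ASVs, groups of 4 (SD) and 10 (WD) mice, mean depth 20,000
reads with a hard floor of 1000 (the depth-filter boundary), 5%
contaminant ASVs, and 20% support overlap between groups — a strong
diet-shift scenario.

Construction: `round(overlap_fraction × n_asvs)` ASVs get nonzero
expected abundance in both groups, the remainder is split between the
groups as exclusive support. Each group's mean composition is a
normalized vector of Exponential(1) weights on its support (a flat
Dirichlet draw, giving realistic rank-abundance skew). Each sample's
composition is Dirichlet with parameters `concentration × group_mean`
(default concentration 50 — strongly overdispersed relative to
multinomial, typical of 16S data); counts are multinomial at a depth of
`depth_min + Poisson(depth_mean − depth_min)`. Contaminant ASVs are
drawn by the same machinery and flagged only in their taxonomy, so
filtering must act through lineages, not abundances.
`identical_group_means=True` (requires full overlap) gives both groups
literally the same expected composition — the exchangeable control used
to validate the null.

What the generator does *not* emulate: sequencing error and chimeras,
phylogenetic correlation among ASVs, covariate structure (cage, sex,
time), or taxon-specific depth biases. Passing tests therefore show the
statistics behave correctly on overdispersed compositional counts with
known overlap — not that any particular biological dataset will show a
given shared percentage.

`simulate_alignment` evolves site-independent sequences along a tree
under TN93 (root states from the stationary frequencies, closed-form
transition probabilities per branch), providing ground-truth topologies
for the phylogenetics chain.

## Phylogenetics

* **Complete deletion** removes every column containing `-`, `N` or an
  IUPAC ambiguity code in any sequence, and reports the retained
  position count.
* **Composite-likelihood TN93 distances**: base frequencies are the
  average empirical composition; the two transition/transversion rate
  ratios are estimated once by maximizing the sum over all sequence
  pairs of the pairwise log-likelihood (Nelder–Mead over log-ratios,
  each pair profiled over its own distance by bounded scalar
  minimization, tolerance 1e-10). Distances are then the per-pair
  maximizers under the common parameters, in substitutions/site. This
  is the shared-parameter pairwise-likelihood construction in the
  spirit of Tamura–Nei–Kumar (2004), not a bit-for-bit re-creation of
  any particular GUI package. A pair whose fitted distance reaches the
  saturation bound (10 substitutions/site) raises an error naming the
  pair rather than returning an unstable number. Under equal
  frequencies and symmetric substitution counts the estimate reduces to
  the Jukes–Cantor closed form `−(3/4) ln(1 − 4p/3)`, verified
  analytically in the tests; with a single pair the composite
  likelihood is the full likelihood, verified against an independent
  matrix-exponential optimizer.
* **Neighbor joining** is the classical Saitou–Nei agglomeration with
  the Q criterion. It is deterministic: the scan runs over pairs in
  index order and ties go to the lowest pair. Negative branch lengths
  are retained with a warning (clamping to zero is available) because
  clamping would break the exact-recovery property on additive
  matrices, which is the algorithm's defining guarantee and the test
  suite's oracle. The unrooted tree is returned as a
  `skbio.TreeNode` with a trifurcating root; Newick round-trips
  topology and lengths.

## Reproductive-event arithmetic

All quantities are pure arithmetic over `ReproParams`:
births/day = `n_females × offspring_per_female / (generation_years ×
days_per_year)`; lifetime bacterial events = `daily_bacterial_cells ×
days_per_year × lifespan_years`; equivalent years = events /
(births/day × days/year); universe-age multiple = years / universe age.
The closure identity `years × births/day × days/year = lifetime events`
holds to relative 1e-12 by construction and is property-tested. A year
is 365 days by default (configurable); with the default parameters the
straight product gives 3.172e17 lifetime events where 3.16e17 is often
quoted — a ~0.4% rounding difference that is reported as computed, not
absorbed. Likewise the fiber calculator reports the loss bounds that
actually follow from 80–150 g vs 20 g/day (75% and 86.7%); the
sometimes-quoted 92.5% upper bound is not derivable from those inputs
and is flagged in the output notes instead of being presented as
computed truth.

## Problem sizes used in the shipped checks

The packaged verification runs use: 1000 random profiles for the
closure property; 100 random splits per null on 120 × 14 tables; 100
random additive matrices (4–12 taxa) for NJ exactness; and 50
simulate→distance→NJ replicates (8 taxa, 2000 sites) for end-to-end
topology recovery. These sizes give stable pass/fail behaviour at
negligible runtime on a single CPU.
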