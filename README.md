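# gutshift

Analyses for two-group 16S ASV studies of gut-microbiota shifts —
built around the question of what removing dietary fiber does to the
niche space of the gut.

`gutshift` is aimed at microbiome researchers who have a denoised ASV
count table (e.g. a dada2 output), a taxonomy and a sample-to-group
mapping, and want to quantify how much of two groups' communities is
actually the same. It provides:

* **Community-overlap partition.** Each group's mean relative-abundance
  profile `p_g` is split, per group, into three parts that sum to 100%:

  - *unique*: Σ `p_g(i)` over ASVs absent from the other group,
  - *shared*: Σ `min(p_A(i), p_B(i))` over co-occurring ASVs
    (symmetric between groups),
  - *increased*: Σ `p_g(i) − min(p_A(i), p_B(i))` — each group's
    excess over the shared minimum.

* **Random-split permutation null.** The shared percentage recomputed
  between two pseudo-groups of five samples drawn repeatedly from
  within one group — the no-difference reference distribution.
* **The standard 16S filter chain** (depth ≥ 1000 reads, strict;
  mitochondria/chloroplast/Eukaryota/uncharacterized removal;
  prevalence ≥ 2 samples and ≥ 1% group-mean abundance).
* **Distance phylogenetics**: complete deletion of gapped/ambiguous
  columns, Tamura–Nei (TN93) distances with parameters fitted by
  composite likelihood (the pairwise log-likelihoods summed over all
  pairs), classical Saitou–Nei neighbor joining, Newick output.
* **A synthetic two-group community generator** (Dirichlet-multinomial
  with controllable support overlap, depth variation and contaminant
  taxa) with recorded ground truth, and a TN93 sequence simulator.
* **Reproductive-event arithmetic** comparing gut-bacterial turnover in
  one person against the birth rate of the entire pre-agricultural
  human population, plus hunter-gatherer vs US fiber-intake ratios.

## Worked example

Simulate a strong diet-shift scenario (4 + 10 samples, 20% ASV-support
overlap between groups), then run filters, partition and null in one
go:

```sh
gutshift simulate --n-asvs 120 --seed 7 --out-prefix demo
# wrote demo_table.tsv (120 ASVs x 14 samples); true shared fraction 0.1601
gutshift overlap --table demo_table.tsv --taxonomy demo_taxonomy.tsv \
    --metadata demo_metadata.tsv --groups SD,WD \
    --null-group WD --n-splits 100 --seed 7 --out overlap.json
```

Key fields of `overlap.json` from that run:

```json
"partition": {
  "unique_pct":    {"SD": 69.25, "WD": 71.08},
  "shared_pct":    17.26,
  "increased_pct": {"SD": 13.49, "WD": 11.66},
  "n_co_occurring": 15
},
"null": {"shared_pct_mean": 77.58, "shared_pct_sd": 2.10}
```

Reading: after filtering (6 contaminant ASVs dropped by taxonomy, 48
rare/low-abundance ASVs dropped), only 17.3% of either group's
abundance is shared with the other — close to the generator's true
overlap of 16% — while random 5-vs-5 splits *within* the larger group
share 77.6% on average (SD 2.1). The between-group value sits ~29 null
SDs below the null mean: the two diets support largely different
communities, far beyond sampling noise. Each group's partition closes
to 100% (e.g. SD: 69.25 + 17.26 + 13.49).

The desk calculator:

```sh
gutshift evotime
```

```json
{
  "lifetime_bacterial_events": 3.17185e+17,
  "human_births_per_day": 2232.37,
  "years_equivalent": 3.8927e+11,
  "universe_age_multiple": 28.2
}
```

With ~1.1 × 10¹³ bacterial cells produced per day in one gut, a 79-year
life hosts ~3.2 × 10¹⁷ bacterial reproductive events; a pre-agricultural
humanity of 5 × 10⁶ females bearing 4.4 offspring per 27-year
generation (≈ 2232 births/day) would need ~3.9 × 10¹¹ years — about 28
universe ages — to match it.

Other subcommands: `gutshift filter`, `gutshift null`, `gutshift tree`
(aligned FASTA → Newick + summary), `gutshift fiber`, and
`gutshift run --config run.toml --out-dir out` for the full pipeline
with a checksummed, seed-reproducible manifest. Everything is equally
usable as a library (`import gutshift`); see `docs/methods.md` for the
models, defaults and design choices.

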