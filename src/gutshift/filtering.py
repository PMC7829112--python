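"""Sample- and ASV-level filters for ASV count tables.

Three filters are provided, applied in a fixed order by
:func:`apply_filter_chain`:

1. **Depth filter** — drop samples with fewer reads than a minimum
   (default 1000).  The bound is strict: a sample with exactly the
   minimum is retained.
2. **Taxonomy filter** — drop ASVs whose lineage contains a flagged
   label (mitochondria, chloroplast, Eukaryota, uncharacterized), the
   standard 16S contaminant screen.  ASVs missing from the taxonomy are
   treated as uncharacterized and dropped.
3. **Prevalence/abundance filter** — keep only ASVs observed in at
   least a minimum number of samples overall and reaching a minimum
   group-mean relative abundance in at least one of the two compared
   groups.

The chain is idempotent: applying it twice yields the same table.
Filters only ever drop rows/columns; retained counts are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from gutshift.io import AsvTable, SampleMetadata, TaxonomyTable

#: Lineage labels flagged as contaminants / unusable in 16S surveys.
DEFAULT_EXCLUDED_TAXA = frozenset(
    {"uncharacterized", "mitochondria", "chloroplast", "eukaryota"}
)


@dataclass
class FilterConfig:
    """Thresholds for the three-stage filter chain.

    Parameters
    ----------
    min_reads_per_sample:
        Samples with strictly fewer total reads are excluded.
    excluded_taxon_labels:
        Case-insensitive lineage labels that disqualify an ASV.
    min_prevalence_samples:
        An ASV must be observed (count > 0) in at least this many
        samples overall.
    min_group_mean_abundance:
        An ASV must reach this group-mean relative abundance in at
        least one of the two compared groups.
    prevalence_abundance_logic:
        ``"AND"`` requires both the prevalence and the abundance
        criterion to keep an ASV; ``"OR"`` requires either.
    """

    min_reads_per_sample: int = 1000
    excluded_taxon_labels: frozenset = DEFAULT_EXCLUDED_TAXA
    min_prevalence_samples: int = 2
    min_group_mean_abundance: float = 0.01
    prevalence_abundance_logic: str = "AND"

    def __post_init__(self) -> None:
        if self.min_reads_per_sample < 0:
            raise ValueError("min_reads_per_sample must be >= 0")
        if not 0.0 <= self.min_group_mean_abundance <= 1.0:
            raise ValueError("min_group_mean_abundance must be in [0, 1]")
        if self.prevalence_abundance_logic not in ("AND", "OR"):
            raise ValueError("prevalence_abundance_logic must be 'AND' or 'OR'")
        self.excluded_taxon_labels = frozenset(
            str(x).lower() for x in self.excluded_taxon_labels
        )


@dataclass
class FilterReport:
    """Accounting of what a filter removed and why."""

    stage: str
    samples_removed: List[Tuple[str, str]] = field(default_factory=list)
    asvs_removed: List[Tuple[str, str]] = field(default_factory=list)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_asvs_before: int = 0
    n_asvs_after: int = 0

    def check(self) -> None:
        """Assert the before - removed = after identity on both axes."""
        assert self.n_samples_before - len(self.samples_removed) == self.n_samples_after
        assert self.n_asvs_before - len(self.asvs_removed) == self.n_asvs_after


def _report(stage: str, before: AsvTable, after: AsvTable,
            samples_removed, asvs_removed) -> FilterReport:
    rep = FilterReport(
        stage=stage,
        samples_removed=list(samples_removed),
        asvs_removed=list(asvs_removed),
        n_samples_before=before.n_samples,
        n_samples_after=after.n_samples,
        n_asvs_before=before.n_asvs,
        n_asvs_after=after.n_asvs,
    )
    rep.check()
    return rep


def filter_samples_by_depth(
    table: AsvTable, config: FilterConfig = FilterConfig()
) -> Tuple[AsvTable, FilterReport]:
    """Remove samples whose read total is strictly below the minimum.

    A sample with exactly ``min_reads_per_sample`` reads is retained.
    Raises if every sample would be removed.
    """
    depths = table.sample_depths()
    keep = [s for s, d in zip(table.sample_ids, depths)
            if d >= config.min_reads_per_sample]
    removed = [
        (s, f"depth {d} < {config.min_reads_per_sample}")
        for s, d in zip(table.sample_ids, depths)
        if d < config.min_reads_per_sample
    ]
    if not keep:
        raise ValueError(
            f"all {table.n_samples} samples fall below "
            f"{config.min_reads_per_sample} reads"
        )
    out = table.subset(sample_ids=keep)
    return out, _report("depth", table, out, removed, [])


def filter_taxa(
    table: AsvTable,
    taxonomy: TaxonomyTable,
    config: FilterConfig = FilterConfig(),
) -> Tuple[AsvTable, FilterReport]:
    """Remove ASVs whose lineage matches an excluded label.

    Matching is case-insensitive and per-rank.  An ASV absent from the
    taxonomy is treated as uncharacterized and removed.
    """
    excluded = config.excluded_taxon_labels
    keep: List[str] = []
    removed: List[Tuple[str, str]] = []
    for asv_id in table.asv_ids:
        lineage = taxonomy.get(asv_id)
        if lineage is None:
            removed.append((asv_id, "missing from taxonomy (uncharacterized)"))
            continue
        hit = next(
            (rank for rank in lineage if rank.strip().lower() in excluded), None
        )
        if hit is not None:
            removed.append((asv_id, f"lineage label {hit!r}"))
        else:
            keep.append(asv_id)
    out = table.subset(asv_ids=keep)
    return out, _report("taxonomy", table, out, [], removed)


def relative_abundance(table: AsvTable) -> np.ndarray:
    """Column-normalized proportions; zero-depth columns stay all-zero."""
    counts = table.counts.astype(float)
    depths = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(depths > 0, counts / depths, 0.0)
    return rel


def group_columns(
    table: AsvTable, metadata: SampleMetadata, group: str
) -> List[int]:
    """Column indices of the samples assigned to ``group``."""
    missing = [s for s in table.sample_ids if s not in metadata]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    return [j for j, s in enumerate(table.sample_ids) if metadata[s] == group]


def filter_prevalence_abundance(
    table: AsvTable,
    metadata: SampleMetadata,
    group_pair: Sequence[str],
    config: FilterConfig = FilterConfig(),
) -> Tuple[AsvTable, FilterReport]:
    """Keep ASVs that are prevalent overall and abundant in some group.

    Prevalence: observed (count > 0) in at least
    ``min_prevalence_samples`` samples across the whole table.
    Abundance: group-mean relative abundance (per-sample proportions
    averaged with equal sample weight) of at least
    ``min_group_mean_abundance`` in at least one of the two groups.
    The two criteria combine per ``prevalence_abundance_logic``.
    """
    if len(group_pair) != 2:
        raise ValueError("group_pair must name exactly two groups")
    cols = {g: group_columns(table, metadata, g) for g in group_pair}
    for g, idx in cols.items():
        if not idx:
            raise ValueError(f"group {g!r} has no samples in the table")
    rel = relative_abundance(table)
    prevalence = (table.counts > 0).sum(axis=1)
    group_means = {g: rel[:, idx].mean(axis=1) for g, idx in cols.items()}
    keep: List[str] = []
    removed: List[Tuple[str, str]] = []
    for i, asv_id in enumerate(table.asv_ids):
        prevalent = prevalence[i] >= config.min_prevalence_samples
        abundant = any(
            group_means[g][i] >= config.min_group_mean_abundance
            for g in group_pair
        )
        ok = (prevalent and abundant) if config.prevalence_abundance_logic == "AND" \
            else (prevalent or abundant)
        if ok:
            keep.append(asv_id)
        else:
            reasons = []
            if not prevalent:
                reasons.append(
                    f"prevalence {prevalence[i]} < {config.min_prevalence_samples}"
                )
            if not abundant:
                reasons.append(
                    "group-mean abundance below "
                    f"{config.min_group_mean_abundance:g} in both groups"
                )
            removed.append((asv_id, "; ".join(reasons)))
    out = table.subset(asv_ids=keep)
    return out, _report("prevalence_abundance", table, out, [], removed)


def apply_filter_chain(
    table: AsvTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    group_pair: Sequence[str],
    config: FilterConfig = FilterConfig(),
) -> Tuple[AsvTable, List[FilterReport]]:
    """Depth -> taxonomy -> prevalence/abundance, in that fixed order."""
    t1, r1 = filter_samples_by_depth(table, config)
    t2, r2 = filter_taxa(t1, taxonomy, config)
    t3, r3 = filter_prevalence_abundance(t2, metadata, group_pair, config)
    return t3, [r1, r2, r3]
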