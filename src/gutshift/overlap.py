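"""Community-overlap partition between two groups and its permutation null.

Each group's community is summarized as a profile of mean relative ASV
abundances.  Between two profiles ``p_A`` and ``p_B`` the abundance of
each group is split into three non-negative components that close to
100%:

* **unique** — abundance in ASVs with zero mean abundance in the other
  group;
* **shared** — for each co-occurring ASV (nonzero in both groups), the
  group-symmetric minimum ``min(p_A(i), p_B(i))``, summed;
* **increased** — each group's excess above the shared minimum on
  co-occurring ASVs.

``shared`` is the same number from either group's perspective (a sum of
minima is symmetric), so the partition per group is
``unique_g + shared + increased_g = 100``.

The permutation null re-draws the statistic between two pseudo-groups
split at random from within a single biological group, giving the
no-difference reference distribution for the between-group shared
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from gutshift.filtering import (
    FilterConfig,
    apply_filter_chain,
    filter_prevalence_abundance,
    group_columns,
    relative_abundance,
)
from gutshift.io import AsvTable, SampleMetadata, TaxonomyTable

_NORM_TOL = 1e-9


@dataclass
class GroupProfile:
    """Per-ASV mean relative abundances for one sample group."""

    group: str
    asv_ids: List[str]
    abundances: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.asv_ids),):
            raise ValueError("abundances must align with asv_ids")
        if (self.abundances < 0).any():
            raise ValueError("abundances must be non-negative")

    def is_normalized(self) -> bool:
        return abs(self.abundances.sum() - 1.0) <= _NORM_TOL

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.asv_ids, self.abundances))


@dataclass
class OverlapPartition:
    """The unique / shared / increased partition, in percent."""

    group_a: str
    group_b: str
    unique_pct_a: float
    unique_pct_b: float
    shared_pct: float
    increased_pct_a: float
    increased_pct_b: float
    co_occurring_asvs: frozenset

    def closure_residuals(self) -> tuple:
        """Deviation of each group's partition sum from 100."""
        return (
            self.unique_pct_a + self.shared_pct + self.increased_pct_a - 100.0,
            self.unique_pct_b + self.shared_pct + self.increased_pct_b - 100.0,
        )


@dataclass
class NullSplitResult:
    """Shared-percent distribution over random within-group splits."""

    group: str
    shared_pcts: List[float]
    n_splits: int
    split_size: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.shared_pcts))

    @property
    def sd(self) -> float:
        return float(np.std(self.shared_pcts, ddof=1))

    def central_interval(self, level: float = 0.95) -> tuple:
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(self.shared_pcts, [lo, 1.0 - lo]))


def group_profile(
    table: AsvTable, metadata: SampleMetadata, group: str
) -> GroupProfile:
    """Mean relative-abundance profile of one group.

    Each sample column is normalized to proportions first, then the
    group's samples are averaged with equal weight, so deeply sequenced
    samples do not dominate the profile.
    """
    cols = group_columns(table, metadata, group)
    if not cols:
        raise ValueError(f"group {group!r} has no samples in the table")
    depths = table.sample_depths()[cols]
    if not (depths > 0).all():
        empty = [table.sample_ids[c] for c, d in zip(cols, depths) if d == 0]
        raise ValueError(f"group {group!r} has zero-count samples: {empty}")
    rel = relative_abundance(table)[:, cols]
    return GroupProfile(group, list(table.asv_ids), rel.mean(axis=1), len(cols))


def _aligned(profile_a: GroupProfile, profile_b: GroupProfile):
    """Union the two ASV universes; absent ASVs contribute zero."""
    ids = list(profile_a.asv_ids)
    seen = set(ids)
    ids += [a for a in profile_b.asv_ids if a not in seen]
    da, db = profile_a.as_dict(), profile_b.as_dict()
    pa = np.array([da.get(a, 0.0) for a in ids])
    pb = np.array([db.get(a, 0.0) for a in ids])
    return ids, pa, pb


def partition_overlap(
    profile_a: GroupProfile, profile_b: GroupProfile
) -> OverlapPartition:
    """Partition the two groups' abundance into unique/shared/increased."""
    for p in (profile_a, profile_b):
        if not p.is_normalized():
            raise ValueError(
                f"profile for group {p.group!r} is not normalized "
                f"(sums to {p.abundances.sum():.12g})"
            )
    ids, pa, pb = _aligned(profile_a, profile_b)
    co = (pa > 0) & (pb > 0)
    mins = np.minimum(pa, pb)
    shared = float(mins[co].sum())
    unique_a = float(pa[pb == 0].sum())
    unique_b = float(pb[pa == 0].sum())
    increased_a = float((pa[co] - mins[co]).sum())
    increased_b = float((pb[co] - mins[co]).sum())
    return OverlapPartition(
        group_a=profile_a.group,
        group_b=profile_b.group,
        unique_pct_a=100.0 * unique_a,
        unique_pct_b=100.0 * unique_b,
        shared_pct=100.0 * shared,
        increased_pct_a=100.0 * increased_a,
        increased_pct_b=100.0 * increased_b,
        co_occurring_asvs=frozenset(np.array(ids)[co]),
    )


def _pseudo_partition(
    table: AsvTable,
    sample_split: Sequence[Sequence[str]],
    config: FilterConfig,
    refilter: bool,
) -> OverlapPartition:
    """Overlap partition between two pseudo-groups of named samples."""
    labels = {"_split0": list(sample_split[0]), "_split1": list(sample_split[1])}
    sub = table.subset(sample_ids=labels["_split0"] + labels["_split1"])
    meta = {s: g for g, ss in labels.items() for s in ss}
    if refilter:
        sub, _ = filter_prevalence_abundance(
            sub, meta, ("_split0", "_split1"), config
        )
    pa = group_profile(sub, meta, "_split0")
    pb = group_profile(sub, meta, "_split1")
    return partition_overlap(pa, pb)


def random_split_null(
    table: AsvTable,
    metadata: SampleMetadata,
    group: str,
    n_splits: int = 100,
    split_size: int = 5,
    seed: int = 0,
    config: FilterConfig = FilterConfig(),
    refilter: bool = True,
    unique_splits: bool = False,
) -> NullSplitResult:
    """Shared-percent null from random splits within one group.

    For each of ``n_splits`` iterations, ``2 * split_size`` of the
    group's samples are drawn without replacement and divided into two
    pseudo-groups; samples beyond ``2 * split_size`` are left out of
    that split.  With ``refilter`` (default) the prevalence/abundance
    filter is re-applied within each split, treating pseudo-groups
    exactly like real groups.  Splits are drawn independently across
    iterations, so duplicate configurations can occur unless
    ``unique_splits`` is set (which requires enough distinct splits to
    exist).  Fixed ``seed`` reproduces the result bit-exactly.
    """
    cols = group_columns(table, metadata, group)
    samples = [table.sample_ids[j] for j in cols]
    if len(samples) < 2 * split_size:
        raise ValueError(
            f"group {group!r} has {len(samples)} samples; "
            f"need at least {2 * split_size}"
        )
    rng = np.random.default_rng(seed)
    shared: List[float] = []
    seen: set = set()
    attempts = 0
    while len(shared) < n_splits:
        perm = rng.permutation(len(samples))
        left = frozenset(perm[:split_size])
        right = frozenset(perm[split_size : 2 * split_size])
        key = tuple(sorted((tuple(sorted(left)), tuple(sorted(right)))))
        if unique_splits:
            attempts += 1
            if key in seen:
                if attempts > 100 * n_splits:
                    raise ValueError("cannot find enough unique splits")
                continue
            seen.add(key)
        split = (
            [samples[i] for i in sorted(left)],
            [samples[i] for i in sorted(right)],
        )
        part = _pseudo_partition(table, split, config, refilter)
        shared.append(part.shared_pct)
    return NullSplitResult(group, shared, n_splits, split_size, seed)


def compare_groups(
    table: AsvTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    group_pair: Sequence[str],
    config: FilterConfig = FilterConfig(),
    null_group: Optional[str] = None,
    n_splits: int = 100,
    split_size: int = 5,
    seed: int = 0,
) -> dict:
    """Run the full chain: filters -> profiles -> partition -> null.

    Returns a plain-dict report (JSON-serializable) with the filter
    accounting, both group profiles' sizes, every partition component,
    and — if ``null_group`` is given — the within-group null summary.
    """
    filtered, reports = apply_filter_chain(
        table, taxonomy, metadata, group_pair, config
    )
    prof_a = group_profile(filtered, metadata, group_pair[0])
    prof_b = group_profile(filtered, metadata, group_pair[1])
    part = partition_overlap(prof_a, prof_b)
    out = {
        "groups": list(group_pair),
        "n_asvs_retained": filtered.n_asvs,
        "n_samples_retained": filtered.n_samples,
        "filter_stages": [
            {
                "stage": r.stage,
                "samples_removed": len(r.samples_removed),
                "asvs_removed": len(r.asvs_removed),
            }
            for r in reports
        ],
        "partition": {
            "unique_pct": {group_pair[0]: part.unique_pct_a,
                           group_pair[1]: part.unique_pct_b},
            "shared_pct": part.shared_pct,
            "increased_pct": {group_pair[0]: part.increased_pct_a,
                              group_pair[1]: part.increased_pct_b},
            "increased_pct_total": part.increased_pct_a + part.increased_pct_b,
            "n_co_occurring": len(part.co_occurring_asvs),
        },
    }
    if null_group is not None:
        # the null operates on the depth/taxonomy-filtered table so each
        # split can apply its own prevalence filter
        from gutshift.filtering import filter_samples_by_depth, filter_taxa

        t1, _ = filter_samples_by_depth(table, config)
        t2, _ = filter_taxa(t1, taxonomy, config)
        null = random_split_null(
            t2, metadata, null_group,
            n_splits=n_splits, split_size=split_size, seed=seed, config=config,
        )
        out["null"] = {
            "group": null_group,
            "n_splits": null.n_splits,
            "split_size": null.split_size,
            "seed": null.seed,
            "shared_pct_mean": null.mean,
            "shared_pct_sd": null.sd,
            "shared_pct_ci95": list(null.central_interval(0.95)),
            "shared_pcts": null.shared_pcts,
        }
    return out
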