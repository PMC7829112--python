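"""Synthetic two-group ASV communities and alignments with known truth.

The community generator emulates the structure of a two-diet-group 16S
mouse study: a small standard-diet group and a larger western-diet
group, overdispersed compositions, per-sample sequencing-depth
variation around a mean with a hard floor, and a sprinkling of
contaminant ASVs (mitochondria / chloroplast / Eukaryota /
uncharacterized) that must be removed by taxonomy, not by abundance.

Counts follow a Dirichlet-multinomial construction: each group has a
mean composition over its ASV support; each sample's composition is
Dirichlet-distributed around that mean with spread set by a
concentration parameter (larger = samples closer to the group mean);
counts are a multinomial draw at the sample's depth.  The fraction of
ASVs whose support is common to both groups — and hence the expected
community overlap — is an explicit dial with recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from skbio import TreeNode

from gutshift.io import Alignment, AsvTable, SampleMetadata, TaxonomyTable
from gutshift.phylo import TN93Model

_BASES = "ACGT"

#: Contaminant lineages cycled over flagged ASVs.
_CONTAMINANT_LINEAGES = [
    ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
     "Mitochondria"],
    ["Bacteria", "Cyanobacteria", "Oxyphotobacteria", "Chloroplast"],
    ["Eukaryota", "Opisthokonta"],
    ["uncharacterized"],
]

_CLEAN_PHYLA = [
    ["Bacteria", "Firmicutes", "Clostridia", "Lachnospirales",
     "Lachnospiraceae"],
    ["Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales"],
    ["Bacteria", "Proteobacteria", "Gammaproteobacteria"],
    ["Bacteria", "Actinobacteriota", "Actinobacteria"],
    ["Bacteria", "Verrucomicrobiota", "Verrucomicrobiae"],
]


@dataclass
class SyntheticCommunitySpec:
    """Parameters of the two-group community generator.

    Defaults describe the emulated study design: groups of 4 and 10
    mice, ~20k reads per sample with a 1000-read floor, strong
    between-group divergence (20% of ASVs with common support) and 5%
    contaminant ASVs.
    """

    n_asvs: int = 120
    group_sizes: Tuple[int, ...] = (4, 10)
    group_labels: Tuple[str, ...] = ("SD", "WD")
    overlap_fraction: float = 0.2
    concentration: float = 50.0
    depth_mean: int = 20000
    depth_min: int = 1000
    contaminant_fraction: float = 0.05
    identical_group_means: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if len(self.group_sizes) != 2 or len(self.group_labels) != 2:
            raise ValueError("exactly two groups are supported")
        if self.depth_min < 1 or self.depth_mean < self.depth_min:
            raise ValueError("need depth_mean >= depth_min >= 1")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.identical_group_means and self.overlap_fraction != 1.0:
            raise ValueError(
                "identical_group_means requires overlap_fraction = 1"
            )


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery tests."""

    group_means: Dict[str, np.ndarray]
    contaminant_asvs: List[str]
    shared_fraction: float

    def __post_init__(self) -> None:
        for g, v in self.group_means.items():
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"group {g!r} expectation does not sum to 1")


def _support_split(spec: SyntheticCommunitySpec) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean support masks for the two groups over the ASV axis."""
    n = spec.n_asvs
    n_shared = round(spec.overlap_fraction * n)
    if spec.overlap_fraction > 0 and n_shared == 0:
        raise ValueError(
            f"overlap_fraction {spec.overlap_fraction} rounds to zero shared "
            f"ASVs at n_asvs={n}"
        )
    if spec.overlap_fraction < 1:
        n_excl = n - n_shared
        n_a = n_excl // 2
        n_b = n_excl - n_a
        if n_a == 0 or n_b == 0:
            raise ValueError(
                f"n_asvs={n} too small to give both groups exclusive ASVs "
                f"at overlap_fraction {spec.overlap_fraction}"
            )
    else:
        n_a = n_b = 0
    mask_a = np.zeros(n, dtype=bool)
    mask_b = np.zeros(n, dtype=bool)
    mask_a[:n_shared] = mask_b[:n_shared] = True
    mask_a[n_shared : n_shared + n_a] = True
    mask_b[n_shared + n_a :] = True
    return mask_a, mask_b


def simulate_community(
    spec: SyntheticCommunitySpec,
) -> Tuple[AsvTable, TaxonomyTable, SampleMetadata, GroundTruth]:
    """Draw a two-group ASV table with taxonomy, metadata and truth.

    Deterministic under a fixed ``spec.seed``: the same spec yields a
    bit-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_asvs
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n)]
    mask_a, mask_b = _support_split(spec)

    def draw_mean(mask: np.ndarray) -> np.ndarray:
        w = np.zeros(n)
        w[mask] = rng.gamma(shape=1.0, scale=1.0, size=int(mask.sum()))
        w[mask] = np.maximum(w[mask], 1e-12)
        return w / w.sum()

    mean_a = draw_mean(mask_a)
    mean_b = mean_a.copy() if spec.identical_group_means else draw_mean(mask_b)

    label_a, label_b = spec.group_labels
    metadata: SampleMetadata = {}
    columns: List[np.ndarray] = []
    sample_ids: List[str] = []
    for label, size, mean, mask in (
        (label_a, spec.group_sizes[0], mean_a, mask_a),
        (label_b, spec.group_sizes[1], mean_b, mask_b),
    ):
        alpha = spec.concentration * mean[mask]
        for k in range(size):
            sid = f"{label}{k + 1}"
            sample_ids.append(sid)
            metadata[sid] = label
            comp = np.zeros(n)
            comp[mask] = rng.dirichlet(alpha)
            depth = spec.depth_min + rng.poisson(spec.depth_mean - spec.depth_min)
            columns.append(rng.multinomial(depth, comp))
    counts = np.column_stack(columns)

    n_contam = round(spec.contaminant_fraction * n)
    contam_idx = (
        np.linspace(0, n - 1, n_contam).round().astype(int) if n_contam else
        np.array([], dtype=int)
    )
    contam_set = set(contam_idx.tolist())
    taxonomy: TaxonomyTable = {}
    for i, asv_id in enumerate(asv_ids):
        if i in contam_set:
            lineage = _CONTAMINANT_LINEAGES[i % len(_CONTAMINANT_LINEAGES)]
        else:
            lineage = _CLEAN_PHYLA[i % len(_CLEAN_PHYLA)] + [f"Genus{i + 1}"]
        taxonomy[asv_id] = list(lineage)

    truth = GroundTruth(
        group_means={label_a: mean_a, label_b: mean_b},
        contaminant_asvs=[asv_ids[i] for i in sorted(contam_set)],
        shared_fraction=float(np.minimum(mean_a, mean_b).sum()),
    )
    return AsvTable(asv_ids, sample_ids, counts), taxonomy, metadata, truth


def simulate_alignment(
    tree: TreeNode,
    length: int,
    model: Optional[TN93Model] = None,
    seed: int = 0,
) -> Alignment:
    """Evolve site-independent sequences along a tree under TN93.

    Branch lengths are expected substitutions per site; the root state
    of each site is drawn from the model's stationary frequencies.
    Tips must carry unique names.  Deterministic under a fixed seed.
    """
    if length <= 0:
        raise ValueError("alignment length must be positive")
    if model is None:
        model = TN93Model.jukes_cantor()
    rng = np.random.default_rng(seed)
    states: Dict[int, np.ndarray] = {}
    root_state = rng.choice(4, size=length, p=model.freqs)
    states[id(tree)] = root_state
    records: List[Tuple[str, np.ndarray]] = []
    for node in tree.preorder(include_self=True):
        if node.is_root():
            node_state = root_state
        else:
            parent_state = states[id(node.parent)]
            t = node.length or 0.0
            if t == 0.0:
                node_state = parent_state.copy()
            else:
                p = model.transition_matrix(t)
                node_state = np.empty(length, dtype=np.int64)
                for s in range(4):
                    where = parent_state == s
                    k = int(where.sum())
                    if k:
                        node_state[where] = rng.choice(4, size=k, p=p[s])
            states[id(node)] = node_state
        if node.is_tip():
            if node.name is None:
                raise ValueError("every tip must be named")
            records.append((str(node.name), node_state))
    base_arr = np.array(list(_BASES))
    return Alignment(
        [name for name, _ in records],
        ["".join(base_arr[s]) for _, s in records],
    )


def make_toy_fixture() -> Tuple[AsvTable, TaxonomyTable, SampleMetadata]:
    """A hand-specified 6-ASV x 6-sample table for desk-checking.

    Design (counts; sample depths in brackets):

    ========  ====  ====  ====  ====  ====  ====
    ASV       S1    S2    W1    W2    W3    L1
    ========  ====  ====  ====  ====  ====  ====
    ASV1      500   300   100   100   200   100
    ASV2      500   700     0     0     0     0
    ASV3        0     0   850   800   700     0
    ASV4        0     0    50   100   100     0
    ASV5        0     0     0     0     0   500
    ASV6        0     0     0     0     0   399
    depth     1000  1000  1000  1000  1000  999
    ========  ====  ====  ====  ====  ====  ====

    Groups: S1, S2, L1 -> SD; W1, W2, W3 -> WD.  ASV6 is mitochondrial.
    The full filter chain removes L1 (999 < 1000 reads), ASV6
    (taxonomy) and ASV5 (observed in a single, already-removed sample).
    The resulting SD profile is (0.4, 0.6, 0, 0) and the WD profile
    (2/15, 0, 47/60, 1/12), giving the exact partition

    * shared = 100 * 2/15 = 13.3333...%
    * SD: unique 60%, increased 100 * 4/15 = 26.6666...%
    * WD: unique 100 * 13/15 = 86.6666...%, increased 0%.
    """
    counts = np.array(
        [
            [500, 300, 100, 100, 200, 100],
            [500, 700, 0, 0, 0, 0],
            [0, 0, 850, 800, 700, 0],
            [0, 0, 50, 100, 100, 0],
            [0, 0, 0, 0, 0, 500],
            [0, 0, 0, 0, 0, 399],
        ]
    )
    asv_ids = [f"ASV{i}" for i in range(1, 7)]
    sample_ids = ["S1", "S2", "W1", "W2", "W3", "L1"]
    table = AsvTable(asv_ids, sample_ids, counts)
    taxonomy: TaxonomyTable = {
        "ASV1": ["Bacteria", "Firmicutes", "Clostridia", "Lachnospirales"],
        "ASV2": ["Bacteria", "Bacteroidota", "Bacteroidia"],
        "ASV3": ["Bacteria", "Firmicutes", "Bacilli"],
        "ASV4": ["Bacteria", "Proteobacteria"],
        "ASV5": ["Bacteria", "Verrucomicrobiota"],
        "ASV6": ["Bacteria", "Proteobacteria", "Alphaproteobacteria",
                 "Rickettsiales", "Mitochondria"],
    }
    metadata: SampleMetadata = {
        "S1": "SD", "S2": "SD", "L1": "SD",
        "W1": "WD", "W2": "WD", "W3": "WD",
    }
    return table, taxonomy, metadata
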