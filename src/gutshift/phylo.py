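"""Distance-based phylogenetics: TN93 composite-likelihood distances and NJ.

The chain mirrors the classic MEGA-style workflow for 16S trees:

1. **complete deletion** — every alignment column holding a gap or an
   ambiguous/missing state in any sequence is dropped;
2. **composite-likelihood TN93 distances** — the Tamura–Nei model's
   shared parameters (base frequencies and the two
   transition/transversion rate ratios) are estimated once by
   maximizing the *sum* of pairwise log-likelihoods over all sequence
   pairs; each pairwise distance is then the maximizer of that pair's
   log-likelihood under the common parameters, in expected
   substitutions per site;
3. **neighbor joining** (Saitou & Nei) with the standard Q criterion,
   deterministic tie-breaking, and branch lengths retained as produced
   (negative lengths are kept and flagged, not clamped, unless asked);
4. total branch length and Newick serialization.

Trees are :class:`skbio.TreeNode` objects (the unrooted topology is
represented with a trifurcating root, as usual for NJ output); distance
matrices are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from skbio import DistanceMatrix, TreeNode

from gutshift.io import NON_ACGT, Alignment

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
#: Upper bound (substitutions/site) beyond which a pair is called saturated.
MAX_DISTANCE = 10.0


class SaturationError(ValueError):
    """A pairwise distance is undefined (sequences too diverged)."""


@dataclass
class TN93Model:
    """Tamura–Nei (1993) nucleotide substitution model.

    Parameters
    ----------
    freqs:
        Stationary base frequencies in A, C, G, T order; must sum to 1.
    kappa1:
        Purine transition / transversion rate ratio (A<->G vs. beta).
    kappa2:
        Pyrimidine transition / transversion rate ratio (C<->T vs. beta).

    The rate matrix is normalized so branch lengths are expected
    substitutions per site.  ``kappa1 == kappa2`` gives HKY; adding
    equal frequencies gives K2P, and ``kappa == 1`` on top of that is
    Jukes–Cantor.
    """

    freqs: np.ndarray
    kappa1: float = 1.0
    kappa2: float = 1.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or abs(self.freqs.sum() - 1) > 1e-8:
            raise ValueError("freqs must be 4 probabilities summing to 1")
        if (self.freqs <= 0).any():
            raise ValueError("freqs must be strictly positive")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("rate ratios must be positive")

    @classmethod
    def jukes_cantor(cls) -> "TN93Model":
        return cls(np.full(4, 0.25), 1.0, 1.0)

    @property
    def pi_r(self) -> float:
        return float(self.freqs[0] + self.freqs[2])  # A + G

    @property
    def pi_y(self) -> float:
        return float(self.freqs[1] + self.freqs[3])  # C + T

    def _rates(self) -> Tuple[float, float, float]:
        """(alpha1, alpha2, beta), normalized to one substitution/site/unit."""
        pa, pc, pg, pt = self.freqs
        beta = 1.0 / (
            2 * pa * pg * self.kappa1
            + 2 * pc * pt * self.kappa2
            + 2 * self.pi_r * self.pi_y
        )
        return self.kappa1 * beta, self.kappa2 * beta, beta

    def rate_matrix(self) -> np.ndarray:
        """The normalized 4x4 generator (rows sum to zero)."""
        a1, a2, beta = self._rates()
        q = np.empty((4, 4))
        purine = np.array([True, False, True, False])
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                if purine[i] and purine[j]:
                    rate = a1
                elif not purine[i] and not purine[j]:
                    rate = a2
                else:
                    rate = beta
                q[i, j] = rate * self.freqs[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t): closed-form TN93 transition probabilities.

        Same-class entries decay with the class-specific rate, cross
        class entries with the transversion rate; checked elsewhere
        against the matrix exponential of :meth:`rate_matrix`.
        """
        if t < 0:
            raise ValueError("time must be non-negative")
        a1, a2, beta = self._rates()
        pr, py = self.pi_r, self.pi_y
        e_b = np.exp(-beta * t)
        e_r = np.exp(-(pr * a1 + py * beta) * t)
        e_y = np.exp(-(py * a2 + pr * beta) * t)
        purine = (True, False, True, False)
        p = np.empty((4, 4))
        for i in range(4):
            cls_i = purine[i]
            pi_cls = pr if cls_i else py
            e_cls = e_r if cls_i else e_y
            for j in range(4):
                pj = self.freqs[j]
                if purine[j] != cls_i:
                    p[i, j] = pj * (1 - e_b)
                elif i == j:
                    p[i, j] = (
                        pj
                        + pj * (1 - pi_cls) / pi_cls * e_b
                        + (pi_cls - pj) / pi_cls * e_cls
                    )
                else:
                    p[i, j] = (
                        pj
                        + pj * (1 - pi_cls) / pi_cls * e_b
                        - pj / pi_cls * e_cls
                    )
        return p


def complete_deletion(alignment: Alignment) -> Tuple[Alignment, int]:
    """Drop every column containing a gap, N or ambiguity code anywhere.

    Returns the reduced alignment and the number of retained positions;
    column order is otherwise preserved.  Raises if nothing survives.
    """
    mat = alignment.to_matrix()
    bad = np.isin(mat, list(NON_ACGT)).any(axis=0)
    keep = ~bad
    if not keep.any():
        raise ValueError("complete deletion removed every column")
    reduced = ["".join(row) for row in mat[:, keep]]
    return Alignment(list(alignment.seq_ids), reduced), int(keep.sum())


def _pair_pattern_counts(alignment: Alignment) -> np.ndarray:
    """4x4 site-pattern count matrices for every sequence pair.

    Returns an array of shape (n, n, 4, 4) with ``counts[i, j, x, y]``
    = number of columns where sequence i holds base x and j holds y.
    """
    mat = alignment.to_matrix()
    idx = np.empty(mat.shape, dtype=np.int8)
    for b, k in _BASE_INDEX.items():
        idx[mat == b] = k
    n = alignment.n_seqs
    counts = np.zeros((n, n, 4, 4), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            pair = idx[i] * 4 + idx[j]
            c = np.bincount(pair, minlength=16).reshape(4, 4)
            counts[i, j] = c
            counts[j, i] = c.T
    return counts

def _pair_neg_loglik(d: float, counts: np.ndarray, model: TN93Model) -> float:
    p = model.transition_matrix(d)
    joint = model.freqs[:, None] * p
    mask = counts > 0
    if (joint[mask] <= 0).any():
        return np.inf
    return -float((counts[mask] * np.log(joint[mask])).sum())


def _fit_pair_distance(counts: np.ndarray, model: TN93Model) -> float:
    res = minimize_scalar(
        _pair_neg_loglik,
        bounds=(0.0, MAX_DISTANCE),
        args=(counts, model),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def composite_likelihood_distances(
    alignment: Alignment, return_model: bool = False
):
    """Pairwise TN93 distances with parameters shared across all pairs.

    Base frequencies are the average empirical composition of the
    sequences.  The two transition/transversion rate ratios are chosen
    to maximize the composite likelihood — the sum over all pairs of
    the pairwise log-likelihood, each pair profiled over its own
    distance.  Distances are then the per-pair maximizers under the
    common parameters.

    Raises :class:`SaturationError`, naming the pair, when a distance
    runs into the saturation bound.
    """
    if alignment.n_seqs < 2:
        raise ValueError("need at least two sequences")
    residues = set("".join(alignment.sequences))
    if not residues <= set(_BASES):
        raise ValueError(
            f"alignment contains non-ACGT characters {residues - set(_BASES)}; "
            "run complete_deletion first"
        )
    mat = alignment.to_matrix()
    freqs = np.array(
        [np.mean([np.mean(row == b) for row in mat]) for b in _BASES]
    )
    freqs = np.clip(freqs, 1e-9, None)
    freqs = freqs / freqs.sum()
    counts = _pair_pattern_counts(alignment)
    n = alignment.n_seqs
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def neg_composite(log_kappas: np.ndarray) -> float:
        model = TN93Model(freqs, float(np.exp(log_kappas[0])),
                          float(np.exp(log_kappas[1])))
        total = 0.0
        for i, j in pairs:
            d = _fit_pair_distance(counts[i, j], model)
            total += _pair_neg_loglik(d, counts[i, j], model)
        return total

    res = minimize(
        neg_composite,
        x0=np.log([2.0, 2.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
    )
    model = TN93Model(freqs, float(np.exp(res.x[0])), float(np.exp(res.x[1])))
    dmat = np.zeros((n, n))
    for i, j in pairs:
        d = _fit_pair_distance(counts[i, j], model)
        if d > MAX_DISTANCE - 1e-3:
            raise SaturationError(
                f"distance between {alignment.seq_ids[i]!r} and "
                f"{alignment.seq_ids[j]!r} is saturated"
            )
        dmat[i, j] = dmat[j, i] = d
    dm = DistanceMatrix(dmat, ids=list(alignment.seq_ids))
    return (dm, model) if return_model else dm


def neighbor_joining(
    dm: DistanceMatrix, clamp_negative: bool = False
) -> TreeNode:
    """Classical Saitou–Nei neighbor joining.

    Deterministic: the pair minimizing the Q criterion is chosen, ties
    broken by the lowest pair of current indices.  Negative branch
    lengths are retained (a warning is emitted) unless
    ``clamp_negative`` is set, which floors them at zero.
    """
    if isinstance(dm, DistanceMatrix):
        ids = list(dm.ids)
        d = np.array(dm.data, dtype=float)
    else:
        raise TypeError("dm must be a skbio DistanceMatrix")
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=name) for name in ids]
    active = list(range(n))
    saw_negative = False

    def set_length(node: TreeNode, length: float) -> None:
        nonlocal saw_negative
        if length < 0:
            saw_negative = True
            if clamp_negative:
                length = 0.0
        node.length = float(length)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        iu = np.triu_indices(r, k=1)
        flat = q[iu]
        best = int(np.argmin(flat))  # first minimum: lexicographic (i, j)
        ai, aj = iu[0][best], iu[1][best]
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        parent = TreeNode()
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to all remaining active nodes
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes at a trifurcating root
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for k, lk in zip((a, b, c), (la, lb, lc)):
        set_length(nodes[k], lk)
    root.extend([nodes[a], nodes[b], nodes[c]])
    if saw_negative and not clamp_negative:
        warnings.warn("neighbor joining produced negative branch lengths")
    return root


def total_branch_length(tree: TreeNode) -> float:
    """Arithmetic sum of all branch lengths in the tree."""
    return float(
        sum(node.length or 0.0 for node in tree.traverse(include_self=False))
    )


def build_tree(alignment: Alignment) -> dict:
    """Run the full chain on an aligned FASTA: deletion -> distances -> NJ.

    Returns a report dict with the tree, the Newick string, the number
    of sequences, retained positions, and the total branch length.
    """
    reduced, n_positions = complete_deletion(alignment)
    dm, model = composite_likelihood_distances(reduced, return_model=True)
    tree = neighbor_joining(dm)
    return {
        "tree": tree,
        "newick": str(tree),
        "n_sequences": alignment.n_seqs,
        "n_positions": n_positions,
        "sum_branch_length": total_branch_length(tree),
        "model": model,
    }
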