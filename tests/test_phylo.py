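import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import minimize
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from gutshift.io import Alignment
from gutshift.phylo import (
    MAX_DISTANCE,
    SaturationError,
    TN93Model,
    complete_deletion,
    composite_likelihood_distances,
    neighbor_joining,
    total_branch_length,
)
from gutshift.simulate import simulate_alignment

from conftest import random_unrooted_tree


def jc_pair(p, n=1200):
    """Two sequences with proportion ``p`` of differences spread evenly
    over all substitution types and a uniform base composition."""
    n_mis = int(round(p * n / 12)) * 12
    n_match = n - n_mis
    assert n_match % 4 == 0
    s1, s2 = [], []
    for b in "ACGT":
        s1 += [b] * (n_match // 4)
        s2 += [b] * (n_match // 4)
    for x, y in itertools.permutations("ACGT", 2):
        s1 += [x] * (n_mis // 12)
        s2 += [y] * (n_mis // 12)
    return Alignment(["a", "b"], ["".join(s1), "".join(s2)])


class TestTN93Model:
    @pytest.mark.parametrize("t", [0.0, 0.01, 0.3, 2.0])
    def test_closed_form_matches_matrix_exponential(self, t):
        model = TN93Model(np.array([0.3, 0.2, 0.3, 0.2]), 2.5, 4.0)
        p_closed = model.transition_matrix(t)
        p_expm = expm(model.rate_matrix() * t)
        assert np.allclose(p_closed, p_expm, atol=1e-12)
        assert np.allclose(p_closed.sum(axis=1), 1.0)

    def test_rate_matrix_normalized_to_one_substitution(self):
        model = TN93Model(np.array([0.1, 0.4, 0.2, 0.3]), 3.0, 0.5)
        q = model.rate_matrix()
        mean_rate = -(model.freqs * np.diag(q)).sum()
        assert mean_rate == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TN93Model(np.array([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ValueError):
            TN93Model(np.full(4, 0.25), kappa1=-1.0)


class TestCompleteDeletion:
    def test_gap_free_identity(self):
        aln = Alignment(["a", "b"], ["ACGT", "TGCA"])
        out, n = complete_deletion(aln)
        assert out.sequences == aln.sequences and n == 4

    def test_single_gap_removes_whole_column(self):
        aln = Alignment(["a", "b", "c"], ["ACGT", "A-GT", "ACGT"])
        out, n = complete_deletion(aln)
        assert n == 3
        assert out.sequences == ["AGT", "AGT", "AGT"]

    def test_ambiguity_codes_count_as_missing(self):
        aln = Alignment(["a", "b"], ["ANRT", "ACGT"])
        out, n = complete_deletion(aln)
        assert out.sequences == ["AT", "AT"] and n == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_column_scan(self, seed):
        rng = np.random.default_rng(seed)
        chars = np.array(list("ACGT-N"))
        mat = chars[rng.integers(0, 6, size=(4, 60))]
        seqs = ["".join(row) for row in mat]
        expected_cols = [
            j for j in range(60)
            if all(mat[i, j] in "ACGT" for i in range(4))
        ]
        if not expected_cols:
            with pytest.raises(ValueError):
                complete_deletion(Alignment(list("wxyz"), seqs))
            return
        out, n = complete_deletion(Alignment(list("wxyz"), seqs))
        assert n == len(expected_cols)
        assert out.sequences[0] == "".join(mat[0, expected_cols])

    def test_everything_removed_is_error(self):
        with pytest.raises(ValueError, match="every column"):
            complete_deletion(Alignment(["a", "b"], ["-A", "T-"]))


class TestCompositeLikelihoodDistances:
    def test_identical_sequences_distance_zero(self):
        aln = Alignment(["a", "b"], ["ACGTACGT" * 20] * 2)
        dm = composite_likelihood_distances(aln)
        assert dm["a", "b"] == pytest.approx(0.0, abs=1e-6)

    def test_reduces_to_jukes_cantor_closed_form(self):
        """Equal frequencies and symmetric substitution counts: the
        distance is -(3/4) ln(1 - 4p/3)."""
        for p in (0.05, 0.1, 0.2):
            dm = composite_likelihood_distances(jc_pair(p))
            expected = -0.75 * np.log(1 - 4 * p / 3)
            assert dm["a", "b"] == pytest.approx(expected, abs=1e-5)

    def test_distance_monotone_in_p(self):
        ds = [composite_likelihood_distances(jc_pair(p))["a", "b"]
              for p in (0.05, 0.15, 0.3)]
        assert ds[0] < ds[1] < ds[2]
        # and each exceeds its own p-distance
        for p, d in zip((0.05, 0.15, 0.3), ds):
            assert d > p

    def test_two_sequence_composite_equals_full_ml(self):
        """With a single pair the composite likelihood IS the full
        pairwise likelihood; cross-check against a generic optimizer
        built on the matrix exponential."""
        rng = np.random.default_rng(5)
        tree = TreeNode()
        tree.extend([TreeNode(name="a", length=0.08),
                     TreeNode(name="b", length=0.12)])
        model = TN93Model(np.array([0.35, 0.15, 0.25, 0.25]), 3.0, 5.0)
        aln = simulate_alignment(tree, 5000, model, seed=11)
        dm, fitted = composite_likelihood_distances(aln, return_model=True)

        # independent route: optimize (d, k1, k2) numerically with expm
        mat = aln.to_matrix()
        idx = np.searchsorted(list("ACGT"), mat)
        counts = np.zeros((4, 4))
        for x, y in zip(idx[0], idx[1]):
            counts[x, y] += 1
        freqs = counts.sum(axis=1) + counts.sum(axis=0)
        freqs = freqs / freqs.sum()

        def nll(theta):
            d, k1, k2 = np.exp(theta)
            m = TN93Model(freqs, k1, k2)
            p = expm(m.rate_matrix() * d)
            joint = freqs[:, None] * p
            return -(counts * np.log(np.maximum(joint, 1e-300))).sum()

        res = minimize(nll, np.log([0.2, 2.0, 2.0]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        d_oracle = float(np.exp(res.x[0]))
        assert dm["a", "b"] == pytest.approx(d_oracle, abs=2e-4)

    def test_non_acgt_input_rejected(self):
        with pytest.raises(ValueError, match="complete_deletion"):
            composite_likelihood_distances(Alignment(["a", "b"], ["A-GT", "ACGT"]))

    def test_saturated_pair_is_named_error(self):
        # 96% observed differences exceeds the 75% saturation plateau
        aln = jc_pair(0.96)
        with pytest.raises(SaturationError, match="'a'"):
            composite_likelihood_distances(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]),
            ids=["a", "b", "c"],
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(1)
        true = random_unrooted_tree(5, rng)
        tt = true.tip_tip_distances()
        dm = DistanceMatrix(tt.data, ids=[str(i) for i in tt.ids])
        tree = neighbor_joining(dm)
        back = tree.tip_tip_distances().filter([str(i) for i in tt.ids])
        assert np.abs(back.data - tt.data).max() < 1e-10
        assert true.compare_rfd(tree) == 0

    def test_taxon_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        true = random_unrooted_tree(7, rng)
        tt = true.tip_tip_distances()
        ids = [str(i) for i in tt.ids]
        perm = rng.permutation(len(ids))
        dm1 = DistanceMatrix(tt.data, ids=ids)
        dm2 = DistanceMatrix(tt.data[np.ix_(perm, perm)],
                             ids=[ids[i] for i in perm])
        t1 = neighbor_joining(dm1)
        t2 = neighbor_joining(dm2)
        assert t1.compare_rfd(t2) == 0

    def test_agrees_with_reference_nj_on_noisy_matrix(self):
        """On a generic (non-additive) matrix the topology matches the
        scikit-bio reference implementation."""
        rng = np.random.default_rng(3)
        true = random_unrooted_tree(8, rng)
        tt = true.tip_tip_distances()
        noisy = tt.data + rng.uniform(0, 0.02, tt.data.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm = DistanceMatrix(noisy, ids=[str(i) for i in tt.ids])
        ours = neighbor_joining(dm)
        reference = skbio_nj(dm)
        assert ours.compare_rfd(reference) == 0

    def test_negative_branch_lengths_warned_not_clamped(self):
        # a sits far from c/d while b sits close to them: joining (a, b)
        # forces b's branch below zero
        d = np.array([
            [0.0, 0.01, 1.0, 1.0],
            [0.01, 0.0, 0.1, 0.1],
            [1.0, 0.1, 0.0, 0.3],
            [1.0, 0.1, 0.3, 0.0],
        ])
        dm = DistanceMatrix(d, ids=list("abcd"))
        with pytest.warns(UserWarning, match="negative"):
            tree = neighbor_joining(dm)
        assert any((t.length or 0) < 0 for t in tree.traverse())
        clamped = neighbor_joining(dm, clamp_negative=True)
        assert all((t.length or 0) >= 0 for t in clamped.traverse())

    def test_fewer_than_three_taxa_is_error(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)

    @pytest.mark.parametrize("seed", range(10))
    def test_consistency_on_random_trees(self, seed):
        """NJ is exact on tree-additive matrices (n up to 12)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        true = random_unrooted_tree(n, rng)
        tt = true.tip_tip_distances()
        tree = neighbor_joining(DistanceMatrix(tt.data,
                                               ids=[str(i) for i in tt.ids]))
        assert true.compare_rfd(tree) == 0
        back = tree.tip_tip_distances().filter([str(i) for i in tt.ids])
        assert np.abs(back.data - tt.data).max() < 1e-10


class TestTreeSummaries:
    def test_total_branch_length(self):
        tree = TreeNode.read(["(a:0.1,b:0.2,c:0.3);"])
        assert total_branch_length(tree) == pytest.approx(0.6)
        zero = TreeNode.read(["(a:0.0,b:0.0,c:0.0);"])
        assert total_branch_length(zero) == 0.0

    def test_nj_total_length_matches_generating_tree(self):
        rng = np.random.default_rng(4)
        true = random_unrooted_tree(9, rng)
        true_total = sum(n.length for n in true.traverse(include_self=False))
        tt = true.tip_tip_distances()
        tree = neighbor_joining(DistanceMatrix(tt.data,
                                               ids=[str(i) for i in tt.ids]))
        assert total_branch_length(tree) == pytest.approx(true_total, abs=1e-10)

    def test_newick_round_trip(self):
        rng = np.random.default_rng(6)
        tree = neighbor_joining_from_random(rng)
        newick = str(tree)
        back = TreeNode.read([newick])
        assert back.compare_rfd(tree) == 0
        d1 = tree.tip_tip_distances()
        d2 = back.tip_tip_distances().filter([str(i) for i in d1.ids])
        assert np.abs(d1.data - d2.data).max() < 1e-9


def neighbor_joining_from_random(rng, n=6):
    true = random_unrooted_tree(n, rng)
    tt = true.tip_tip_distances()
    return neighbor_joining(DistanceMatrix(tt.data,
                                           ids=[str(i) for i in tt.ids]))
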