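"""Substitution costs, Markov imputation, and optimal-matching distances."""

import itertools

import numpy as np
import pytest

from trajmorbid.dissimilarity import (CostModel, TransitionModel, cost_matrix,
                                      estimate_transitions, impute_tail,
                                      increment_sensitivity, om_distance,
                                      pairwise_matrix, position_cost,
                                      substitution_cost)
from trajmorbid.sequences import StateSequence, build_alphabet, build_sequences


@pytest.fixture(scope="module")
def cm():
    return CostModel()


def enc(alphabet, *labels):
    return alphabet.encode(labels)


class TestSubstitutionCost:
    @pytest.mark.parametrize("a, b, expected", [
        (("F1",), ("F3",), 1.0),
        (("F1", "F3"), ("F3", "F4"), 0.5),
        (("F1", "F3"), ("F4", "F50"), 1.0),
        (("F1", "F3"), ("F1", "F3"), 0.0),
        ((), (), 0.0),
        (("F1",), ("F1", "F3"), 1 / 3),  # Dice: 1 - 2*1/(1+2)
    ])
    def test_overlap_scheme(self, alphabet, cm, a, b, expected):
        assert substitution_cost(enc(alphabet, *a), enc(alphabet, *b), cm,
                                 alphabet) == pytest.approx(expected)

    def test_jaccard_scheme_differs_on_partial_overlap(self, alphabet):
        jac = CostModel("jaccard")
        c = substitution_cost(enc(alphabet, "F1", "F3"),
                              enc(alphabet, "F3", "F4"), jac, alphabet)
        assert c == pytest.approx(2 / 3)

    def test_constant_scheme(self, alphabet):
        const = CostModel("constant")
        assert substitution_cost(1, 2, const, alphabet) == 1.0
        assert substitution_cost(7, 7, const, alphabet) == 0.0

    def test_state_outside_alphabet(self, alphabet, cm):
        with pytest.raises(KeyError):
            substitution_cost(0, 256, cm, alphabet)

    @pytest.mark.parametrize("scheme", ["paper_overlap", "jaccard", "constant"])
    def test_cost_matrix_properties(self, alphabet2, scheme):
        C = cost_matrix(alphabet2, CostModel(scheme))
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 0)
        assert C.min() >= 0 and C.max() <= 1

    def test_cost_matrix_matches_scalar(self, alphabet, cm):
        C = cost_matrix(alphabet, cm)
        rng = np.random.default_rng(0)
        for a, b in rng.integers(0, 256, size=(50, 2)):
            assert C[a, b] == pytest.approx(
                substitution_cost(int(a), int(b), cm, alphabet))


class TestTransitions:
    def test_direct_count(self, alphabet):
        f1 = enc(alphabet, "F1")
        s1 = StateSequence("a", np.array([0, 0, f1]), target_length=3)
        s2 = StateSequence("b", np.array([0, 0, 0]), target_length=3)
        tm = estimate_transitions([s1, s2], alphabet)
        assert tm.matrix[0, 0] == pytest.approx(3 / 4)
        assert tm.matrix[0, f1] == pytest.approx(1 / 4)
        assert tm.estimated_from == 4

    def test_constant_sequences_give_identity_rows(self, alphabet):
        seqs = [StateSequence("a", np.zeros(5, dtype=int), target_length=5)]
        tm = estimate_transitions(seqs, alphabet)
        assert np.array_equal(tm.matrix, np.eye(alphabet.n_states))

    def test_rows_normalized(self, alphabet, small_cases):
        seqs = build_sequences(small_cases[:60], alphabet)
        tm = estimate_transitions(seqs, alphabet)
        assert np.allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_no_transitions_error(self, alphabet):
        seqs = [StateSequence("a", np.zeros(1, dtype=int), target_length=5)]
        with pytest.raises(ValueError, match="no observed transitions"):
            estimate_transitions(seqs, alphabet)


class TestImputedTail:
    def test_identity_model_point_mass(self, alphabet):
        tm = TransitionModel(np.eye(alphabet.n_states), 1, alphabet)
        f1 = enc(alphabet, "F1")
        seq = StateSequence("a", np.array([0, f1]), target_length=6)
        tail = impute_tail(seq, tm)
        assert tail.probs.shape == (4, alphabet.n_states)
        assert np.all(tail.probs[:, f1] == 1.0)

    def test_fully_observed_empty_tail(self, alphabet):
        tm = TransitionModel(np.eye(alphabet.n_states), 1, alphabet)
        seq = StateSequence("a", np.zeros(6, dtype=int), target_length=6)
        assert impute_tail(seq, tm).probs.shape[0] == 0

    def test_two_step_chain(self, alphabet):
        f1 = enc(alphabet, "F1")
        M = np.eye(alphabet.n_states)
        M[0, 0], M[0, f1] = 0.9, 0.1
        tm = TransitionModel(M, 1, alphabet)
        seq = StateSequence("a", np.array([0]), target_length=3)
        tail = impute_tail(seq, tm)
        assert tail.probs[1, 0] == pytest.approx(0.81)
        assert tail.probs[1, f1] == pytest.approx(0.19)


class TestPositionCost:
    def test_point_mass_reduces_to_substitution(self, alphabet, cm):
        f1, f3 = enc(alphabet, "F1"), enc(alphabet, "F3")
        p = np.zeros(alphabet.n_states)
        p[f1] = 1.0
        assert position_cost(p, f3, cm, alphabet) == pytest.approx(
            substitution_cost(f1, f3, cm, alphabet))

    def test_weighted_mean(self, alphabet, cm):
        f1, f3 = enc(alphabet, "F1"), enc(alphabet, "F3")
        p = np.zeros(alphabet.n_states)
        p[f1] = p[f3] = 0.5
        assert position_cost(p, f1, cm, alphabet) == pytest.approx(0.5)

    def test_identical_distributions_nonzero(self, alphabet, cm):
        # expected cost of two i.i.d. draws is not 0
        f1, f3 = enc(alphabet, "F1"), enc(alphabet, "F3")
        p = np.zeros(alphabet.n_states)
        p[f1] = p[f3] = 0.5
        assert position_cost(p, p, cm, alphabet) == pytest.approx(0.5)

    def test_unnormalized_rejected(self, alphabet, cm):
        p = np.zeros(alphabet.n_states)
        p[0] = 0.5
        with pytest.raises(ValueError, match="not normalized"):
            position_cost(p, 0, cm, alphabet)


def _brute_force_om(x, y, C, indel):
    """Independent oracle: exhaustive recursion over all edit scripts."""
    if not len(x):
        return len(y) * indel
    if not len(y):
        return len(x) * indel
    return min(_brute_force_om(x[1:], y[1:], C, indel) + C[x[0], y[0]],
               _brute_force_om(x[1:], y, C, indel) + indel,
               _brute_force_om(x, y[1:], C, indel) + indel)


def _monotone_sequences(length, n_states):
    return [s for s in itertools.product(range(n_states), repeat=length)
            if all(s[i] & ~s[i + 1] == 0 for i in range(length - 1))]


class TestOMDistance:
    def test_identical_sequences_zero(self, alphabet, cm):
        s = StateSequence("a", np.array([0, 1, 3]), target_length=3)
        t = StateSequence("b", np.array([0, 1, 3]), target_length=3)
        assert om_distance(s, t, None, None, cm, alphabet) == 0.0

    def test_single_substitution_beats_two_indels(self, alphabet, cm):
        f1, f3 = enc(alphabet, "F1"), enc(alphabet, "F3")
        s = StateSequence("a", np.array([0, f1]), target_length=2)
        t = StateSequence("b", np.array([0, f3]), target_length=2)
        assert om_distance(s, t, None, None, cm, alphabet) == pytest.approx(1.0)

    @pytest.mark.parametrize("length", [2, 3])
    def test_matches_exhaustive_oracle(self, alphabet2, cm, length):
        C = cost_matrix(alphabet2, cm)
        seqs = _monotone_sequences(length, alphabet2.n_states)
        for x in seqs:
            for y in seqs:
                sx = StateSequence("x", np.array(x), target_length=length)
                sy = StateSequence("y", np.array(y), target_length=length)
                got = om_distance(sx, sy, None, None, cm, alphabet2)
                want = _brute_force_om(list(x), list(y), C, cm.indel_cost)
                assert got == pytest.approx(want, abs=1e-12)

    def test_length_mismatch_rejected(self, alphabet, cm):
        s = StateSequence("a", np.array([0, 0]), target_length=2)
        t = StateSequence("b", np.array([0]), target_length=3)
        with pytest.raises(ValueError):
            om_distance(s, t, None, None, cm, alphabet)

    def test_length_independence_with_deterministic_chain(self, alphabet, cm):
        # identical observed prefixes, different censoring: distance -> 0
        # when the transition model is deterministic (identity)
        tmod = TransitionModel(np.eye(alphabet.n_states), 1, alphabet)
        f1 = enc(alphabet, "F1")
        long = StateSequence("a", np.array([0, f1, f1, f1]), target_length=4)
        short = StateSequence("b", np.array([0, f1]), target_length=4)
        tail = impute_tail(short, tmod)
        assert om_distance(long, short, None, tail, cm,
                           alphabet) == pytest.approx(0.0)


@pytest.fixture(scope="module")
def matrix(alphabet, small_cases):
    seqs = build_sequences(small_cases[:80], alphabet)
    tmod = estimate_transitions(seqs, alphabet)
    return pairwise_matrix(seqs, CostModel(), tmod)


class TestPairwiseMatrix:
    def test_symmetry_and_zero_diagonal(self, matrix):
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.all(np.diag(matrix.values) == 0)
        assert np.all(matrix.values >= 0)

    def test_triangle_inequality_exact_under_jaccard_scheme(self, alphabet,
                                                            small_cases):
        # edit distances over a metric substitution cost compose; the
        # set-theoretic Jaccard cost is a metric (the default Dice cost of
        # the worked examples is not)
        from trajmorbid.sequences import build_sequences

        seqs = build_sequences(small_cases[:60], alphabet)
        tmod = estimate_transitions(seqs, alphabet)
        D = pairwise_matrix(seqs, CostModel("jaccard"), tmod).values
        rng = np.random.default_rng(0)
        for _ in range(500):
            i, j, k = rng.choice(len(seqs), 3, replace=False)
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_triangle_violations_under_dice_are_rare_and_bounded(
            self, matrix):
        # the Dice substitution cost is non-metric and the censored-tail
        # cost is an expectation over independent draws, so the default
        # matrix is only approximately metric; violations should remain a
        # small fraction of sampled triples
        rng = np.random.default_rng(0)
        n, D = matrix.n, matrix.values
        viol = 0
        for _ in range(1000):
            i, j, k = rng.choice(n, 3, replace=False)
            viol += D[i, j] > D[i, k] + D[k, j] + 1e-9
        assert viol <= 20  # <= 2% of sampled triples

    def test_identical_sequences_all_zero(self, alphabet):
        seqs = [StateSequence(f"p{i}", np.array([0, 1, 1]), target_length=3)
                for i in range(4)]
        tmod = TransitionModel(np.eye(alphabet.n_states), 1, alphabet)
        D = pairwise_matrix(seqs, CostModel(), tmod)
        assert np.all(D.values == 0)

    def test_permutation_consistency(self, alphabet, small_cases):
        seqs = build_sequences(small_cases[:12], alphabet)
        tmod = estimate_transitions(seqs, alphabet)
        D = pairwise_matrix(seqs, CostModel(), tmod).values
        perm = np.arange(len(seqs))[::-1]
        D2 = pairwise_matrix([seqs[i] for i in perm], CostModel(), tmod).values
        assert np.allclose(D2, D[np.ix_(perm, perm)])

    def test_matrix_io_roundtrip(self, matrix, tmp_path):
        from trajmorbid.dissimilarity import DissimilarityMatrix

        p = tmp_path / "D.tsv"
        matrix.write(p)
        back = DissimilarityMatrix.read(p)
        assert back.ids == matrix.ids
        assert np.allclose(back.values, matrix.values, atol=1e-8)


class TestIncrementSensitivity:
    def test_same_increment_r_one(self, alphabet, small_cases):
        r = increment_sensitivity(small_cases[:40], [1.0], alphabet,
                                  CostModel())
        assert r[1.0] == pytest.approx(1.0)

    def test_six_month_grid_highly_correlated(self, alphabet, small_cases):
        r = increment_sensitivity(small_cases[:60], [0.5], alphabet,
                                  CostModel())
        assert r[0.5] >= 0.95

    def test_empty_increments_error(self, alphabet, small_cases):
        with pytest.raises(ValueError, match="no increments"):
            increment_sensitivity(small_cases[:10], [], alphabet, CostModel())
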