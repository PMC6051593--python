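"""Markov stimulus models, sequence generation and KL-based selection."""

import numpy as np
import pytest
from scipy import stats

import statseq as sq
from statseq.markov import _as_items


def brute_force_kl(sequence, model, epsilon=1e-6):
    """Independent term-by-term summation oracle for kl_to_ideal."""
    seq = list(_as_items(sequence))
    k = model.order
    counts = {}
    for i in range(k, len(seq)):
        ctx = tuple(seq[i - k:i])
        counts.setdefault(ctx, [0.0] * 4)[seq[i]] += 1
    total = 0.0
    for ci, ctx in enumerate(model.contexts):
        w = model.context_weights[ci]
        row = counts.get(ctx)
        if row is None:
            p = [0.25] * 4
        else:
            s = sum(row)
            p = [(r / s + epsilon) / (1 + 4 * epsilon) for r in row]
        for t in range(4):
            q = model.row(ctx)[t]
            if q > 0:
                total += w * q * np.log(q / p[t])
    return total


class TestBuildModel:
    def test_level0_row_is_printed_occurrence_distribution(self):
        m = sq.build_model(0)
        assert np.allclose(m.row(()), (0.18, 0.72, 0.05, 0.05))

    def test_level1_context_a_allows_only_b_and_c(self):
        m = sq.build_model(1)
        row = m.row((0,))
        assert row[1] == 0.8
        assert row[2] == pytest.approx(0.2, abs=1e-15)
        assert row[0] == 0 and row[3] == 0

    def test_symmetric_degenerate_high_low(self):
        m = sq.build_model(1, high_p=0.5, low_p=0.5)
        for c in m.contexts:
            assert sorted(m.row(c))[-2:] == [0.5, 0.5]

    def test_permutation_remaps_structural_roles(self):
        perm = (2, 0, 3, 1)
        m = sq.build_model(0, permutation=perm)
        row = m.row(())
        assert row[perm[1]] == 0.72 and row[perm[0]] == 0.18
        m1 = sq.build_model(1, permutation=perm)
        # canonical A -> B(high) becomes perm[0] -> perm[1]
        assert m1.row((perm[0],))[perm[1]] == 0.8

    def test_level2_rows_depend_on_both_context_items(self):
        m = sq.build_model(2)
        assert m.n_contexts == 8
        by_last = {}
        for (a, b) in m.contexts:
            by_last.setdefault(b, []).append(m.row((a, b)))
        for b, rows in by_last.items():
            assert len(rows) == 2
            # same allowed targets, opposite high/low assignment
            assert set(np.flatnonzero(rows[0])) == set(np.flatnonzero(rows[1]))
            assert not np.allclose(rows[0], rows[1])

    @pytest.mark.parametrize("bad", [3, -1, "x"])
    def test_invalid_level_rejected(self, bad):
        with pytest.raises(ValueError):
            sq.build_model(bad)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            sq.build_model(0, level0_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            sq.build_model(1, high_p=0.8, low_p=0.3)

    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_rows_sum_to_one_with_support_two(self, models, level):
        m = models[level]
        for c in m.contexts:
            assert abs(m.row(c).sum() - 1.0) <= 1e-12
            if level >= 1:
                assert np.count_nonzero(m.row(c)) == 2


class TestStationaryDistribution:
    def test_level0_single_empty_context(self, models):
        pi = sq.stationary_context_distribution(models[0])
        assert pi.shape == (1,) and pi[0] == 1.0

    def test_symmetric_level1_is_uniform(self):
        m = sq.build_model(1, high_p=0.5, low_p=0.5)
        assert np.allclose(sq.stationary_context_distribution(m), 0.25)

    @pytest.mark.parametrize("level", [1, 2])
    def test_matches_power_iteration_oracle(self, models, level):
        m = models[level]
        n = m.n_contexts
        T = np.zeros((n, n))
        idx = {c: i for i, c in enumerate(m.contexts)}
        for c in m.contexts:
            for t in range(4):
                p = m.row(c)[t]
                if p > 0:
                    nxt = (c + (t,))[-m.order:]
                    T[idx[c], idx[nxt]] += p
        v = np.full(n, 1.0 / n)
        for _ in range(500):
            v = v @ T
        assert np.allclose(sq.stationary_context_distribution(m), v, atol=1e-12)

    def test_non_ergodic_chain_reports_contexts(self):
        # closed but not strongly connected: A,B never reach C or D
        table = {
            (0,): (0.2, 0.8, 0, 0), (1,): (0.8, 0.2, 0, 0),
            (2,): (0.8, 0.2, 0, 0), (3,): (0.2, 0.8, 0, 0),
        }
        with pytest.raises(ValueError, match="unreachable"):
            sq.MarkovModel(1, table)


class TestGeneration:
    def test_conditional_frequencies_approach_table(self, models, rng):
        m = models[1]
        seq = sq.generate_sequence(m, 100_000, rng)
        emp = sq.empirical_distribution(seq, 1)
        for c in m.contexts:
            assert np.allclose(emp.row(c), m.row(c), atol=0.01)

    def test_level0_length_one(self, models, rng):
        seq = sq.generate_sequence(models[0], 1, rng)
        assert seq.shape == (1,) and 0 <= seq[0] < 4

    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_same_seed_identical(self, models, level):
        a = sq.generate_sequences(models[level], 5, 50, np.random.default_rng(9))
        b = sq.generate_sequences(models[level], 5, 50, np.random.default_rng(9))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("level", [1, 2])
    def test_only_legal_transitions(self, models, rng, level):
        m = models[level]
        for seq in sq.generate_sequences(m, 20, 200, rng):
            for i in range(m.order, len(seq)):
                ctx = tuple(int(x) for x in seq[i - m.order:i])
                assert m.row(ctx)[seq[i]] > 0

    def test_length_too_small_rejected(self, models, rng):
        with pytest.raises(ValueError):
            sq.generate_sequence(models[2], 2, rng)


class TestEmpiricalDistribution:
    def test_alternating_sequence(self):
        tab = sq.empirical_distribution("ABABABAB", 1)
        assert tab.row((0,))[1] == 1.0
        assert tab.row((1,))[0] == 1.0
        assert (2,) not in tab and (3,) not in tab

    def test_constant_sequence_order0(self):
        tab = sq.empirical_distribution("BBBB", 0)
        assert tab.row(())[1] == 1.0

    def test_rows_normalized_on_generated_sequence(self, models, rng):
        seq = sq.generate_sequence(models[2], 672, rng)
        tab = sq.empirical_distribution(seq, 2)
        for c in tab.contexts:
            assert abs(tab.row(c).sum() - 1.0) < 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sq.empirical_distribution("", 0)


class TestKLToIdeal:
    def test_hand_computed_level0_value(self):
        m = sq.build_model(0)
        # B:14, A:4, C:1, D:1 of 20 -> P = (0.20, 0.70, 0.05, 0.05)
        seq = "B" * 14 + "A" * 4 + "C" + "D"
        expect = (0.72 * np.log(0.72 / 0.70) + 0.18 * np.log(0.18 / 0.20))
        assert sq.kl_to_ideal(seq, m) == pytest.approx(expect, abs=1e-4)
        assert expect == pytest.approx(0.00132, abs=2e-5)

    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_matches_brute_force_summation(self, models, rng, level):
        m = models[level]
        for seq in sq.generate_sequences(m, 5, 300, rng):
            got = sq.kl_to_ideal(seq, m)
            assert got >= 0
            assert got == pytest.approx(brute_force_kl(seq, m), rel=1e-10)

    def test_zero_when_empirical_matches_exactly(self):
        m = sq.build_model(0, level0_probs=(0.25, 0.25, 0.25, 0.25))
        assert sq.kl_to_ideal("ABCD" * 5, m) == pytest.approx(0, abs=1e-9)

    def test_log_base_conversion(self, models, rng):
        seq = sq.generate_sequence(models[1], 300, rng)
        nats = sq.kl_to_ideal(seq, models[1])
        bits = sq.kl_to_ideal(seq, models[1], log_base=2)
        assert bits == pytest.approx(nats / np.log(2))


class TestSelectSequences:
    def test_matches_exhaustive_sort_oracle(self, models):
        m = models[1]
        sel = sq.select_sequences(m, 10, 100, 3, np.random.default_rng(3))
        pool = sq.generate_sequences(m, 10, 100, np.random.default_rng(3))
        scores = [sq.kl_to_ideal(s, m) for s in pool]
        order = np.argsort(scores, kind="stable")[:3]
        assert np.array_equal(sel.sequences, pool[order])
        assert np.allclose(sel.kl_scores, np.array(scores)[order])

    def test_empty_selection(self, models, rng):
        assert len(sq.select_sequences(models[0], 10, 50, 0, rng)) == 0

    def test_n_select_exceeding_pool_rejected(self, models, rng):
        with pytest.raises(ValueError):
            sq.select_sequences(models[0], 5, 50, 6, rng)

    def test_selected_scores_sorted_and_stochastically_small(self, models):
        m = models[2]
        sel = sq.select_sequences(m, 200, 300, 50, np.random.default_rng(11))
        assert np.all(np.diff(sel.kl_scores) >= 0)
        pool = sq.generate_sequences(m, 200, 300, np.random.default_rng(11))
        all_scores = np.array([sq.kl_to_ideal(s, m) for s in pool])
        random_subset = np.random.default_rng(1).choice(all_scores, 50, replace=False)
        res = stats.mannwhitneyu(sel.kl_scores, random_subset, alternative="less")
        assert res.pvalue < 0.01


class TestTrialAssembly:
    def test_block_has_eight_trials_per_length(self, models, rng):
        seqset = sq.select_sequences(models[1], 20, 300, 5, rng)
        block = sq.make_training_block(seqset, 56, (8, 14), rng)
        assert len(block) == 56
        lengths = [t.presented.size for t in block]
        assert all(lengths.count(L) == 8 for L in range(8, 15))

    def test_one_trial_per_length(self, models, rng):
        seqset = sq.select_sequences(models[0], 10, 100, 3, rng)
        block = sq.make_training_block(seqset, 7, (8, 14), rng)
        assert sorted(t.presented.size for t in block) == list(range(8, 15))

    def test_divisibility_violation_rejected(self, models, rng):
        seqset = sq.select_sequences(models[0], 10, 100, 3, rng)
        with pytest.raises(ValueError):
            sq.make_training_block(seqset, 55, (8, 14), rng)

    def test_trial_contexts_are_model_reachable(self, models, rng):
        m = models[2]
        seqset = sq.select_sequences(m, 20, 300, 5, rng)
        block = sq.make_training_block(seqset, 56, (8, 14), rng)
        for t in block:
            assert t.context(m.order) in m._ctx_index

    def test_test_run_composition(self, models, rng):
        run = sq.make_test_run(models[1], rng)
        assert len(run) == 20
        conditions = [t.condition for t in run]
        assert conditions.count("structured") == 10
        assert conditions.count("random") == 10
        assert all(t.presented.size == 10 for t in run)

    def test_random_trials_uniform_over_runs(self, models):
        rng = np.random.default_rng(21)
        counts = np.zeros(4)
        for _ in range(150):
            for t in sq.make_test_run(models[0], rng):
                if t.condition == "random":
                    counts += np.bincount(t.presented, minlength=4)
        freq = counts / counts.sum()
        assert np.allclose(freq, 0.25, atol=0.01)


class TestRandomSequence:
    def test_uniform_frequencies(self):
        seq = sq.make_random_sequence(400_000, np.random.default_rng(5))
        freq = np.bincount(seq, minlength=4) / seq.size
        assert np.allclose(freq, 0.25, atol=0.005)

    def test_single_item_and_determinism(self):
        assert sq.make_random_sequence(1, np.random.default_rng(0)).size == 1
        a = sq.make_random_sequence(100, np.random.default_rng(4))
        b = sq.make_random_sequence(100, np.random.default_rng(4))
        assert np.array_equal(a, b)


def test_alphabet_requires_bijection():
    with pytest.raises(ValueError):
        sq.Alphabet(symbol_map=(0, 1, 1, 3))
    assert sq.Alphabet().items == ("A", "B", "C", "D")
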