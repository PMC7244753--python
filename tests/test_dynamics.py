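"""Occupancy, dwell, appearance, transition statistics, permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brainstates as bs
from brainstates.dynamics import (
    appearance_rate,
    block_restrict,
    compress_runs,
    dwell_times,
    fractional_occupancy,
    group_average_tp,
    lagged_transition_probability,
    permutation_test_tp,
    transition_probability,
)
from brainstates.types import StateSequence, TransitionMatrix, ValidationError

seq_strategy = st.lists(st.integers(1, 4), min_size=1, max_size=60).map(
    lambda labels: StateSequence(labels=np.array(labels), k=4, tr=2.0)
)


class TestToySequence:
    """Hand-counted values on the worked example [1 1 1 2 2 3 2 2], TR = 3 s."""

    def test_run_compression(self, toy_seq):
        assert np.array_equal(compress_runs(toy_seq).labels, [1, 2, 3, 2])

    def test_fractional_occupancy(self, toy_seq):
        assert np.allclose(fractional_occupancy(toy_seq), [37.5, 50.0, 12.5])

    def test_dwell_times(self, toy_seq):
        # runs: state 1 {3}, state 2 {2, 2}, state 3 {1}; x 3 s
        assert np.allclose(dwell_times(toy_seq), [9.0, 6.0, 3.0])

    def test_appearance_rate(self, toy_seq):
        # 24 s of scan: state 2 appears twice -> 5 runs per minute
        assert np.allclose(appearance_rate(toy_seq), [2.5, 5.0, 2.5])

    def test_transition_probabilities(self, toy_seq):
        tp = transition_probability(toy_seq)
        expected = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        assert np.allclose(tp.probs, expected)
        assert tp.counts.sum() == 3


class TestMetrics:
    def test_dwell_scales_with_tr(self, toy_seq):
        double = StateSequence(labels=toy_seq.labels, k=3, tr=6.0)
        assert np.allclose(dwell_times(double), 2 * dwell_times(toy_seq))

    def test_single_frame_scan(self):
        seq = StateSequence(labels=np.array([2]), k=3, tr=3.0)
        assert dwell_times(seq)[1] == 3.0
        assert np.isnan(dwell_times(seq)[0])
        assert np.allclose(fractional_occupancy(seq), [0.0, 100.0, 0.0])

    def test_constant_sequence_rate_closed_form(self):
        n, tr = 37, 2.0
        seq = StateSequence(labels=np.full(n, 1), k=2, tr=tr)
        assert appearance_rate(seq)[0] == pytest.approx(60.0 / (n * tr))
        assert appearance_rate(seq)[1] == 0.0

    @given(seq_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_occupancy_dwell_rate_identity(self, seq):
        # FO_i = rate_i (per min) * dwell_i (s) * 100 / 60, exactly
        fo = fractional_occupancy(seq)
        dw = dwell_times(seq)
        rate = appearance_rate(seq)
        visited = ~np.isnan(dw)
        assert np.allclose(fo[visited], rate[visited] * dw[visited] * 100.0 / 60.0)
        assert fo.sum() == pytest.approx(100.0)

    @given(seq_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_compression_idempotent_and_tp_run_invariant(self, seq):
        comp = compress_runs(seq)
        assert np.array_equal(compress_runs(comp).labels, comp.labels)
        assert np.allclose(
            transition_probability(seq).probs,
            transition_probability(comp).probs,
            equal_nan=True,
        )


class TestTransitionMatrices:
    def test_constant_sequence_all_rows_undefined(self):
        tp = transition_probability(StateSequence(labels=np.full(9, 2), k=3, tr=1.0))
        assert np.all(np.isnan(tp.probs))
        assert not tp.defined_rows().any()

    def test_lagged_hand_count(self):
        seq = StateSequence(labels=np.array([1, 1, 2]), k=2, tr=1.0)
        lag = lagged_transition_probability(seq)
        assert np.allclose(lag[0], [0.5, 0.5])
        assert np.all(np.isnan(lag[1]))

    def test_lagged_constant_sequence_identity_row(self):
        lag = lagged_transition_probability(
            StateSequence(labels=np.full(5, 1), k=2, tr=1.0)
        )
        assert np.allclose(lag[0], [1.0, 0.0])

    def test_lagged_consistent_with_compressed_on_markov_chain(self):
        # zero the diagonal of the lagged matrix and renormalize: for a chain
        # with geometric dwell this equals the persistence-excluded TP
        tp = np.array([[0.0, 0.8, 0.2], [0.4, 0.0, 0.6], [0.3, 0.7, 0.0]])
        seq = bs.generate_state_sequence(tp, dwell=4.0, n_frames=200_000, seed=6)
        lag = lagged_transition_probability(seq)
        np.fill_diagonal(lag, 0.0)
        lag /= lag.sum(axis=1, keepdims=True)
        comp = transition_probability(seq).probs
        assert np.nanmax(np.abs(lag - comp)) < 0.02

    def test_group_average_and_nan_policy(self):
        a = TransitionMatrix(
            probs=np.array([[0.0, 1.0], [1.0, 0.0]]),
            counts=np.ones((2, 2), int),
            k=2,
        )
        nanrow = np.array([[0.0, 1.0], [np.nan, np.nan]])
        b = TransitionMatrix(probs=nanrow, counts=np.zeros((2, 2), int), k=2)
        mean, n = group_average_tp([a, a])
        assert np.allclose(mean, a.probs)
        mean, n = group_average_tp([a, b])
        assert mean[1, 0] == 1.0  # undefined row excluded, not imputed
        assert n[1, 0] == 1

    def test_group_average_empty_rejected(self):
        with pytest.raises(ValidationError):
            group_average_tp([])


class TestBlockRestrict:
    def test_uniform_block_is_identity(self):
        labels = np.array([1, 2, 2, 3])
        seq = StateSequence(
            labels=labels, k=3, tr=1.0, block_labels=np.full(4, "2back", dtype=object)
        )
        out = block_restrict(seq, "2back")
        assert np.array_equal(out.labels, labels)

    def test_restrictions_partition_the_frames(self):
        rng = np.random.default_rng(0)
        blocks = np.repeat(["0back", "1back", "2back", "0back"], 10).astype(object)
        seq = StateSequence(
            labels=rng.integers(1, 4, size=40), k=3, tr=1.0, block_labels=blocks
        )
        total = sum(
            block_restrict(seq, b).n_frames for b in ("0back", "1back", "2back")
        )
        assert total == 40

    def test_block_boundary_terminates_runs(self):
        # state 1 spans a 0back/0back boundary across an intervening 1back
        labels = np.array([1, 1, 2, 1, 1])
        blocks = np.array(["0back", "0back", "1back", "0back", "0back"], dtype=object)
        seq = StateSequence(labels=labels, k=2, tr=1.0, block_labels=blocks)
        out = block_restrict(seq, "0back")
        # two separate runs of state 1, no 1->1 "transition" bridged
        assert appearance_rate(out)[0] * out.n_frames * out.tr / 60.0 == 2
        assert transition_probability(out).counts.sum() == 0

    def test_planted_block_chains_recovered(self):
        tp_a = bs.tilted_jump_matrix(3, {(1, 2): 0.3})
        tp_b = bs.tilted_jump_matrix(3, {(1, 3): 0.3})
        rng = np.random.default_rng(8)
        labels, blocks = [], []
        for rep in range(300):
            for tp, name in ((tp_a, "0back"), (tp_b, "2back")):
                part = bs.generate_state_sequence(tp, 2.0, 50, seed=rng)
                labels.append(part.labels)
                blocks.append(np.full(50, name, dtype=object))
        seq = StateSequence(
            labels=np.concatenate(labels),
            k=3,
            tr=1.0,
            block_labels=np.concatenate(blocks),
        )
        est_a = transition_probability(block_restrict(seq, "0back")).probs
        est_b = transition_probability(block_restrict(seq, "2back")).probs
        # ~2700 transitions per condition: binomial SE < 0.01, use a 4-SE band
        assert np.nanmax(np.abs(est_a - tp_a)) < 0.04
        assert np.nanmax(np.abs(est_b - tp_b)) < 0.04

    def test_unknown_block_rejected(self, toy_seq):
        seq = StateSequence(
            labels=toy_seq.labels,
            k=3,
            tr=3.0,
            block_labels=np.full(8, "0back", dtype=object),
        )
        with pytest.raises(ValidationError):
            block_restrict(seq, "7back")


def _subject_tps(rng, n, tp, frames=300, dwell=3.0):
    out = []
    for _ in range(n):
        seq = bs.generate_state_sequence(tp, dwell, frames, seed=rng)
        out.append(transition_probability(seq))
    return out


class TestPermutationTest:
    def test_identical_conditions_not_significant(self):
        rng = np.random.default_rng(0)
        tps = _subject_tps(rng, 30, bs.uniform_jump_matrix(4))
        res = permutation_test_tp(tps, tps, n_perm=2000, seed=1)
        # per-subject rest == task: every null difference equals the observed
        assert np.nanmin(res.pvals_corrected) == 1.0

    def test_planted_shift_detected_with_type_I_control(self):
        rng = np.random.default_rng(2)
        k = 4
        rest_tp = bs.uniform_jump_matrix(k)
        task_tp = bs.tilted_jump_matrix(k, {(1, 2): 0.25})
        rest = _subject_tps(rng, 100, rest_tp)
        task = _subject_tps(rng, 100, task_tp)
        res = permutation_test_tp(rest, task, n_perm=5000, seed=3)
        assert res.pvals_corrected[0, 1] < 0.05
        assert res.observed_diff[0, 1] > 0
        others = ~np.eye(k, dtype=bool)
        others[0, 1] = False
        # the renormalization of row 1 shifts (1,3) and (1,4) down slightly;
        # elements in untouched rows stay controlled
        untouched = others.copy()
        untouched[0, :] = False
        assert np.nanmin(res.pvals[untouched]) > 0.05 / (k * (k - 1))

    def test_pvalue_bounds(self):
        rng = np.random.default_rng(4)
        rest = _subject_tps(rng, 10, bs.uniform_jump_matrix(3), frames=100)
        task = _subject_tps(rng, 10, bs.uniform_jump_matrix(3), frames=100)
        n_perm = 500
        res = permutation_test_tp(rest, task, n_perm=n_perm, seed=5)
        off = ~np.eye(3, dtype=bool)
        assert np.all(res.pvals[off] >= 1.0 / (n_perm + 1))
        assert np.all(res.pvals[off] <= 1.0)

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(6)
        tps = _subject_tps(rng, 4, bs.uniform_jump_matrix(3), frames=60)
        with pytest.raises(ValidationError):
            permutation_test_tp(tps, tps[:2], n_perm=10, seed=0)
        with pytest.raises(ValidationError):
            permutation_test_tp(tps, tps, n_perm=0, seed=0)

    def test_result_table_shape(self):
        rng = np.random.default_rng(7)
        tps = _subject_tps(rng, 6, bs.uniform_jump_matrix(3), frames=100)
        res = permutation_test_tp(tps, tps, n_perm=50, seed=0)
        frame = res.to_frame()
        assert len(frame) == 6  # k(k-1) off-diagonal elements
        assert set(frame.columns) >= {"from_state", "to_state", "p", "p_corrected"}
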