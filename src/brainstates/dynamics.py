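"""Temporal statistics of brain-state sequences.

Three per-state summaries describe how a scan occupies its states:
fractional occupancy (percent of frames in the state), dwell time (mean run
duration in seconds), and appearance rate (runs per minute). Transitions are
treated separately from persistence: the state sequence is first compressed
by collapsing consecutive duplicates (e.g. [1 1 1 2 2 3 2 2] -> [1 2 3 2]),
and the transition probability from i to j is the probability that j is the
next *new* state after i, so the statistic is free of state autocorrelation.
A lagged (frame-to-frame) variant that keeps the diagonal is provided for
non-randomness checks. Rest-vs-task differences in group-average transition
matrices are tested with a half-sample-mixing permutation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import StateSequence, TransitionMatrix, ValidationError

__all__ = [
    "compress_runs",
    "fractional_occupancy",
    "dwell_times",
    "appearance_rate",
    "scan_metrics",
    "transition_probability",
    "lagged_transition_probability",
    "block_restrict",
    "group_average_tp",
    "permutation_test_tp",
    "PermutationResult",
]


def _segments(seq: StateSequence) -> np.ndarray:
    if seq.segment_ids is None:
        return np.zeros(seq.n_frames, dtype=int)
    return seq.segment_ids


def _runs(seq: StateSequence) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode labels; runs never cross segment boundaries."""
    labels = seq.labels
    seg = _segments(seq)
    change = np.empty(labels.size, dtype=bool)
    change[0] = True
    change[1:] = (labels[1:] != labels[:-1]) | (seg[1:] != seg[:-1])
    starts = np.flatnonzero(change)
    lengths = np.diff(np.append(starts, labels.size))
    return labels[starts], lengths


def compress_runs(seq: StateSequence) -> StateSequence:
    """Collapse consecutive duplicate states so every dwell time equals one.

    Segment boundaries are preserved: identical states on either side of a
    boundary stay separate entries.
    """
    labels = seq.labels
    seg = _segments(seq)
    change = np.empty(labels.size, dtype=bool)
    change[0] = True
    change[1:] = (labels[1:] != labels[:-1]) | (seg[1:] != seg[:-1])
    starts = np.flatnonzero(change)
    return StateSequence(
        labels=labels[starts],
        k=seq.k,
        tr=seq.tr,
        subject_id=seq.subject_id,
        condition=seq.condition,
        segment_ids=seg[starts] if seq.segment_ids is not None else None,
    )


def fractional_occupancy(seq: StateSequence, k: int | None = None) -> np.ndarray:
    """Percent of frames assigned to each state; sums to 100."""
    k = seq.k if k is None else k
    counts = np.bincount(seq.labels, minlength=k + 1)[1 : k + 1]
    return 100.0 * counts / seq.n_frames


def dwell_times(seq: StateSequence, k: int | None = None) -> np.ndarray:
    """Mean duration (seconds) of continuous runs of each state.

    Unvisited states are NaN. Runs truncated at scan or block boundaries
    count toward the mean.
    """
    k = seq.k if k is None else k
    states, lengths = _runs(seq)
    out = np.full(k, np.nan)
    for s in range(1, k + 1):
        mask = states == s
        if mask.any():
            out[s - 1] = lengths[mask].mean() * seq.tr
    return out


def appearance_rate(seq: StateSequence, k: int | None = None) -> np.ndarray:
    """Number of runs of each state per minute of scan; unvisited -> 0."""
    k = seq.k if k is None else k
    states, _ = _runs(seq)
    counts = np.bincount(states, minlength=k + 1)[1 : k + 1]
    minutes = seq.n_frames * seq.tr / 60.0
    return counts / minutes


def scan_metrics(seq: StateSequence, k: int | None = None) -> pd.DataFrame:
    """Tidy per-state table of FO (percent), dwell (s), and rate (/min)."""
    k = seq.k if k is None else k
    return pd.DataFrame(
        {
            "state": np.arange(1, k + 1),
            "fractional_occupancy": fractional_occupancy(seq, k),
            "dwell_time": dwell_times(seq, k),
            "appearance_rate": appearance_rate(seq, k),
        }
    )


def transition_probability(seq: StateSequence, k: int | None = None) -> TransitionMatrix:
    """Persistence-excluded transition probabilities.

    Counts are accumulated over consecutive entries of the run-compressed
    sequence (within segments); probabilities are row-normalized counts with
    a structurally zero diagonal. Rows of states never exited are undefined
    and stored as NaN.
    """
    k = seq.k if k is None else k
    comp = compress_runs(seq)
    labels = comp.labels
    seg = _segments(comp)
    counts = np.zeros((k, k), dtype=int)
    if labels.size > 1:
        a, b = labels[:-1], labels[1:]
        ok = seg[:-1] == seg[1:]
        np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1)
    row_sums = counts.sum(axis=1)
    probs = np.full((k, k), np.nan)
    defined = row_sums > 0
    probs[defined] = counts[defined] / row_sums[defined, None]
    probs[np.arange(k)[defined], np.arange(k)[defined]] = 0.0
    return TransitionMatrix(probs=probs, counts=counts, k=k, scope=seq.condition)


def lagged_transition_probability(
    seq: StateSequence, k: int | None = None
) -> np.ndarray:
    """Frame-to-frame conditional probabilities P(s_{t+1} = j | s_t = i).

    Unlike :func:`transition_probability`, the diagonal (state persistence
    across one TR) is retained. Rows of states with no outgoing frame pair
    are NaN.
    """
    k = seq.k if k is None else k
    labels = seq.labels
    seg = _segments(seq)
    counts = np.zeros((k, k), dtype=float)
    if labels.size > 1:
        ok = seg[:-1] == seg[1:]
        np.add.at(counts, (labels[:-1][ok] - 1, labels[1:][ok] - 1), 1)
    row_sums = counts.sum(axis=1)
    probs = np.full((k, k), np.nan)
    defined = row_sums > 0
    probs[defined] = counts[defined] / row_sums[defined, None]
    return probs


def block_restrict(seq: StateSequence, block: str) -> StateSequence:
    """Restrict a sequence to frames carrying a given block label.

    Retained frames that were not adjacent in the original scan receive
    distinct segment ids, so block boundaries terminate runs and are never
    counted as transitions.
    """
    if seq.block_labels is None:
        raise ValidationError("sequence carries no block labels")
    mask = seq.block_labels == block
    if not mask.any():
        raise ValidationError(f"no frames labelled {block!r}")
    idx = np.flatnonzero(mask)
    base_seg = _segments(seq)[idx]
    gaps = np.empty(idx.size, dtype=bool)
    gaps[0] = True
    gaps[1:] = (np.diff(idx) != 1) | (base_seg[1:] != base_seg[:-1])
    return StateSequence(
        labels=seq.labels[idx],
        k=seq.k,
        tr=seq.tr,
        subject_id=seq.subject_id,
        condition=seq.condition,
        block_labels=seq.block_labels[idx],
        segment_ids=np.cumsum(gaps) - 1,
    )


def group_average_tp(tps: list[TransitionMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean of transition matrices, ignoring undefined rows.

    Returns ``(mean, n)`` where ``n`` counts the matrices contributing to
    each element. Elements undefined everywhere are NaN.
    """
    if not tps:
        raise ValidationError("empty list of transition matrices")
    k = tps[0].k
    for t in tps:
        if t.k != k:
            raise ValidationError("transition matrices disagree on k")
    stack = np.stack([t.probs for t in tps])
    n = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(stack, axis=0) / np.maximum(n, 1), np.nan)
    return mean, n


@dataclass
class PermutationResult:
    """Result of the rest-vs-task transition-matrix permutation test."""

    observed_diff: np.ndarray  # (k, k) task - rest group means
    pvals: np.ndarray  # (k, k), NaN diagonal
    pvals_corrected: np.ndarray  # Bonferroni over the k(k-1) off-diagonals
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        k = self.observed_diff.shape[0]
        rows = []
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    {
                        "from_state": i + 1,
                        "to_state": j + 1,
                        "observed_diff": self.observed_diff[i, j],
                        "p": self.pvals[i, j],
                        "p_corrected": self.pvals_corrected[i, j],
                    }
                )
        return pd.DataFrame(rows)


def permutation_test_tp(
    rest_tps: list[TransitionMatrix],
    task_tps: list[TransitionMatrix],
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
    batch: int = 10_000,
) -> PermutationResult:
    """Half-sample-mixing permutation test of task-vs-rest transition matrices.

    The observed statistic is the element-wise difference between the group
    average task and rest matrices. Under the null, subjects are repeatedly
    split into random halves; the rest matrices of one half are averaged with
    the task matrices of the other (and vice versa), and the difference of
    the two mixed averages forms the null distribution. Two-sided p-values
    use the add-one correction, p >= 1/(n_perm + 1); Bonferroni correction is
    applied over the k(k-1) off-diagonal elements.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if len(rest_tps) != len(task_tps) or not rest_tps:
        raise ValidationError("rest and task lists must be paired and nonempty")
    n = len(rest_tps)
    k = rest_tps[0].k
    rng = np.random.default_rng(seed)

    R = np.stack([t.probs for t in rest_tps]).reshape(n, -1)
    Tk = np.stack([t.probs for t in task_tps]).reshape(n, -1)
    Rv, Rc = np.nan_to_num(R), (~np.isnan(R)).astype(float)
    Tv, Tc = np.nan_to_num(Tk), (~np.isnan(Tk)).astype(float)
    sum_R, cnt_R = Rv.sum(axis=0), Rc.sum(axis=0)
    sum_T, cnt_T = Tv.sum(axis=0), Tc.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(cnt_T > 0, sum_T / np.maximum(cnt_T, 1), np.nan) - np.where(
            cnt_R > 0, sum_R / np.maximum(cnt_R, 1), np.nan
        )

    half = n // 2
    exceed = np.zeros(k * k)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # boolean half masks, one per permutation
        masks = np.zeros((b, n))
        order = np.argsort(rng.random((b, n)), axis=1)[:, :half]
        np.put_along_axis(masks, order, 1.0, axis=1)
        sum_R_A, cnt_R_A = masks @ Rv, masks @ Rc
        sum_T_A, cnt_T_A = masks @ Tv, masks @ Tc
        with np.errstate(invalid="ignore", divide="ignore"):
            mixed1 = (sum_R_A + (sum_T - sum_T_A)) / (cnt_R_A + (cnt_T - cnt_T_A))
            mixed2 = ((sum_R - sum_R_A) + sum_T_A) / ((cnt_R - cnt_R_A) + cnt_T_A)
            null_diff = mixed1 - mixed2
        exceed += np.sum(np.abs(null_diff) >= np.abs(obs)[None, :], axis=0)
        done += b

    pv = (1.0 + exceed) / (n_perm + 1.0)
    pv = pv.reshape(k, k)
    obs = obs.reshape(k, k)
    np.fill_diagonal(pv, np.nan)
    m = k * (k - 1)
    pcorr = np.minimum(pv * m, 1.0)
    return PermutationResult(
        observed_diff=obs, pvals=pv, pvals_corrected=pcorr, n_perm=n_perm
    )
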