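"""Correlation-distance k-means, state naming, reliability, surrogates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brainstates as bs
from brainstates.clustering import (
    _greedy_align,
    assign_states,
    autocorr_surrogate,
    concatenate_scans,
    elbow_scan,
    fit_kmeans,
    name_states,
    split_concatenated,
    split_half_reliability,
    variance_explained,
)
from brainstates.types import BoldScan, ClusterModel, ValidationError


def _scan(data, sid="s0", cond="rest", tr=3.0):
    return BoldScan(subject_id=sid, condition=cond, data=data, tr=tr)


class TestConcatenate:
    def test_row_count_and_invertible_index(self, cohort40):
        X, index = concatenate_scans(cohort40.scans)
        assert X.shape[0] == 40 * (120 + 225) == len(index)
        parts = split_concatenated(X, index)
        assert len(parts) == 80
        # round-trip: re-concatenating the parts reproduces the matrix
        rebuilt = np.vstack(
            [parts[(s.subject_id, s.condition)] for s in cohort40.scans]
        )
        assert np.array_equal(rebuilt, X)

    def test_single_scan_without_standardization_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(10, 4))
        X, _ = concatenate_scans([_scan(data)], standardize=False)
        assert np.array_equal(X, data)

    def test_region_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        a = _scan(rng.normal(size=(5, 4)))
        b = _scan(rng.normal(size=(5, 6)), sid="s1")
        with pytest.raises(ValidationError):
            concatenate_scans([a, b])

    def test_standardization_zscales_each_region(self):
        rng = np.random.default_rng(1)
        X, _ = concatenate_scans([_scan(rng.normal(5.0, 2.0, size=(200, 3)))])
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(X.std(axis=0), 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(42)
    C = rng.normal(size=(4, 30))
    X = np.repeat(C, 100, axis=0) + rng.normal(0, 0.01, size=(400, 30))
    return C, X


class TestKMeans:
    def test_recovers_planted_centroids(self, planted):
        C, X = planted
        model = fit_kmeans(X, 4, n_reps=5, seed=0)
        pairs = _greedy_align(model.centroids, C)
        assert all(r > 0.99 for _, _, r in pairs)

    def test_k_below_two_rejected(self, planted):
        with pytest.raises(ValidationError):
            fit_kmeans(planted[1], 1)

    def test_deterministic_for_fixed_seed(self, planted):
        _, X = planted
        a = fit_kmeans(X, 4, n_reps=3, seed=5)
        b = fit_kmeans(X, 4, n_reps=3, seed=5)
        assert np.array_equal(a.centroids, b.centroids)

    def test_constant_frame_rejected(self):
        X = np.vstack([np.ones(10), np.random.default_rng(0).normal(size=(20, 10))])
        with pytest.raises(ValidationError):
            fit_kmeans(X, 2)


class TestVarianceExplained:
    def test_perfect_partition_explains_everything(self):
        C = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 1.0]])
        X = np.repeat(C, 5, axis=0)
        labels = np.repeat([1, 2], 5)
        assert variance_explained(X, labels, C) == pytest.approx(1.0)

    def test_single_cluster_explains_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        labels = np.ones(30, dtype=int)
        assert variance_explained(X, labels) == pytest.approx(0.0)

    def test_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        labels = rng.integers(1, 4, size=40)
        centroids = np.vstack([X[labels == c].mean(axis=0) for c in (1, 2, 3)])
        # direct summation oracle
        grand = X.mean(axis=0)
        ssb = sum(
            (labels == c).sum() * np.sum((centroids[c - 1] - grand) ** 2)
            for c in (1, 2, 3)
        )
        ssw = sum(
            np.sum((X[labels == c] - centroids[c - 1]) ** 2) for c in (1, 2, 3)
        )
        assert variance_explained(X, labels, centroids) == pytest.approx(
            ssb / (ssb + ssw)
        )

    def test_invariant_to_cluster_relabeling(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        labels = rng.integers(1, 4, size=30)
        swapped = labels.copy()
        swapped[labels == 1], swapped[labels == 2] = 2, 1
        assert variance_explained(X, labels) == pytest.approx(
            variance_explained(X, swapped)
        )


class TestElbow:
    def test_gain_drops_after_planted_k(self, fitted40):
        X, _, _ = fitted40
        table = elbow_scan(X, range(2, 8), n_reps=5, seed=2)
        gains = table.set_index("k")["gain"]
        assert gains.loc[6] < 0.01 and gains.loc[7] < 0.01
        assert gains.loc[5] > 0.01

    def test_single_k_has_no_gain(self, fitted40):
        X, _, _ = fitted40
        table = elbow_scan(X[:500], [2], n_reps=2, seed=0)
        assert len(table) == 1
        assert np.isnan(table["gain"].iloc[0])


class TestAssign:
    def test_frame_equal_to_centroid_gets_its_label(self):
        rng = np.random.default_rng(0)
        C = rng.normal(size=(4, 10))
        model = ClusterModel(
            k=4, centroids=C, variance_explained=0.0, within_cluster_error=0.0
        )
        scan = _scan(C[[2]], tr=3.0)
        assert assign_states(model, scan, standardize=False).labels[0] == 3

    def test_tie_goes_to_lowest_state_index(self):
        c = np.array([1.0, 0.0, -1.0, 0.5])
        model = ClusterModel(
            k=2,
            centroids=np.vstack([c, c]),  # duplicated centroid: every frame ties
            variance_explained=0.0,
            within_cluster_error=0.0,
        )
        scan = _scan(np.random.default_rng(1).normal(size=(5, 4)))
        assert np.all(assign_states(model, scan).labels == 1)

    def test_zero_noise_assignment_recovers_planted_sequence(self, small_parc):
        C = bs.planted_centroids(small_parc)
        seq = bs.generate_state_sequence(bs.uniform_jump_matrix(5), 3.0, 300, seed=2)
        scan = bs.generate_bold_from_sequence(seq, C, noise_sd=0.0, seed=2)
        model = ClusterModel(
            k=5, centroids=C, variance_explained=0.0, within_cluster_error=0.0
        )
        out = assign_states(model, scan, standardize=False)
        assert np.array_equal(out.labels, seq.labels)

    def test_dimension_mismatch_rejected(self):
        model = ClusterModel(
            k=2,
            centroids=np.random.default_rng(0).normal(size=(2, 6)),
            variance_explained=0.0,
            within_cluster_error=0.0,
        )
        with pytest.raises(ValidationError):
            assign_states(model, _scan(np.random.default_rng(1).normal(size=(4, 5))))


class TestNaming:
    def test_system_indicator_named_positive(self, small_parc):
        c = small_parc.indicator("DMN")
        names, table = name_states(c[None, :], small_parc)
        assert names == ["DMN+"]
        row = table[(table.system == "DMN") & (table.component == "pos")]
        assert row["cosine"].iloc[0] == pytest.approx(1.0)

    def test_negated_indicator_flips_suffix(self, small_parc):
        names, _ = name_states(-small_parc.indicator("VIS")[None, :], small_parc)
        assert names == ["VIS-"]

    def test_mixed_centroid_matches_brute_force_argmax(self, small_parc):
        rng = np.random.default_rng(6)
        c = rng.normal(size=small_parc.n_regions)
        names, table = name_states(c[None, :], small_parc)
        # independent argmax over the 14 component similarities
        pos, neg = np.maximum(c, 0), np.maximum(-c, 0)
        best, best_sim = None, -np.inf
        for system in bs.SYSTEMS:
            ind = small_parc.indicator(system)
            for vec, suffix in ((pos, "+"), (neg, "-")):
                sim = vec @ ind / (np.linalg.norm(vec) * np.linalg.norm(ind))
                if sim > best_sim:
                    best_sim, best = sim, f"{system}{suffix}"
        assert names[0] == best

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_negation_equivariance(self, seed):
        parc = bs.generate_parcellation(21, {s: 3 for s in bs.SYSTEMS}, seed=11)
        c = np.random.default_rng(seed).normal(size=21)
        n_pos, _ = name_states(c[None, :], parc)
        n_neg, _ = name_states(-c[None, :], parc)
        flip = {"+": "-", "-": "+"}
        assert n_neg[0] == n_pos[0][:-1] + flip[n_pos[0][-1]]


class TestReliability:
    def test_duplicated_data_gives_perfect_agreement(self, small_parc):
        C = bs.planted_centroids(small_parc)
        seq = bs.generate_state_sequence(bs.uniform_jump_matrix(5), 3.0, 400, seed=3)
        data = bs.generate_bold_from_sequence(seq, C, noise_sd=0.05, seed=3).data
        scans = [
            BoldScan(subject_id=f"s{i}", condition="rest", data=data, tr=3.0)
            for i in range(4)
        ]
        out = split_half_reliability(scans, k=5, n_splits=3, seed=0, n_reps=5)
        assert np.all(out["r"].to_numpy() > 0.999)

    def test_planted_cohort_reliable(self, cohort40):
        out = split_half_reliability(
            cohort40.scans[:40], k=5, n_splits=5, seed=1, n_reps=5
        )
        assert out.groupby("split")["r"].median().min() > 0.9

    def test_zero_splits_empty_result(self, cohort40):
        out = split_half_reliability(cohort40.scans[:8], k=5, n_splits=0, seed=0)
        assert len(out) == 0

    def test_single_subject_rejected(self, cohort40):
        with pytest.raises(ValidationError):
            split_half_reliability(cohort40.scans[:2], k=5, n_splits=1, seed=0)


class TestSurrogate:
    def test_power_spectrum_preserved(self, cohort40):
        scan = cohort40.scans[0]
        sur = autocorr_surrogate(scan, seed=0)
        assert np.allclose(
            np.abs(np.fft.rfft(scan.data, axis=0)),
            np.abs(np.fft.rfft(sur.data, axis=0)),
        )

    def test_cross_regional_structure_destroyed(self, small_parc):
        C = bs.planted_centroids(small_parc)
        seq = bs.generate_state_sequence(bs.uniform_jump_matrix(5), 3.0, 5000, seed=4)
        scan = bs.generate_bold_from_sequence(seq, C, noise_sd=0.3, seed=4)
        sur = autocorr_surrogate(scan, seed=5)
        R = np.corrcoef(sur.data.T)
        off = ~np.eye(R.shape[0], dtype=bool)
        assert np.mean(np.abs(R[off])) < 0.05

    def test_planted_structure_clusters_better_than_surrogates(self, cohort40):
        scans = cohort40.scans[:10]
        X, _ = concatenate_scans(scans)
        ve_real = fit_kmeans(X, 5, n_reps=3, seed=0).variance_explained
        rng = np.random.default_rng(0)
        ve_null = []
        for rep in range(5):
            surs = [autocorr_surrogate(s, seed=rng) for s in scans]
            Xs, _ = concatenate_scans(surs)
            ve_null.append(fit_kmeans(Xs, 5, n_reps=3, seed=rep).variance_explained)
        assert ve_real > max(ve_null)
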