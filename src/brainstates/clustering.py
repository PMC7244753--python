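"""Frame-wise clustering of BOLD data into recurrent brain states.

Frames from all scans are z-scored per region within each scan, concatenated
into one large frames x regions matrix, and clustered with k-means under
correlation distance d(x, c) = 1 - r(x, c). Correlation distance is realized
as spherical k-means on row-centered, unit-norm vectors, for which the
Euclidean and correlation argmins coincide, preserving the usual Lloyd
convergence guarantee. The best of ``n_reps`` restarts (lowest within-cluster
error) is kept. States are named by the cosine similarity of their positive
and negative components to binary indicator vectors of the seven canonical
resting-state systems.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    SYSTEMS,
    BoldScan,
    ClusterModel,
    RegionParcellation,
    StateSequence,
    ValidationError,
)

__all__ = [
    "standardize_scan",
    "concatenate_scans",
    "split_concatenated",
    "fit_kmeans",
    "variance_explained",
    "elbow_scan",
    "assign_states",
    "name_states",
    "split_half_reliability",
    "autocorr_surrogate",
]


# ---------------------------------------------------------------------------
# standardization and concatenation
# ---------------------------------------------------------------------------

def standardize_scan(scan: BoldScan) -> BoldScan:
    """z-score each region's time series within the scan.

    Regions with zero temporal variance are centered only (they carry no
    signal to rescale).
    """
    X = scan.data
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return BoldScan(
        subject_id=scan.subject_id,
        condition=scan.condition,
        data=(X - mu) / sd,
        tr=scan.tr,
        block_labels=scan.block_labels,
    )


def concatenate_scans(
    scans: list[BoldScan], standardize: bool = True
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack scans into one frames x regions matrix with an invertible index.

    Returns ``(X, index)`` where ``index`` has one row per frame with columns
    ``subject_id``, ``condition``, ``frame`` (frame position within its scan),
    and ``block`` when present.
    """
    if not scans:
        raise ValidationError("no scans to concatenate")
    P = scans[0].n_regions
    for s in scans:
        if s.n_regions != P:
            raise ValidationError(
                f"region count mismatch: {s.subject_id}/{s.condition} has "
                f"{s.n_regions} regions, expected {P}"
            )
    prepared = [standardize_scan(s) if standardize else s for s in scans]
    X = np.vstack([s.data for s in prepared])
    index = pd.DataFrame(
        {
            "subject_id": np.concatenate(
                [np.full(s.n_frames, s.subject_id, dtype=object) for s in scans]
            ),
            "condition": np.concatenate(
                [np.full(s.n_frames, s.condition, dtype=object) for s in scans]
            ),
            "frame": np.concatenate([np.arange(s.n_frames) for s in scans]),
            "block": np.concatenate([s.block_labels for s in scans]),
        }
    )
    return X, index


def split_concatenated(
    X: np.ndarray, index: pd.DataFrame
) -> dict[tuple[str, str], np.ndarray]:
    """Invert :func:`concatenate_scans`: map (subject, condition) -> matrix."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for (sid, cond), grp in index.groupby(["subject_id", "condition"], sort=False):
        rows = grp.index.to_numpy()
        order = np.argsort(grp["frame"].to_numpy())
        out[(sid, cond)] = X[rows[order]]
    return out


# ---------------------------------------------------------------------------
# correlation-distance k-means
# ---------------------------------------------------------------------------

def _unit_rows(X: np.ndarray, what: str = "row") -> np.ndarray:
    """Center each row and scale to unit norm; constant rows are rejected."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValidationError(
            f"constant {what} {bad}: Pearson correlation distance is undefined"
        )
    return Xc / norms[:, None]


def _correlation_error(Xu: np.ndarray, Cu: np.ndarray, labels: np.ndarray) -> float:
    """Sum over frames of 1 - r(frame, assigned centroid)."""
    r = np.einsum("ij,ij->i", Xu, Cu[labels])
    return float(np.sum(1.0 - r))


def fit_kmeans(
    X: np.ndarray,
    k: int,
    n_reps: int = 20,
    max_iter: int = 200,
    seed: int | np.random.Generator = 0,
) -> ClusterModel:
    """k-means under correlation distance, best of ``n_reps`` restarts.

    Centroids in the returned model are the means of the (standardized input)
    frames assigned to each cluster; the final labelling is recomputed from
    those stored centroids so that :func:`assign_states` reproduces the fit.
    Empty clusters are re-seeded at the frame farthest from its centroid.
    """
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if X.shape[0] < k:
        raise ValidationError("fewer frames than clusters")
    rng = np.random.default_rng(seed)
    Xu = _unit_rows(X, "frame")
    n = X.shape[0]

    best_labels, best_err = None, np.inf
    for _ in range(n_reps):
        idx = rng.choice(n, size=k, replace=False)
        Cu = Xu[idx].copy()
        labels = np.full(n, -1)
        for _it in range(max_iter):
            sim = Xu @ Cu.T  # correlation; argmax == argmin of 1 - r
            new_labels = np.argmax(sim, axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = labels == c
                if not members.any():
                    # re-seed at the globally worst-fit frame
                    worst = int(np.argmin(np.max(sim, axis=1)))
                    Cu[c] = Xu[worst]
                    labels[worst] = c
                    continue
                m = Xu[members].mean(axis=0)
                m -= m.mean()
                nrm = np.linalg.norm(m)
                Cu[c] = m / nrm if nrm > 0 else Xu[int(np.flatnonzero(members)[0])]
        err = _correlation_error(Xu, Cu, labels)
        if err < best_err:
            best_err, best_labels = err, labels.copy()

    # stored centroids: mean of input frames per cluster, labels recomputed
    centroids = np.vstack([X[best_labels == c].mean(axis=0) for c in range(k)])
    Cu = _unit_rows(centroids, "centroid")
    labels = np.argmax(Xu @ Cu.T, axis=1)
    err = _correlation_error(Xu, Cu, labels)
    ve = variance_explained(X, labels + 1, centroids)
    return ClusterModel(
        k=k,
        centroids=centroids,
        variance_explained=ve,
        within_cluster_error=err,
    )


def variance_explained(
    X: np.ndarray, labels: np.ndarray, centroids: np.ndarray | None = None
) -> float:
    """Fraction of total Euclidean variance explained by the partition.

    Returns SSB / (SSB + SSW) where SSB is the between-cluster sum of squares
    about the grand mean and SSW the within-cluster sum of squares. With one
    cluster (centroid at the mean) this is 0; when every frame equals its
    centroid it is 1.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int) - 1
    k = labels.max() + 1
    if labels.min() < 0:
        raise ValidationError("labels must be 1-based")
    if centroids is None:
        centroids = np.vstack(
            [X[labels == c].mean(axis=0) if (labels == c).any() else X.mean(axis=0)
             for c in range(k)]
        )
    grand = X.mean(axis=0)
    ssb = ssw = 0.0
    for c in range(k):
        members = labels == c
        if not members.any():
            continue
        ssb += members.sum() * float(np.sum((centroids[c] - grand) ** 2))
        ssw += float(np.sum((X[members] - centroids[c]) ** 2))
    total = ssb + ssw
    return ssb / total if total > 0 else 0.0


def elbow_scan(
    X: np.ndarray,
    k_range: list[int] | range,
    n_reps: int = 20,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Variance explained and its first difference (gain) across k.

    The gain column reports the increase in variance explained for a unit
    increase in k; it is NaN for the first entry.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        model = fit_kmeans(X, k, n_reps=n_reps, seed=rng)
        rows.append({"k": k, "variance_explained": model.variance_explained})
    table = pd.DataFrame(rows)
    table["gain"] = table["variance_explained"].diff()
    return table


def assign_states(
    model: ClusterModel, scan: BoldScan, standardize: bool = True
) -> StateSequence:
    """Assign each frame of a scan to its nearest centroid (1 - Pearson r).

    Ties go to the lowest state index. Labels are 1-based.
    """
    if scan.n_regions != model.n_regions:
        raise ValidationError(
            f"scan has {scan.n_regions} regions, model expects {model.n_regions}"
        )
    data = standardize_scan(scan).data if standardize else scan.data
    Xu = _unit_rows(data, "frame")
    Cu = _unit_rows(model.centroids, "centroid")
    labels = np.argmax(Xu @ Cu.T, axis=1) + 1
    return StateSequence(
        labels=labels,
        k=model.k,
        tr=scan.tr,
        subject_id=scan.subject_id,
        condition=scan.condition,
        block_labels=scan.block_labels,
    )


# ---------------------------------------------------------------------------
# state naming
# ---------------------------------------------------------------------------

def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def name_states(
    centroids: np.ndarray, parc: RegionParcellation
) -> tuple[list[str], pd.DataFrame]:
    """Name each state after the system its dominant component aligns with.

    For centroid c, the positive component p = max(c, 0) and the magnitude of
    the negative component n = max(-c, 0) are each compared, by cosine
    similarity, with the binary indicator vector of every system. The name is
    the system achieving the maximum over all 2 x |systems| similarities,
    suffixed "+" if the positive component won and "-" otherwise. The full
    similarity table (state, system, component, cosine) is also returned.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[1] != parc.n_regions:
        raise ValidationError("centroid width must equal region count")
    names: list[str] = []
    rows = []
    for s in range(centroids.shape[0]):
        c = centroids[s]
        pos, neg = np.maximum(c, 0.0), np.maximum(-c, 0.0)
        best, best_sim = None, -np.inf
        for system in SYSTEMS:
            ind = parc.indicator(system)
            for comp, vec, suffix in (("pos", pos, "+"), ("neg", neg, "-")):
                sim = _cosine(vec, ind)
                rows.append(
                    {"state": s + 1, "system": system, "component": comp, "cosine": sim}
                )
                if sim > best_sim:
                    best_sim, best = sim, f"{system}{suffix}"
        names.append(best if best is not None else f"state{s + 1}")
    # disambiguate exact duplicates deterministically
    seen: dict[str, int] = {}
    for i, nm in enumerate(names):
        seen[nm] = seen.get(nm, 0) + 1
        if seen[nm] > 1:
            names[i] = f"{nm}({seen[nm]})"
    return names, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reliability and surrogates
# ---------------------------------------------------------------------------

def _greedy_align(C1: np.ndarray, C2: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedily pair rows of C1 with rows of C2 by maximal Pearson r."""
    k = C1.shape[0]
    r = np.corrcoef(C1, C2)[:k, k:]
    pairs = []
    used_i, used_j = set(), set()
    flat = sorted(
        ((r[i, j], i, j) for i in range(k) for j in range(k)), reverse=True
    )
    for val, i, j in flat:
        if i in used_i or j in used_j:
            continue
        pairs.append((i, j, float(val)))
        used_i.add(i)
        used_j.add(j)
        if len(pairs) == k:
            break
    return pairs


def split_half_reliability(
    scans: list[BoldScan],
    k: int,
    n_splits: int = 50,
    seed: int | np.random.Generator = 0,
    n_reps: int = 5,
) -> pd.DataFrame:
    """Between-half centroid agreement over random subject splits.

    For each split, subjects are divided into two halves, each half is
    clustered independently, states are aligned greedily by maximal centroid
    correlation, and the per-state aligned correlations are reported
    (columns: split, state_half1, state_half2, r).
    """
    subjects = sorted({s.subject_id for s in scans})
    if len(subjects) < 2:
        raise ValidationError("split-half reliability needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    rows = []
    for split in range(n_splits):
        perm = rng.permutation(len(subjects))
        half1 = {subjects[i] for i in perm[: len(subjects) // 2]}
        s1 = [s for s in scans if s.subject_id in half1]
        s2 = [s for s in scans if s.subject_id not in half1]
        X1, _ = concatenate_scans(s1)
        X2, _ = concatenate_scans(s2)
        m1 = fit_kmeans(X1, k, n_reps=n_reps, seed=rng)
        m2 = fit_kmeans(X2, k, n_reps=n_reps, seed=rng)
        for i, j, r in _greedy_align(m1.centroids, m2.centroids):
            rows.append(
                {"split": split, "state_half1": i + 1, "state_half2": j + 1, "r": r}
            )
    return pd.DataFrame(rows, columns=["split", "state_half1", "state_half2", "r"])


def autocorr_surrogate(scan: BoldScan, seed: int | np.random.Generator = 0) -> BoldScan:
    """Phase-randomized surrogate preserving each region's power spectrum.

    Random phases are drawn independently per region, so each region keeps
    its autocorrelation function exactly while cross-regional structure is
    destroyed. DC and (for even length) Nyquist bins keep zero phase so the
    surrogate stays real-valued.
    """
    if scan.n_frames < 4:
        raise ValidationError("phase randomization needs >= 4 frames")
    rng = np.random.default_rng(seed)
    X = scan.data
    n = X.shape[0]
    F = np.fft.rfft(X, axis=0)
    n_bins = F.shape[0]
    # interior bins exclude DC (0) and, for even n, the Nyquist bin (-1)
    hi = n_bins - 1 if n % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(hi - 1, X.shape[1]))
    F[1:hi] = np.abs(F[1:hi]) * np.exp(1j * phases)
    surrogate = np.fft.irfft(F, n=n, axis=0)
    return BoldScan(
        subject_id=scan.subject_id,
        condition=scan.condition,
        data=surrogate,
        tr=scan.tr,
        block_labels=scan.block_labels,
    )
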