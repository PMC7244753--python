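"""Synthetic cohorts with planted brain-state structure.

Every downstream stage of the pipeline (clustering, dynamics, control
energies, group statistics) is exercised against data generated here, where
the ground truth is known by construction: state sequences follow a
Markov-switching model that separates *persistence* (geometric run lengths
with a configurable mean dwell) from *transitions* (a diagonal-zero jump
matrix over the k states), exactly mirroring the persistence-excluded
transition statistic the analysis estimates. Regional BOLD is the active
state's centroid plus independent AR(1) noise per region, so the temporal
autocorrelation of the signal is controllable. Cohorts additionally carry
subject covariates (age, sex, handedness, intracranial volume, mean framewise
displacement, per-block d') with planted linear effects whose standardized
magnitudes are recorded in the returned ground truth.

The generator does not convolve with a hemodynamic response, add scanner
artefacts, or smooth spatially; it emulates the statistical structure the
analysis consumes, not raw fMRI physics.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .types import (
    SYSTEMS,
    BoldScan,
    RegionParcellation,
    StateSequence,
    ValidationError,
)


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its contract (e.g. connectivity)."""


# ---------------------------------------------------------------------------
# parcellation and connectome
# ---------------------------------------------------------------------------

def generate_parcellation(
    P: int,
    system_sizes: dict[str, int] | None = None,
    seed: int | np.random.Generator = 0,
) -> RegionParcellation:
    """Generate a random parcellation of ``P`` regions into the 7 systems.

    Coordinates are sampled uniformly in the unit cube. If ``system_sizes``
    is omitted, regions are divided as evenly as possible across systems.
    """
    rng = np.random.default_rng(seed)
    if P < len(SYSTEMS):
        raise ValidationError(f"P must be >= {len(SYSTEMS)}")
    if system_sizes is None:
        base, extra = divmod(P, len(SYSTEMS))
        system_sizes = {
            s: base + (1 if i < extra else 0) for i, s in enumerate(SYSTEMS)
        }
    if set(system_sizes) - set(SYSTEMS):
        raise ValidationError("system_sizes contains unknown systems")
    if sum(system_sizes.values()) != P:
        raise ValidationError("system sizes must sum to P")
    if any(v < 1 for v in system_sizes.values()):
        raise ValidationError("every system needs at least one region")
    systems = np.concatenate(
        [np.full(system_sizes.get(s, 0), s, dtype=object) for s in SYSTEMS]
    )
    coords = rng.uniform(0.0, 1.0, size=(P, 3))
    return RegionParcellation(systems=systems, coords=coords)


def generate_connectome(
    parc: RegionParcellation,
    decay: float = 0.5,
    density: float = 0.3,
    seed: int | np.random.Generator = 0,
    max_retries: int = 50,
) -> "StructuralNetwork":
    """Generate a distance-dependent weighted connectome on a parcellation.

    Edge existence probability and edge weight both decay exponentially with
    Euclidean distance (length scale ``decay``), emulating the strong
    weight-length relationship of tractography-derived networks. The returned
    network is symmetric, nonnegative, zero-diagonal, and connected; sparse
    draws are retried until connected.
    """
    from .types import StructuralNetwork  # local import avoids cycle at typing

    if decay <= 0:
        raise ValidationError("decay must be positive")
    if not 0 < density <= 1:
        raise ValidationError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    P = parc.n_regions
    d = np.linalg.norm(parc.coords[:, None, :] - parc.coords[None, :, :], axis=2)
    iu, ju = np.triu_indices(P, k=1)
    affinity = np.exp(-d[iu, ju] / decay)

    for _ in range(max_retries):
        if density >= 1.0:
            keep = np.ones(iu.size, dtype=bool)
        else:
            n_edges = max(P - 1, int(round(density * iu.size)))
            # distance-biased sampling without replacement
            gumbel = rng.gumbel(size=iu.size)
            score = np.log(affinity + 1e-12) + gumbel
            keep = np.zeros(iu.size, dtype=bool)
            keep[np.argsort(score)[-n_edges:]] = True
        w = np.zeros(iu.size)
        w[keep] = np.exp(-d[iu, ju][keep] / decay) * rng.uniform(0.5, 1.5, keep.sum())
        A = np.zeros((P, P))
        A[iu, ju] = w
        A = A + A.T
        if _is_connected(A):
            return StructuralNetwork(adjacency=A, coords=parc.coords.copy())
    raise GenerationError(
        f"could not draw a connected network in {max_retries} tries "
        f"(P={P}, density={density}, decay={decay})"
    )


def _is_connected(A: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components((A > 0).astype(int), directed=False)
    return n == 1


# ---------------------------------------------------------------------------
# state sequences and BOLD
# ---------------------------------------------------------------------------

def _check_jump_matrix(tp: np.ndarray) -> np.ndarray:
    tp = np.asarray(tp, dtype=float)
    if tp.ndim != 2 or tp.shape[0] != tp.shape[1]:
        raise ValidationError("jump matrix must be square")
    if np.any(np.abs(np.diag(tp)) > 1e-12):
        raise ValidationError("jump matrix diagonal must be zero")
    if np.any(tp < -1e-12):
        raise ValidationError("jump matrix must be nonnegative")
    if not np.allclose(tp.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("jump matrix rows must sum to 1")
    return tp


def generate_state_sequence(
    tp: np.ndarray,
    dwell: float,
    n_frames: int,
    seed: int | np.random.Generator = 0,
    tr: float = 3.0,
    initial_state: int | None = None,
    dwell_per_state: np.ndarray | None = None,
    **seq_meta,
) -> StateSequence:
    """Simulate a Markov-switching state sequence.

    Run lengths are geometric with mean ``dwell`` frames (optionally per-state
    via ``dwell_per_state``); on each run end, the next state is drawn from
    the diagonal-zero jump matrix ``tp``. The final run is truncated at
    ``n_frames``.
    """
    tp = _check_jump_matrix(tp)
    k = tp.shape[0]
    if dwell < 1:
        raise ValidationError("mean dwell must be >= 1 frame")
    if n_frames < 1:
        raise ValidationError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    dw = (
        np.full(k, float(dwell))
        if dwell_per_state is None
        else np.asarray(dwell_per_state, dtype=float)
    )
    if np.any(dw < 1):
        raise ValidationError("per-state dwell must be >= 1 frame")

    # worst case every run has length 1
    max_runs = n_frames + 1
    cums = [list(np.cumsum(row)) for row in tp]
    states = np.empty(max_runs, dtype=int)
    s = int(rng.integers(k)) if initial_state is None else int(initial_state) - 1
    u = rng.random(max_runs)
    n_runs = 0
    total = 0
    # jump-chain loop; run lengths drawn vectorized afterwards would change
    # the total, so lengths are drawn per run from the same generator
    lengths = np.empty(max_runs, dtype=int)
    geo_u = rng.random(max_runs)
    while total < n_frames and n_runs < max_runs:
        states[n_runs] = s
        p = 1.0 / dw[s]
        # inverse-cdf geometric draw with support {1, 2, ...}
        L = int(np.ceil(np.log1p(-geo_u[n_runs]) / np.log1p(-p))) if p < 1 else 1
        lengths[n_runs] = max(L, 1)
        total += lengths[n_runs]
        s = bisect_left(cums[s], u[n_runs])
        n_runs += 1
    labels = np.repeat(states[:n_runs] + 1, lengths[:n_runs])[:n_frames]
    return StateSequence(labels=labels, k=k, tr=tr, **seq_meta)


def generate_bold_from_sequence(
    seq: StateSequence,
    centroids: np.ndarray,
    noise_sd: float,
    ar_coef: float = 0.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
    condition: str = "rest",
    tr: float | None = None,
) -> BoldScan:
    """Render a state sequence into a frames x regions BOLD matrix.

    Frame ``t`` equals the centroid of its state plus stationary AR(1) noise
    (coefficient ``ar_coef``, innovation sd ``noise_sd``), independent across
    regions. ``noise_sd == 0`` reproduces the centroids exactly.
    """
    centroids = np.asarray(centroids, dtype=float)
    if not np.all(np.isfinite(centroids)):
        raise ValidationError("centroids must be finite")
    if centroids.shape[0] < seq.k:
        raise ValidationError("centroid count must cover all states")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not 0 <= ar_coef < 1:
        raise ValidationError("ar_coef must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n, P = seq.n_frames, centroids.shape[1]
    data = centroids[seq.labels - 1].copy()
    if noise_sd > 0:
        innov = rng.normal(0.0, noise_sd, size=(n, P))
        if ar_coef > 0:
            stat_sd = noise_sd / np.sqrt(1.0 - ar_coef**2)
            x0 = rng.normal(0.0, stat_sd, size=P)
            zi = (ar_coef * x0)[None, :]
            noise, _ = _signal.lfilter([1.0], [1.0, -ar_coef], innov, axis=0, zi=zi)
        else:
            noise = innov
        data += noise
    return BoldScan(
        subject_id=subject_id,
        condition=condition,
        data=data,
        tr=seq.tr if tr is None else tr,
        block_labels=seq.block_labels,
    )


# ---------------------------------------------------------------------------
# planted centroids
# ---------------------------------------------------------------------------

#: default planted states, mirroring commonly reported coactivation patterns:
#: high/low default-mode, high frontoparietal, high/low visual.
DEFAULT_STATE_SPEC = (
    ("DMN", +1),
    ("DMN", -1),
    ("FPN", +1),
    ("VIS", +1),
    ("VIS", -1),
)

#: each planted state co-deactivates an "anticorrelated" partner system
_ANTI = {"DMN": "DAT", "FPN": "VAT", "VIS": "SOM"}


def planted_centroids(
    parc: RegionParcellation,
    state_spec: tuple[tuple[str, int], ...] = DEFAULT_STATE_SPEC,
    anti_weight: float = 0.4,
) -> np.ndarray:
    """Build k planted centroids from (system, sign) specifications.

    State (S, +1) has amplitude +1 on the regions of S and about
    ``-anti_weight`` on the regions of S's anticorrelated partner system;
    (S, -1) is its negation. Partner-system amplitudes ramp across the
    partner's regions (mean ``anti_weight``), so the dominant component of
    each planted state aligns strictly better with its system than the
    partner component does with its own (cosine 1 vs < 1), making the
    planted state names unambiguous.
    """
    rows = []
    for system, sign in state_spec:
        c = parc.indicator(system).astype(float)
        partner = _ANTI.get(system)
        if partner is not None:
            ind = parc.indicator(partner)
            idx = np.flatnonzero(ind)
            ramp = np.linspace(0.6, 1.4, idx.size)
            c[idx] -= anti_weight * ramp
        rows.append(sign * c)
    return np.array(rows)


def uniform_jump_matrix(k: int) -> np.ndarray:
    """Jump matrix with uniform probability over the other k-1 states."""
    tp = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(tp, 0.0)
    return tp


def tilted_jump_matrix(k: int, bias: dict[tuple[int, int], float]) -> np.ndarray:
    """Uniform jump matrix with additive biases on chosen (i, j) elements.

    States are 1-based. Each biased row is renormalized over its off-diagonal
    entries; results must stay within [0, 1].
    """
    tp = uniform_jump_matrix(k)
    for (i, j), delta in bias.items():
        if i == j:
            raise ValidationError("cannot bias a diagonal element")
        tp[i - 1, j - 1] += delta
    if np.any(tp < 0):
        raise ValidationError("bias drives a probability below 0")
    tp = tp / tp.sum(axis=1, keepdims=True)
    np.fill_diagonal(tp, 0.0)
    return tp


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; nothing is hard-coded downstream.

    Defaults emulate the study design at reduced scale: per subject one rest
    scan (120 frames) and one n-back task scan (225 frames in nine 25-frame
    blocks cycling 0-back / 1-back / 2-back), TR = 3 s, 50 regions, five
    planted states with mean dwell 3 frames.
    """

    n_subjects: int = 40
    n_regions: int = 50
    n_rest_frames: int = 120
    n_task_frames: int = 225
    tr: float = 3.0
    block_len: int = 25
    state_spec: tuple[tuple[str, int], ...] = DEFAULT_STATE_SPEC
    dwell: float = 3.0
    noise_sd: float = 0.5
    ar_coef: float = 0.3
    rest_tp: np.ndarray | None = None  # default: uniform jumps
    task_tp: np.ndarray | None = None  # default: tilted toward FPN+ state
    # planted covariate effects -------------------------------------------
    #: standardized effect of age on the subject-level dwell parameter, per
    #: 1-based state index (rest scans)
    age_dwell_effects: dict[int, float] = field(default_factory=dict)
    #: between-subject sd (frames) of the dwell parameter for affected states
    dwell_subject_sd: float = 1.5
    #: planted effects of subject jump-probability traits on block d':
    #: (block, i, j) -> standardized beta
    tp_dprime_effects: dict[tuple[str, int, int], float] = field(default_factory=dict)
    #: between-subject sd of the perturbed jump elements
    tp_subject_sd: float = 0.05
    generate_bold: bool = True

    @property
    def k(self) -> int:
        return len(self.state_spec)

    def __post_init__(self) -> None:
        if self.n_task_frames % self.block_len != 0:
            raise ValidationError(
                "n_task_frames must be a whole number of blocks "
                f"({self.n_task_frames} % {self.block_len} != 0)"
            )


@dataclass
class GroundTruth:
    """Planted parameters of a generated cohort."""

    planted_centroids: np.ndarray
    rest_tp: np.ndarray
    task_tp: np.ndarray
    dwell: float
    noise_sd: float
    ar_coef: float
    subject_dwell: np.ndarray  # (n_subjects, k) planted rest dwell (frames)
    subject_task_tp: np.ndarray  # (n_subjects, k, k)
    effect_sizes: dict
    sequences: dict  # (subject, condition) -> planted label array


@dataclass
class Cohort:
    scans: list[BoldScan]
    sequences: list[StateSequence]
    covariates: "object"  # pandas.DataFrame
    parcellation: RegionParcellation
    truth: GroundTruth


def _task_blocks(n_task_frames: int, block_len: int) -> np.ndarray:
    order = ["0back", "1back", "2back"]
    n_blocks = n_task_frames // block_len
    labels = [order[b % 3] for b in range(n_blocks)]
    return np.repeat(np.array(labels, dtype=object), block_len)


def generate_cohort(config: CohortConfig, seed: int | np.random.Generator = 0) -> Cohort:
    """Generate a full synthetic cohort with planted ground truth.

    Returns scans (unless ``config.generate_bold`` is off), the planted state
    sequences, a covariate table, the parcellation, and a
    :class:`GroundTruth` recording every planted parameter.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    k = config.k
    parc = generate_parcellation(config.n_regions, seed=rng)
    centroids = planted_centroids(parc, config.state_spec)
    rest_tp = (
        uniform_jump_matrix(k) if config.rest_tp is None else _check_jump_matrix(config.rest_tp)
    )
    task_tp = (
        tilted_jump_matrix(k, {(1, 3): 0.1, (5, 3): 0.1})
        if config.task_tp is None
        else _check_jump_matrix(config.task_tp)
    )

    n = config.n_subjects
    age = rng.uniform(8.0, 22.0, size=n)
    z_age = (age - age.mean()) / age.std()
    sex = rng.integers(0, 2, size=n)
    handedness = np.clip(rng.normal(0.7, 0.3, size=n), -1.0, 1.0)
    volume = rng.normal(1.4e6, 1.2e5, size=n)
    mean_fd = rng.gamma(3.0, 0.03, size=n)

    # planted subject-level dwell parameters (rest)
    subject_dwell = np.full((n, k), float(config.dwell))
    for state, beta in config.age_dwell_effects.items():
        if not 1 <= state <= k:
            raise ValidationError(f"age effect on unknown state {state}")
        eps = rng.normal(size=n)
        shift = config.dwell_subject_sd * (beta * z_age + np.sqrt(1 - beta**2) * eps)
        subject_dwell[:, state - 1] = np.maximum(config.dwell + shift, 1.0)

    # planted subject-level task jump matrices and d' traits
    subject_task_tp = np.repeat(task_tp[None], n, axis=0)
    traits: dict[tuple[str, int, int], np.ndarray] = {}
    for (block, i, j), _beta in config.tp_dprime_effects.items():
        w = rng.normal(size=n)
        traits[(block, i, j)] = w
        pert = config.tp_subject_sd * w
        row = subject_task_tp[:, i - 1, :]
        row[:, j - 1] = np.clip(row[:, j - 1] + pert, 1e-3, None)
        row /= row.sum(axis=1, keepdims=True)
        subject_task_tp[:, i - 1, :] = row

    dprime_base = {"0back": 3.5, "1back": 3.0, "2back": 2.0}
    dprime = {}
    for block, base in dprime_base.items():
        effect = np.zeros(n)
        total_b2 = 0.0
        for (b, i, j), beta in config.tp_dprime_effects.items():
            if b == block:
                effect += beta * traits[(b, i, j)]
                total_b2 += beta**2
        resid_sd = np.sqrt(max(1.0 - total_b2, 1e-6))
        dprime[block] = base + effect + resid_sd * rng.normal(size=n)

    block_labels = _task_blocks(config.n_task_frames, config.block_len)
    n_blocks = config.n_task_frames // config.block_len

    scans: list[BoldScan] = []
    sequences: list[StateSequence] = []
    planted_seqs: dict[tuple[str, str], np.ndarray] = {}
    for s in range(n):
        sid = f"sub-{s:04d}"
        rest_seq = generate_state_sequence(
            rest_tp,
            config.dwell,
            config.n_rest_frames,
            seed=rng,
            tr=config.tr,
            dwell_per_state=subject_dwell[s],
            subject_id=sid,
            condition="rest",
        )
        # task scan: per-block chains so block boundaries break runs honestly
        task_labels = []
        for b in range(n_blocks):
            bl = generate_state_sequence(
                subject_task_tp[s],
                config.dwell,
                config.block_len,
                seed=rng,
                tr=config.tr,
            ).labels
            task_labels.append(bl)
        task_seq = StateSequence(
            labels=np.concatenate(task_labels),
            k=k,
            tr=config.tr,
            subject_id=sid,
            condition="nback",
            block_labels=block_labels,
        )
        sequences.extend([rest_seq, task_seq])
        planted_seqs[(sid, "rest")] = rest_seq.labels
        planted_seqs[(sid, "nback")] = task_seq.labels
        if config.generate_bold:
            scans.append(
                generate_bold_from_sequence(
                    rest_seq, centroids, config.noise_sd, config.ar_coef,
                    seed=rng, subject_id=sid, condition="rest",
                )
            )
            scans.append(
                generate_bold_from_sequence(
                    task_seq, centroids, config.noise_sd, config.ar_coef,
                    seed=rng, subject_id=sid, condition="nback",
                )
            )

    covariates = pd.DataFrame(
        {
            "subject_id": [f"sub-{s:04d}" for s in range(n)],
            "age": age,
            "sex": sex,
            "handedness": handedness,
            "volume": volume,
            "mean_fd": mean_fd,
            "dprime_0back": dprime["0back"],
            "dprime_1back": dprime["1back"],
            "dprime_2back": dprime["2back"],
            "dprime_overall": (dprime["0back"] + dprime["1back"] + dprime["2back"]) / 3,
        }
    )
    truth = GroundTruth(
        planted_centroids=centroids,
        rest_tp=rest_tp,
        task_tp=task_tp,
        dwell=config.dwell,
        noise_sd=config.noise_sd,
        ar_coef=config.ar_coef,
        subject_dwell=subject_dwell,
        subject_task_tp=subject_task_tp,
        effect_sizes={
            "age_dwell": dict(config.age_dwell_effects),
            "tp_dprime": {f"{b}:{i}->{j}": v for (b, i, j), v in config.tp_dprime_effects.items()},
        },
        sequences=planted_seqs,
    )
    return Cohort(
        scans=scans,
        sequences=sequences,
        covariates=covariates,
        parcellation=parc,
        truth=truth,
    )
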