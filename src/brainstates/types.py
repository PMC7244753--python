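"""Core domain containers shared across the pipeline.

The package operates on parcellated fMRI data: each scan is a frames x regions
matrix of regional BOLD amplitude, each region belongs to one of seven
canonical resting-state systems, and a weighted symmetric structural network
(the connectome) links the regions. Brain "states" are k-means centroids in
regional activation space; each frame is assigned to exactly one state,
producing a per-scan integer state sequence from which all temporal dynamics
are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical seven resting-state systems used for state naming.
SYSTEMS = ("VIS", "SOM", "DAT", "VAT", "LIM", "FPN", "DMN")

#: Block labels used inside n-back task scans ("none" marks rest frames).
BLOCKS = ("none", "0back", "1back", "2back")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class RegionParcellation:
    """Assignment of P regions to named systems, with spatial coordinates.

    Parameters
    ----------
    systems : (P,) array of str
        System label per region; every label must be one of :data:`SYSTEMS`.
    coords : (P, 3) array of float
        Region centroid coordinates in arbitrary spatial units.
    """

    systems: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.systems = np.asarray(self.systems, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be a (P, 3) array")
        if self.systems.shape[0] != self.coords.shape[0]:
            raise ValidationError("systems and coords must agree on P")
        unknown = set(self.systems) - set(SYSTEMS)
        if unknown:
            raise ValidationError(f"unknown system labels: {sorted(unknown)}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")

    @property
    def n_regions(self) -> int:
        return self.systems.shape[0]

    def indicator(self, system: str) -> np.ndarray:
        """Binary (P,) indicator vector of a system's regions."""
        if system not in SYSTEMS:
            raise ValidationError(f"unknown system {system!r}")
        return (self.systems == system).astype(float)

    def system_counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.systems == s)) for s in SYSTEMS}


@dataclass
class BoldScan:
    """One subject-scan: frames x regions BOLD amplitude plus metadata.

    ``data`` is expected in standardized (z-scored within region) units once a
    scan enters clustering; raw simulated output may be unstandardized.
    """

    subject_id: str
    condition: str  # "rest" or "nback"
    data: np.ndarray  # (frames, P)
    tr: float  # seconds
    block_labels: np.ndarray | None = None  # (frames,) of str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("scan data must be 2-D (frames x regions)")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("scan data contains non-finite values")
        if self.condition not in ("rest", "nback"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if self.block_labels is None:
            self.block_labels = np.full(self.data.shape[0], "none", dtype=object)
        else:
            self.block_labels = np.asarray(self.block_labels, dtype=object)
        if self.block_labels.shape[0] != self.data.shape[0]:
            raise ValidationError("block_labels length must equal frame count")
        unknown = set(self.block_labels) - set(BLOCKS)
        if unknown:
            raise ValidationError(f"unknown block labels: {sorted(unknown)}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class StateSequence:
    """Per-frame integer state labels (1..k) for one scan."""

    labels: np.ndarray  # (frames,) int in 1..k
    k: int
    tr: float
    subject_id: str = ""
    condition: str = "rest"
    block_labels: np.ndarray | None = None
    #: id of the contiguous-in-time segment each frame belongs to; a change
    #: of segment terminates runs and transitions (used after block
    #: restriction, where retained frames may not be temporally adjacent)
    segment_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("labels must be a nonempty 1-D array")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValidationError("labels must lie in 1..k")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if self.block_labels is not None:
            self.block_labels = np.asarray(self.block_labels, dtype=object)
            if self.block_labels.shape[0] != self.labels.shape[0]:
                raise ValidationError("block_labels length must equal n_frames")
        if self.segment_ids is not None:
            self.segment_ids = np.asarray(self.segment_ids, dtype=int)
            if self.segment_ids.shape[0] != self.labels.shape[0]:
                raise ValidationError("segment_ids length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


@dataclass
class ClusterModel:
    """A fitted k-means model of brain states under correlation distance."""

    k: int
    centroids: np.ndarray  # (k, P)
    variance_explained: float
    within_cluster_error: float
    distance: str = "one-minus-pearson"
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValidationError("centroid count must equal k")
        if not np.all(np.isfinite(self.centroids)):
            raise ValidationError("centroids must be finite")
        if np.any(np.ptp(self.centroids, axis=1) == 0):
            raise ValidationError("constant centroid row (correlation undefined)")

    @property
    def n_regions(self) -> int:
        return self.centroids.shape[1]


@dataclass
class StructuralNetwork:
    """Weighted symmetric structural adjacency with region coordinates."""

    adjacency: np.ndarray  # (P, P), nonnegative, zero diagonal
    coords: np.ndarray  # (P, 3)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(a < 0):
            raise ValidationError("adjacency must be nonnegative")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        if self.coords.shape != (a.shape[0], 3):
            raise ValidationError("coords must be (P, 3)")

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    def edge_list(self) -> np.ndarray:
        """Upper-triangular (i, j) index pairs of nonzero edges."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        mask = self.adjacency[iu, ju] > 0
        return np.column_stack([iu[mask], ju[mask]])


@dataclass
class ControlSystem:
    """Stabilized linear system x' = A_sys x + B u with control horizon T."""

    A_sys: np.ndarray  # (P, P), all eigenvalues with negative real part
    B: np.ndarray  # (P, P) diagonal input matrix
    T: float  # horizon, unitless model time

    def __post_init__(self) -> None:
        self.A_sys = np.asarray(self.A_sys, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A_sys.shape != self.B.shape:
            raise ValidationError("A_sys and B must have matching shape")
        if self.T <= 0:
            raise ValidationError("control horizon T must be positive")

    @property
    def n_regions(self) -> int:
        return self.A_sys.shape[0]


@dataclass
class TransitionMatrix:
    """Persistence-excluded transition probabilities and counts.

    ``probs[i-1, j-1]`` is the probability that state j is the next *new*
    state after state i (diagonal identically zero). Rows with no observed
    outgoing transition are undefined and stored as NaN.
    """

    probs: np.ndarray  # (k, k), diag 0, NaN rows where undefined
    counts: np.ndarray  # (k, k) int
    k: int
    scope: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.probs.shape != (self.k, self.k):
            raise ValidationError("probs must be (k, k)")
        if self.counts.shape != (self.k, self.k):
            raise ValidationError("counts must be (k, k)")

    def defined_rows(self) -> np.ndarray:
        return ~np.isnan(self.probs).any(axis=1)


@dataclass
class EnergyMatrix:
    """k x k minimum control energies; diagonal is persistence energy."""

    energies: np.ndarray  # (k, k), nonnegative
    k: int
    T: float = 1.0
    mode: str = "uniform"

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (self.k, self.k):
            raise ValidationError("energies must be (k, k)")
        if np.any(self.energies < 0):
            raise ValidationError("energies must be nonnegative")
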