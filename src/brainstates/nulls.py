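"""Network and state-vector null models for control-energy comparisons.

Two network nulls randomize the structural connectome at different levels of
stringency: the degree-preserving (DP) null rewires the binary topology by
double-edge swaps and permutes the original weight multiset onto the new
edges, preserving only the degree sequence and the weight distribution; the
strength-length-preserving (SLP) null constrains swaps to Euclidean-length
bins and reassigns weights to new edges by length rank, additionally
preserving the edge-length distribution and the weight-length relationship.
A third null randomizes the *states* rather than the network: null state
vectors are Gaussian draws with the empirical regional covariance, rescaled
to the real centroid's norm. Preservation contracts are asserted on every
generated member, not assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import spearmanr

from .types import EnergyMatrix, StructuralNetwork, ValidationError

__all__ = [
    "NullEnsemble",
    "degree_preserving_null",
    "strength_length_preserving_null",
    "spatial_covariance_null_states",
    "null_comparison_pvalues",
    "check_degree_preserving",
    "check_strength_length",
]


class NullModelError(RuntimeError):
    """Raised when a null network cannot satisfy its preservation contract."""


@dataclass
class NullEnsemble:
    """A set of null networks or null state vectors of one kind."""

    kind: str  # degree_preserving | strength_length_preserving | null_states
    members: list = field(default_factory=list)
    seed: int | None = None
    preserved_properties: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# contract checks
# ---------------------------------------------------------------------------

def _degrees(A: np.ndarray) -> np.ndarray:
    return (A > 0).sum(axis=0)


def _edge_weights(A: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(A.shape[0], k=1)
    w = A[iu, ju]
    return np.sort(w[w > 0])


def check_degree_preserving(
    original: StructuralNetwork, null: StructuralNetwork
) -> dict[str, bool]:
    """Verify the DP contract: identical degree sequence and weight multiset."""
    return {
        "degree_sequence": bool(
            np.array_equal(_degrees(original.adjacency), _degrees(null.adjacency))
        ),
        "weight_multiset": bool(
            np.allclose(_edge_weights(original.adjacency), _edge_weights(null.adjacency))
        ),
    }


def _edge_lengths(net: StructuralNetwork) -> np.ndarray:
    edges = net.edge_list()
    return np.linalg.norm(net.coords[edges[:, 0]] - net.coords[edges[:, 1]], axis=1)


def check_strength_length(
    original: StructuralNetwork,
    null: StructuralNetwork,
    n_bins: int = 10,
    rho_tol: float = 0.05,
) -> dict[str, bool]:
    """Verify the SLP contract: DP contract + length histogram + weight-length rho."""
    out = check_degree_preserving(original, null)
    lo, ln = _edge_lengths(original), _edge_lengths(null)
    bins = np.quantile(lo, np.linspace(0, 1, n_bins + 1))
    bins[0], bins[-1] = -np.inf, np.inf
    ho = np.histogram(lo, bins=bins)[0]
    hn = np.histogram(ln, bins=bins)[0]
    out["length_histogram"] = bool(np.array_equal(ho, hn))
    wo = original.adjacency[tuple(original.edge_list().T)]
    wn = null.adjacency[tuple(null.edge_list().T)]
    rho_o = spearmanr(wo, lo).statistic
    rho_n = spearmanr(wn, ln).statistic
    out["weight_length_relationship"] = bool(abs(rho_o - rho_n) <= rho_tol)
    return out


# ---------------------------------------------------------------------------
# degree-preserving null
# ---------------------------------------------------------------------------

def degree_preserving_null(
    net: StructuralNetwork,
    n_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
    max_tries_factor: int = 100,
) -> StructuralNetwork:
    """Rewire binary topology by double-edge swaps; permute weights onto edges.

    ``n_swaps`` defaults to 10x the edge count. The degree sequence and the
    multiset of edge weights are preserved exactly (asserted before return).
    """
    rng = np.random.default_rng(seed)
    edges = net.edge_list()
    if edges.shape[0] < 2:
        raise ValidationError("need at least two edges to rewire")
    m = edges.shape[0]
    if n_swaps is None:
        n_swaps = 10 * m
    G = nx.Graph()
    G.add_nodes_from(range(net.n_regions))
    G.add_edges_from(map(tuple, edges))
    nx.double_edge_swap(
        G,
        nswap=n_swaps,
        max_tries=max_tries_factor * n_swaps,
        seed=int(rng.integers(2**31 - 1)),
    )
    new_edges = np.array(sorted(tuple(sorted(e)) for e in G.edges()))
    weights = net.adjacency[edges[:, 0], edges[:, 1]]
    perm = rng.permutation(m)
    A = np.zeros_like(net.adjacency)
    A[new_edges[:, 0], new_edges[:, 1]] = weights[perm]
    A = A + A.T
    null = StructuralNetwork(adjacency=A, coords=net.coords.copy())
    contract = check_degree_preserving(net, null)
    if not all(contract.values()):
        raise NullModelError(f"degree-preserving contract violated: {contract}")
    return null


# ---------------------------------------------------------------------------
# strength-length-preserving null
# ---------------------------------------------------------------------------

def strength_length_preserving_null(
    net: StructuralNetwork,
    n_bins: int = 10,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: int = 10,
) -> StructuralNetwork:
    """Length-binned rewiring with length-rank weight reassignment.

    Double-edge swaps are accepted only when both replacement edges fall in
    the same Euclidean-length bin as the edges they replace, preserving the
    degree sequence exactly and the binned length histogram by construction.
    Original weights are then reassigned to the new edge set by length rank
    (shortest new edge gets the weight of the shortest original edge), which
    preserves the weight multiset exactly and the weight-length relationship
    to close approximation.
    """
    rng = np.random.default_rng(seed)
    coords = net.coords
    edges = [tuple(e) for e in net.edge_list()]
    if len(edges) < 2:
        raise ValidationError("need at least two edges to rewire")

    def length(e: tuple[int, int]) -> float:
        return float(np.linalg.norm(coords[e[0]] - coords[e[1]]))

    lengths = np.array([length(e) for e in edges])
    qs = np.quantile(lengths, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf

    def bin_of(ell: float) -> int:
        return int(np.clip(np.searchsorted(qs, ell, side="right") - 1, 0, n_bins - 1))

    edge_set = set(edges)
    by_bin: dict[int, list[tuple[int, int]]] = {b: [] for b in range(n_bins)}
    for e, ell in zip(edges, lengths):
        by_bin[bin_of(ell)].append(e)

    n_attempts = swaps_per_edge * len(edges)
    for b in range(n_bins):
        pool = by_bin[b]
        if len(pool) < 2:
            continue  # sparse bin: nothing to swap, topology kept as-is
        for _ in range(n_attempts // n_bins):
            i1, i2 = rng.integers(len(pool)), rng.integers(len(pool))
            if i1 == i2:
                continue
            (a, bnode), (c, d) = pool[i1], pool[i2]
            if rng.random() < 0.5:
                c, d = d, c
            # proposed replacements (a, d) and (c, bnode)
            if a == d or c == bnode:
                continue
            e1 = tuple(sorted((a, d)))
            e2 = tuple(sorted((c, bnode)))
            if e1 in edge_set or e2 in edge_set:
                continue
            if bin_of(length(e1)) != b or bin_of(length(e2)) != b:
                continue
            edge_set.discard(pool[i1])
            edge_set.discard(pool[i2])
            edge_set.add(e1)
            edge_set.add(e2)
            pool[i1], pool[i2] = e1, e2

    new_edges = sorted(edge_set)
    new_lengths = np.array([length(e) for e in new_edges])
    weights = np.array([net.adjacency[e] for e in edges])
    # length-rank matching: i-th shortest new edge <- i-th smallest original weight-by-length
    order_orig = np.argsort(lengths, kind="stable")
    order_new = np.argsort(new_lengths, kind="stable")
    A = np.zeros_like(net.adjacency)
    for rank, idx in enumerate(order_new):
        e = new_edges[idx]
        A[e[0], e[1]] = weights[order_orig[rank]]
    A = A + A.T
    null = StructuralNetwork(adjacency=A, coords=coords.copy())
    contract = check_strength_length(net, null, n_bins=n_bins)
    if not all(contract.values()):
        raise NullModelError(f"strength-length contract violated: {contract}")
    return null


# ---------------------------------------------------------------------------
# null states and energy comparison
# ---------------------------------------------------------------------------

def spatial_covariance_null_states(
    centroid: np.ndarray,
    Sigma: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null state vectors with a given regional covariance and matched norm.

    Draws n zero-mean Gaussian vectors with covariance ``Sigma`` (estimated
    from the concatenated BOLD matrix) and rescales each to the Euclidean
    norm of the real centroid. Slightly indefinite covariance estimates are
    repaired by clipping negative eigenvalues to zero (with a warning).
    """
    rng = np.random.default_rng(seed)
    centroid = np.asarray(centroid, float)
    Sigma = np.asarray(Sigma, float)
    P = centroid.shape[0]
    if Sigma.shape != (P, P):
        raise ValidationError("Sigma must be (P, P)")
    evals, evecs = np.linalg.eigh(0.5 * (Sigma + Sigma.T))
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        warnings.warn(
            f"covariance not PSD (min eigenvalue {evals.min():.3e}); "
            "clipping negative eigenvalues",
            stacklevel=2,
        )
    evals = np.clip(evals, 0.0, None)
    L = evecs * np.sqrt(evals)
    draws = rng.standard_normal((n, P)) @ L.T
    norms = np.linalg.norm(draws, axis=1)
    norms[norms == 0] = 1.0
    target = np.linalg.norm(centroid)
    return draws * (target / norms)[:, None]


def null_comparison_pvalues(
    real_E: EnergyMatrix | np.ndarray, null_Es: list[EnergyMatrix | np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided p-values that the real energy is *lower* than the null.

    For each matrix entry, p = (1 + #{null <= real}) / (1 + n_null); small p
    means the real network achieves the transition with less energy than
    nearly all nulls. Bonferroni correction is applied over all k^2 entries.
    Returns (p, p_corrected).
    """
    if not null_Es:
        raise ValidationError("empty null ensemble")
    R = real_E.energies if isinstance(real_E, EnergyMatrix) else np.asarray(real_E, float)
    stack = np.stack(
        [e.energies if isinstance(e, EnergyMatrix) else np.asarray(e, float) for e in null_Es]
    )
    n_null = stack.shape[0]
    n_le = (stack <= R[None]).sum(axis=0)
    p = (1.0 + n_le) / (1.0 + n_null)
    p_corr = np.minimum(p * R.size, 1.0)
    return p, p_corr
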