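"""Weighted clustering coefficient, Dijkstra path length, and surrogate
normalization of both.

Clustering of node i is the weighted triangle ratio

    C_i = sum_{k != l, both != i} w_ik w_il w_kl / sum_{k != l, both != i} w_ik w_il

which reduces to the unweighted (Watts-Strogatz) clustering coefficient for
0/1 weights.  Path length uses reciprocal weights as edge lengths
(l_ij = 1 / w_ij: strong coupling = short functional distance) with
shortest paths by Dijkstra; L_i is the mean distance from i to the other
N - 1 nodes.  Both are normalized by their means over an ensemble of
surrogate networks in which the off-diagonal weights are randomly permuted
(weight distribution preserved, topology destroyed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .connectivity import ConnectivityMatrix, validate_weights

__all__ = [
    "ClassicalMeasures",
    "weighted_clustering",
    "weighted_path_length",
    "surrogate_networks",
    "normalize_metrics",
]

#: Surrogate count sufficient for < 1% batch-to-batch variability of the
#: ensemble means on 17-node matrices.
DEFAULT_N_SURROGATES = 50


@dataclass
class ClassicalMeasures:
    """Observed and surrogate-normalized clustering and path length."""

    clustering_per_node: np.ndarray
    path_length_per_node: np.ndarray
    clustering: float
    path_length: float
    clustering_norm: float
    path_length_norm: float
    n_surrogates: int
    surrogate_seed: int


def _as_weights(w: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(w, ConnectivityMatrix):
        return w.weights
    w = np.asarray(w, dtype=float)
    validate_weights(w)
    return w


def weighted_clustering(w: ConnectivityMatrix | np.ndarray
                        ) -> tuple[np.ndarray, float]:
    """Per-node and mean weighted clustering coefficient.

    The triple sum over ordered pairs (k, l) with i, k, l distinct
    collapses to matrix products: the numerator is diag(W^3) and the
    denominator is (sum_k w_ik)^2 - sum_k w_ik^2 (the zero diagonal removes
    the i = k and i = l terms automatically).  Nodes with a zero
    denominator (fewer than two weighted neighbours) get C_i = 0.
    """
    w = _as_weights(w)
    strength = w.sum(axis=1)
    numerator = np.einsum("ij,jk,ki->i", w, w, w)
    denominator = strength**2 - (w**2).sum(axis=1)
    c = np.divide(numerator, denominator,
                  out=np.zeros_like(numerator),
                  where=denominator > 1e-300)
    return c, float(c.mean())


def weighted_path_length(w: ConnectivityMatrix | np.ndarray
                         ) -> tuple[np.ndarray, float]:
    """Per-node and mean shortest-path length under l_ij = 1 / w_ij.

    Zero weights are absent edges.  The graph must be connected; a
    disconnected input is a hard error naming the components, because
    infinite distances would make the mean meaningless.
    """
    w = _as_weights(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    n_comp, labels = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp > 1:
        comps = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        raise ValueError(f"graph is disconnected; components: {comps}")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = dijkstra(csr_matrix(lengths), directed=False)
    per_node = dist.sum(axis=1) / (n - 1)
    return per_node, float(per_node.mean())


def surrogate_networks(w: ConnectivityMatrix | np.ndarray, n: int,
                       seed: int = 0, max_retries: int = 100
                       ) -> list[np.ndarray]:
    """Random weight-permutation surrogates of a symmetric weight matrix.

    Each surrogate permutes the upper-triangle off-diagonal weights and
    mirrors them, preserving the weight multiset while randomizing which
    node pairs carry them.  Permutations that disconnect the graph (possible
    when zero weights are present) are resampled up to ``max_retries``
    times, since the normalization needs finite surrogate path lengths.
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    w = _as_weights(w)
    rng = np.random.default_rng(seed)
    size = w.shape[0]
    iu = np.triu_indices(size, 1)
    values = w[iu]
    out: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(max_retries + 1):
            perm = rng.permutation(values)
            s = np.zeros_like(w)
            s[iu] = perm
            s += s.T
            n_comp, _ = connected_components(csr_matrix(s > 0),
                                             directed=False)
            if n_comp == 1:
                out.append(s)
                break
        else:
            raise RuntimeError(
                f"could not draw a connected surrogate in {max_retries} tries"
            )
    return out


def normalize_metrics(w: ConnectivityMatrix | np.ndarray,
                      n_surrogates: int = DEFAULT_N_SURROGATES,
                      seed: int = 0) -> ClassicalMeasures:
    """Observed C and L with their surrogate-ensemble normalizations.

    Normalized clustering is C / <C_surrogate> and normalized path length is
    L / <L_surrogate>, with <.> the mean over ``n_surrogates`` surrogate
    networks.
    """
    c_per_node, c_mean = weighted_clustering(w)
    l_per_node, l_mean = weighted_path_length(w)
    surr = surrogate_networks(w, n_surrogates, seed=seed)
    c_surr = np.mean([weighted_clustering(s)[1] for s in surr])
    l_surr = np.mean([weighted_path_length(s)[1] for s in surr])
    if c_surr == 0 or l_surr == 0:
        raise ValueError("surrogate mean is zero; cannot normalize")
    return ClassicalMeasures(
        clustering_per_node=c_per_node,
        path_length_per_node=l_per_node,
        clustering=c_mean,
        path_length=l_mean,
        clustering_norm=c_mean / c_surr,
        path_length_norm=l_mean / l_surr,
        n_surrogates=n_surrogates,
        surrogate_seed=seed,
    )
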