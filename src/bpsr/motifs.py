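"""Directed triad census and significance-profile topology comparison.

Networks are compared by the frequencies of their 13 connected 3-node
directed subgraph classes (the connected part of the standard 16-class
triad census).  For a network under test, a degree-preserving random
ensemble provides the null expectation, and the significance profile (SP)
is the unit-normalized z-score vector

    z_i = (N_test_i - mean(N_rand_i)) / std(N_rand_i),   sp = z / ||z||_2.

SPs of different networks (e.g. a trained SNN topology and the C. elegans
connectome supplied as an edge list) can then be compared directly.

Motif class order (conventional triad-type naming):
    021D 021U 021C 111D 111U 030T 030C 201 120D 120U 120C 210 300
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .lif import LayerParams

__all__ = [
    "MOTIF_CLASSES",
    "MotifProfile",
    "triad_census",
    "degree_preserving_ensemble",
    "significance_profile",
    "network_to_graph",
    "read_edgelist",
]

#: The 13 connected triad classes, in conventional motif-ID order.
MOTIF_CLASSES = (
    "021D", "021U", "021C", "111D", "111U", "030T", "030C",
    "201", "120D", "120U", "120C", "210", "300",
)


@dataclass
class MotifProfile:
    counts: np.ndarray
    sp: np.ndarray
    n_random: int


def _as_digraph(adjacency) -> nx.DiGraph:
    if isinstance(adjacency, nx.DiGraph):
        G = adjacency
    else:
        adjacency = np.asarray(adjacency, dtype=bool)
        G = nx.from_numpy_array(
            adjacency.astype(int), create_using=nx.DiGraph
        )
    if any(G.has_edge(v, v) for v in G):
        raise ValueError("self-loops are not allowed in the triad census")
    return G


def triad_census(adjacency) -> np.ndarray:
    """Counts of the 13 connected triad classes (induced subgraphs)."""
    G = _as_digraph(adjacency)
    census = nx.triadic_census(G)
    return np.array([census[c] for c in MOTIF_CLASSES], dtype=np.int64)


def degree_preserving_ensemble(
    adjacency, n_random: int = 100, seed: int | None = None
) -> list[nx.DiGraph]:
    """Null ensemble via directed edge swaps.

    Every sample preserves each node's in- and out-degree exactly and
    introduces no self-loops or multi-edges (10x-edge-count successful
    swaps per sample).  Graphs too small or rigid to randomize yield
    identity samples with a warning.
    """
    if n_random < 1:
        raise ValueError("need at least one random sample")
    G0 = _as_digraph(adjacency)
    rng = np.random.default_rng(seed)
    m = G0.number_of_edges()
    samples = []
    for _ in range(n_random):
        G = G0.copy()
        if m >= 2 and G0.number_of_nodes() >= 4:
            nswap = 10 * m
            try:
                nx.directed_edge_swap(
                    G,
                    nswap=nswap,
                    max_tries=100 * nswap,
                    seed=int(rng.integers(2**31)),
                )
            except nx.NetworkXError:
                pass  # rigid graph: keep however far the swaps got
        else:
            warnings.warn(
                "graph too small to randomize; using identity samples",
                stacklevel=2,
            )
        samples.append(G)
    return samples


def significance_profile(
    adjacency, n_random: int = 100, seed: int | None = None
) -> MotifProfile:
    """Unit-norm z-score vector of the 13 motif counts against the null.

    Motif classes with zero variance in the ensemble get z = 0 (keeps the
    profile finite).  An all-zero z-vector has no direction and raises.
    """
    counts = triad_census(adjacency)
    ensemble = degree_preserving_ensemble(adjacency, n_random, seed)
    rand_counts = np.array([triad_census(G) for G in ensemble], dtype=float)
    mean = rand_counts.mean(axis=0)
    std = rand_counts.std(axis=0)
    z = np.where(std > 0, (counts - mean) / np.where(std > 0, std, 1.0), 0.0)
    norm = float(np.linalg.norm(z))
    if norm == 0.0:
        raise ValueError(
            "all motif z-scores are zero: significance profile undefined"
        )
    return MotifProfile(counts=counts, sp=z / norm, n_random=n_random)


def network_to_graph(
    network: list[LayerParams], layers: slice | list[int] | None = None
) -> np.ndarray:
    """Directed adjacency over neurons from the existing synapses.

    Nodes are the input channels of the first selected layer followed by
    each selected layer's neurons; an edge exists where a synapse is
    unmasked and nonzero.  ``layers`` selects a subset (default: all).
    """
    if layers is None:
        selected = list(network)
    elif isinstance(layers, slice):
        selected = list(network[layers])
    else:
        selected = [network[i] for i in layers]
    if not selected:
        return np.zeros((0, 0), dtype=bool)
    sizes = [selected[0].n_in] + [lp.n_out for lp in selected]
    offsets = np.cumsum([0] + sizes)
    n = offsets[-1]
    adj = np.zeros((n, n), dtype=bool)
    for li, lp in enumerate(selected):
        pre, post = offsets[li], offsets[li + 1]
        live_in = lp.mask_in & (lp.w_in != 0)
        rows, cols = np.nonzero(live_in)
        adj[pre + cols, post + rows] = True
        live_rec = lp.mask_rec & (lp.w_rec != 0)
        rows, cols = np.nonzero(live_rec)
        adj[post + cols, post + rows] = True
    return adj


def read_edgelist(path) -> np.ndarray:
    """Two-column directed edge-list text file to a boolean adjacency."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            edges.append((a, b))
    names = sorted({v for e in edges for v in e})
    index = {v: i for i, v in enumerate(names)}
    adj = np.zeros((len(names), len(names)), dtype=bool)
    for a, b in edges:
        if a != b:
            adj[index[a], index[b]] = True
    return adj
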