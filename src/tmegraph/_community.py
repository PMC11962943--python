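"""Seeded Louvain community detection shared by the subtree- and patient-level stages."""

from __future__ import annotations

import random

import igraph as ig
import numpy as np


def louvain_labels(
    n_nodes: int,
    edges_i: np.ndarray,
    edges_j: np.ndarray,
    weights: np.ndarray,
    seed: int,
    resolution: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Louvain modularity communities on a weighted undirected graph.

    Returns 0-based labels relabeled by descending community size (ties by
    smallest member index) plus the achieved modularity.  The igraph RNG is
    seeded so reruns with the same seed give identical labels.
    """
    if n_nodes == 0:
        raise ValueError("graph is empty")
    ig.set_random_number_generator(random.Random(seed))
    g = ig.Graph(n=n_nodes, edges=list(zip(edges_i.tolist(), edges_j.tolist())))
    if g.ecount() == 0:
        return np.arange(n_nodes), 0.0
    clustering = g.community_multilevel(
        weights=weights.tolist(), resolution=resolution
    )
    raw = np.asarray(clustering.membership)
    modularity = float(clustering.modularity)
    return _relabel_by_size(raw), modularity


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Relabel communities 0..C-1 by descending size, then smallest member index."""
    ids, counts = np.unique(raw, return_counts=True)
    first_member = np.array([int(np.flatnonzero(raw == c)[0]) for c in ids])
    order = np.lexsort((first_member, -counts))
    mapping = np.empty(ids.max() + 1, dtype=np.int64)
    mapping[ids[order]] = np.arange(len(ids))
    return mapping[raw]
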