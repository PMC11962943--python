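"""Patient-level population graph, subgroup detection, and cohesion summaries.

The kernel matrix K (cosine similarities of pattern histograms) is
preprocessed PhenoGraph-style before community detection: each patient's
k★ most similar other patients form its nearest-neighbor set, and the edge
between two patients is reweighted by the intersection-over-union (IoU) of
their sets.  Louvain modularity maximization on the IoU graph yields the
patient subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._community import louvain_labels


@dataclass
class PopulationGraph:
    """k★-NN / IoU patient graph with optional community labels.

    ``iou`` is the dense symmetric (n, n) IoU weight matrix (zero diagonal);
    ``nn_sets`` the boolean (n, n) nearest-neighbor membership matrix
    (``nn_sets[i, j]`` true when j is among i's k★ most similar patients,
    self always excluded).  ``communities`` holds 1-based subgroup labels
    ordered by descending subgroup size.
    """

    patient_ids: list[str]
    iou: np.ndarray
    nn_sets: np.ndarray
    k_star: int
    communities: pd.Series | None = None
    modularity: float | None = None
    seed: int | None = None

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.iou, k=1))
        return pd.DataFrame(
            {
                "patient_i": [self.patient_ids[a] for a in i],
                "patient_j": [self.patient_ids[b] for b in j],
                "iou": self.iou[i, j],
            }
        )


def build_population_graph(K: pd.DataFrame, k_star: int = 30) -> PopulationGraph:
    """IoU-reweighted k★-NN graph from a kernel matrix.

    For each patient, the ``k_star`` most similar *other* patients (ties
    broken by index order) form its NN set; edge (i, j) carries
    ``|NN_i ∩ NN_j| / |NN_i ∪ NN_j|``; zero-IoU pairs carry no edge.
    """
    ids = [str(p) for p in K.index]
    Kv = K.to_numpy(dtype=float)
    n = len(ids)
    if k_star >= n:
        raise ValueError(f"k_star={k_star} must be < number of patients ({n})")
    if not np.allclose(Kv, Kv.T, atol=1e-8):
        raise ValueError("kernel matrix must be symmetric")
    nn = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        sim = Kv[i].copy()
        sim[i] = -np.inf  # self excluded
        order = np.lexsort((idx, -sim))
        nn[i, order[:k_star]] = True
    inter = (nn.astype(np.int64) @ nn.astype(np.int64).T)
    sizes = nn.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(iou, 0.0)
    return PopulationGraph(patient_ids=ids, iou=iou, nn_sets=nn, k_star=k_star)


def detect_communities(pop_graph: PopulationGraph, seed: int = 0) -> pd.Series:
    """Louvain subgroups on the IoU graph; 1-based labels by descending size.

    Stores labels and modularity on the graph and returns the label Series.
    """
    n = pop_graph.n_patients
    i, j = np.nonzero(np.triu(pop_graph.iou, k=1))
    labels0, modularity = louvain_labels(n, i, j, pop_graph.iou[i, j], seed=seed)
    labels = pd.Series(labels0 + 1, index=pop_graph.patient_ids, name="subgroup")
    pop_graph.communities = labels
    pop_graph.modularity = modularity
    pop_graph.seed = seed
    return labels


def group_similarity(K: pd.DataFrame, grouping: pd.Series) -> pd.Series:
    """Mean off-diagonal kernel similarity within each group and cohort-wide.

    Groups of size 1 are reported as NaN (no within-group pair).  The
    ``cohort`` entry averages over all unordered patient pairs.
    """
    Kv = K.to_numpy(dtype=float)
    ids = list(K.index)
    out: dict[str, float] = {}
    for group, members in grouping.groupby(grouping).groups.items():
        pos = [ids.index(m) for m in members]
        if len(pos) < 2:
            out[str(group)] = float("nan")
            continue
        sub = Kv[np.ix_(pos, pos)]
        iu = np.triu_indices(len(pos), k=1)
        out[str(group)] = float(sub[iu].mean())
    iu = np.triu_indices(len(ids), k=1)
    out["cohort"] = float(Kv[iu].mean())
    return pd.Series(out, name="mean_similarity")


def layout_3d(pop_graph: PopulationGraph, seed: int = 0) -> pd.DataFrame:
    """3D force-directed node coordinates (cosmetic; for plotting only)."""
    g = nx.Graph()
    g.add_nodes_from(range(pop_graph.n_patients))
    i, j = np.nonzero(np.triu(pop_graph.iou, k=1))
    g.add_weighted_edges_from(zip(i.tolist(), j.tolist(), pop_graph.iou[i, j]))
    pos = nx.spring_layout(g, dim=3, seed=seed)
    coords = np.array([pos[i] for i in range(pop_graph.n_patients)])
    if pop_graph.n_patients == 1:
        coords = np.zeros((1, 3))
    return pd.DataFrame(coords, index=pop_graph.patient_ids, columns=["x", "y", "z"])
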