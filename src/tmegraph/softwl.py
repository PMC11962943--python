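"""Soft-WL subtree kernel: subtree embeddings, pattern discovery, patient similarity.

The kernel relaxes the classic Weisfeiler-Lehman subtree kernel to weighted,
complete cellular graphs.  Every cell roots one depth-h subtree, summarized
by a feature embedding obtained by h graph-convolution sweeps of the one-hot
phenotype matrix:

    x_i(h) = x_i(h-1) + sum_{j != i} x_j(h-1) * A_ij      (self-weight 1)

equivalently the rows of A^h X(0).  Subtrees pooled across the discovery
cohort are clustered (k-NN graph, Jaccard edge reweighting, Louvain) into
recurring microenvironment patterns; each pattern's signature is the mean
embedding of its members.  A patient is represented by the histogram of
pattern memberships over their cells, and two patients are compared by the
cosine similarity of their histograms, which is 1 for identical graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from ._community import louvain_labels
from .cellular_graph import CellularGraph
from .io import PhenotypeVocabulary


# ---------------------------------------------------------------------------
# subtree embeddings


def compute_embeddings(graph: CellularGraph, h: int = 2, use_sparse: bool | None = None) -> np.ndarray:
    """Depth-``h`` subtree embeddings: rows of A^h X(0).

    Computed by ``h`` convolution sweeps X <- A X starting from the one-hot
    phenotype matrix (the unit self-loop carries each cell's own term).  When
    ``use_sparse`` is true (default: automatic for sparsified graphs) the
    sweeps run on a CSR copy of A; both paths agree to ~1e-12.
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    A = graph.weights
    X = graph.node_features
    if use_sparse is None:
        use_sparse = np.count_nonzero(A) < 0.2 * A.size
    if use_sparse:
        A = sparse.csr_matrix(A)
    for _ in range(h):
        X = A @ X
    return np.asarray(X)


def neighborhood_membership(
    graph: CellularGraph, h: int = 2, tau: float = 0.01
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Cells belonging to each cell's depth-``h`` neighborhood.

    Cell j is a member of cell i's neighborhood iff (A^h)_ij > tau; the root
    always qualifies since (A^h)_ii >= 1.  Returns per-cell member index
    arrays, member counts, and neighborhood radii (maximum centroid distance
    from root to member, in µm).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    Ah = np.linalg.matrix_power(graph.weights, h)
    members = [np.flatnonzero(row > tau) for row in Ah]
    sizes = np.array([m.size for m in members])
    xy = graph.coordinates
    radii = np.array(
        [np.linalg.norm(xy[m] - xy[i], axis=1).max() for i, m in enumerate(members)]
    )
    return members, sizes, radii


# ---------------------------------------------------------------------------
# pattern model


@dataclass
class PatternModel:
    """Learned vocabulary of microenvironment patterns.

    ``signatures`` is (C, m): pattern c's signature is the mean embedding of
    its member subtrees.  ``category_of_pattern`` labels each pattern as a
    tumor / immune / stromal / interface niche from the phenotype-category
    mass of its signature.
    """

    signatures: np.ndarray
    vocabulary: PhenotypeVocabulary
    h: int
    alpha: float
    k_pheno: int
    seed: int
    category_of_pattern: np.ndarray | None = None
    modularity: float | None = None

    @property
    def n_patterns(self) -> int:
        return self.signatures.shape[0]

    def signature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signatures,
            index=[f"P{c}" for c in range(1, self.n_patterns + 1)],
            columns=list(self.vocabulary.names),
        )


def cluster_subtrees(
    embeddings: np.ndarray,
    k_pheno: int = 100,
    seed: int = 0,
    vocabulary: PhenotypeVocabulary | None = None,
    h: int = 2,
    alpha: float = 0.01,
    interface_cutoff: float = 0.5,
) -> tuple[np.ndarray, PatternModel]:
    """Discover patterns by clustering pooled subtree embeddings.

    PhenoGraph-style procedure: exact Euclidean k-NN graph over embedding
    rows, each edge reweighted by the Jaccard overlap of its endpoints'
    neighbor sets, then Louvain modularity communities.  Returns 1-based
    pattern labels per subtree (patterns ordered by descending size) and the
    fitted :class:`PatternModel`.
    """
    X = np.asarray(embeddings, dtype=float)
    n = X.shape[0]
    if n < k_pheno + 1:
        raise ValueError(f"need at least k_pheno+1={k_pheno + 1} subtrees, got {n}")
    nn = NearestNeighbors(n_neighbors=k_pheno + 1).fit(X)
    _, idx = nn.kneighbors(X)
    # drop self from each neighbor list (may not be in column 0 among duplicates)
    neigh = np.empty((n, k_pheno), dtype=np.int64)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k_pheno]
        if row.size < k_pheno:  # self absent from returned list
            row = idx[i][:k_pheno]
        neigh[i] = row
    nbr_sets = [set(r.tolist()) for r in neigh]
    # union k-NN graph
    src = np.repeat(np.arange(n), k_pheno)
    dst = neigh.ravel()
    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    pairs = np.unique(np.stack([lo, hi], axis=1), axis=0)
    ei, ej = pairs[:, 0], pairs[:, 1]
    inter = np.fromiter(
        (len(nbr_sets[a] & nbr_sets[b]) for a, b in zip(ei.tolist(), ej.tolist())),
        dtype=np.int64, count=len(ei),
    )
    union = 2 * k_pheno - inter
    w = inter / union
    keep = w > 0
    labels0, modularity = louvain_labels(n, ei[keep], ej[keep], w[keep], seed=seed)
    labels = labels0 + 1
    signatures = compute_signatures(X, labels)
    category = None
    if vocabulary is not None:
        from .patterns import categorize_patterns

        category = categorize_patterns(signatures, vocabulary, interface_cutoff)
    model = PatternModel(
        signatures=signatures,
        vocabulary=vocabulary,
        h=h,
        alpha=alpha,
        k_pheno=k_pheno,
        seed=seed,
        category_of_pattern=category,
        modularity=modularity,
    )
    return labels, model


def compute_signatures(embeddings: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pattern signatures: arithmetic mean of member embeddings, labels 1..C."""
    labels = np.asarray(labels)
    C = int(labels.max())
    out = np.empty((C, embeddings.shape[1]))
    for c in range(1, C + 1):
        members = labels == c
        if not members.any():
            raise ValueError(f"pattern {c} has no members")
        out[c - 1] = embeddings[members].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# histograms and kernel


def pattern_histogram(labels: np.ndarray, n_patterns: int) -> np.ndarray:
    """Counts of each pattern among one patient's subtrees (labels 1..C)."""
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 1 or labels.max() > n_patterns):
        raise ValueError("labels out of range 1..C")
    return np.bincount(labels, minlength=n_patterns + 1)[1:]


def pattern_histograms(
    labels: np.ndarray, patient_per_subtree: Sequence[str], n_patterns: int
) -> pd.DataFrame:
    """Patient × pattern histogram matrix (each cell roots exactly one subtree)."""
    pids = pd.Series(list(patient_per_subtree))
    order = list(pd.unique(pids))
    rows = {
        pid: pattern_histogram(np.asarray(labels)[(pids == pid).to_numpy()], n_patterns)
        for pid in order
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"P{c}" for c in range(1, n_patterns + 1)])


def kernel(hist_i: np.ndarray, hist_j: np.ndarray) -> float:
    """Cosine similarity of two pattern histograms, in [0, 1]."""
    hi = np.asarray(hist_i, dtype=float)
    hj = np.asarray(hist_j, dtype=float)
    ni, nj = np.linalg.norm(hi), np.linalg.norm(hj)
    if ni == 0 or nj == 0:
        raise ValueError("kernel undefined for an all-zero histogram")
    return float(np.clip(hi @ hj / (ni * nj), 0.0, 1.0))


def kernel_matrix(histograms: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Symmetric PSD cosine-similarity matrix over patient histograms."""
    H = histograms.to_numpy(dtype=float) if isinstance(histograms, pd.DataFrame) else np.asarray(histograms, dtype=float)
    norms = np.linalg.norm(H, axis=1)
    if (norms == 0).any():
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"all-zero histogram at row {bad}")
    K = (H / norms[:, None]) @ (H / norms[:, None]).T
    K = np.clip((K + K.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(K, 1.0)
    if isinstance(histograms, pd.DataFrame):
        return pd.DataFrame(K, index=histograms.index, columns=histograms.index)
    return K
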