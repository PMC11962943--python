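"""Projection of external cohorts onto a fitted discovery model.

Three nested mappings, all nearest-centroid style with lower-index tie
breaking: cells map to the discovery phenotype with the closest mean
expression over the shared antigen panel; subtree embeddings map to the
closest pattern signature; patients map to the subgroup winning a
similarity-weighted vote among their ``knn_map`` most similar discovery
patients (vote ties fall back to the single most similar neighbor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import CellTable, PhenotypeVocabulary
from .softwl import PatternModel, kernel, pattern_histograms

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeCentroids:
    """Mean expression per discovery phenotype over the shared antigen panel."""

    centroids: np.ndarray  # (m, n_shared)
    shared_antigens: tuple[str, ...]
    vocabulary: PhenotypeVocabulary

    def __post_init__(self) -> None:
        if self.centroids.shape != (len(self.vocabulary), len(self.shared_antigens)):
            raise ValueError("centroid matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.centroids, index=list(self.vocabulary.names),
            columns=list(self.shared_antigens),
        )


def fit_phenotype_centroids(
    discovery: CellTable, shared_antigens: list[str], zscale: bool = False
) -> PhenotypeCentroids:
    """Per-phenotype mean expression restricted to the shared antigens.

    ``zscale`` standardizes each antigen over discovery cells first
    (off by default: expression is used as provided).
    """
    if discovery.expression is None:
        raise ValueError("discovery cells carry no expression data")
    missing = [a for a in shared_antigens if a not in discovery.expression.columns]
    if missing:
        raise ValueError(f"antigens missing from discovery expression: {missing}")
    expr = discovery.expression[shared_antigens].to_numpy(dtype=float)
    if zscale:
        expr = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=0)
    codes = discovery.vocabulary.codes(discovery.cells["phenotype"])
    m = len(discovery.vocabulary)
    centroids = np.empty((m, len(shared_antigens)))
    for c in range(m):
        members = codes == c
        if not members.any():
            raise ValueError(
                f"phenotype {discovery.vocabulary.names[c]!r} has no cells"
            )
        centroids[c] = expr[members].mean(axis=0)
    return PhenotypeCentroids(centroids, tuple(shared_antigens), discovery.vocabulary)


def map_cell_phenotypes(
    external: CellTable, centroids: PhenotypeCentroids
) -> np.ndarray:
    """Assign each external cell the phenotype with the nearest centroid.

    Euclidean distance over the shared antigens; exact ties resolve to the
    lower phenotype index and are logged.
    """
    if external.expression is None:
        raise ValueError("external cells carry no expression data")
    missing = [a for a in centroids.shared_antigens if a not in external.expression.columns]
    if missing:
        raise ValueError(f"antigens missing from external expression: {missing}")
    X = external.expression[list(centroids.shared_antigens)].to_numpy(dtype=float)
    D = cdist(X, centroids.centroids)
    assigned = D.argmin(axis=1)
    ties = (D == D[np.arange(len(D)), assigned][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("map_cell_phenotypes: %d ties broken to lower index", int(ties.sum()))
    return np.array([centroids.vocabulary.names[c] for c in assigned], dtype=object)


def map_subtrees_to_patterns(
    embeddings: np.ndarray, model: PatternModel
) -> np.ndarray:
    """Assign each subtree the 1-based label of its nearest pattern signature."""
    X = np.asarray(embeddings, dtype=float)
    if X.shape[1] != model.signatures.shape[1]:
        raise ValueError(
            f"embedding dimension {X.shape[1]} != signature dimension "
            f"{model.signatures.shape[1]}"
        )
    D = cdist(X, model.signatures)
    return D.argmin(axis=1) + 1


def map_patients_to_subgroups(
    external_histograms: pd.DataFrame,
    discovery_histograms: pd.DataFrame,
    discovery_subgroups: pd.Series,
    knn_map: int = 3,
) -> pd.Series:
    """Similarity-weighted vote among the most similar discovery patients.

    For each external patient the ``knn_map`` most kernel-similar discovery
    patients (similarity ties by index) vote with weight equal to their
    similarity; the subgroup with the largest summed weight wins, and exact
    vote ties go to the single most similar neighbor's subgroup.
    """
    if len(discovery_histograms) < knn_map:
        raise ValueError("discovery cohort smaller than knn_map")
    disc = discovery_histograms.to_numpy(dtype=float)
    labels = discovery_subgroups.loc[discovery_histograms.index]
    out = {}
    for pid, row in external_histograms.iterrows():
        h = row.to_numpy(dtype=float)
        if np.linalg.norm(h) == 0:
            raise ValueError(f"external patient {pid!r} has an all-zero histogram")
        sims = np.array([kernel(h, d) for d in disc])
        order = np.lexsort((np.arange(len(sims)), -sims))[:knn_map]
        votes: dict[object, float] = {}
        for pos in order:
            g = labels.iloc[pos]
            votes[g] = votes.get(g, 0.0) + sims[pos]
        best = max(votes.values())
        winners = [g for g, v in votes.items() if v == best]
        if len(winners) == 1:
            out[pid] = winners[0]
        else:
            out[pid] = labels.iloc[order[0]]  # tie: most similar neighbor decides
    return pd.Series(out, name="subgroup")
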