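"""Run configuration shared by every pipeline stage.

All defaults are the published operating point of the method: a Gaussian
edge-decay rate of 0.01 per µm², subtree depth 2, neighborhood cutoff
τ = 0.01, PhenoGraph-style clustering with k = 100, population graph with
k★ = 30 nearest neighbors, a 500-cell patient-inclusion floor, a 1 %
pattern-positivity threshold, and the 50 %-of-max Hodges-Lehmann rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Hyperparameters of the bi-level graph pipeline.

    Parameters
    ----------
    alpha
        Decay rate of the Gaussian edge weight w = exp(-alpha * d²),
        with d the centroid distance in µm.
    h
        Subtree depth: number of graph-convolution sweeps.
    tau
        Neighborhood membership threshold on (A^h)_ij; affects only the
        reported neighborhood sizes/radii, never the embeddings.
    k_pheno
        Neighbor count for the k-NN/Jaccard/Louvain subtree clustering.
    k_star
        Neighbor count for the patient-level k★-NN IoU population graph.
    min_cells
        Patients with fewer total cells (summed over their images) are
        excluded from analysis.
    positivity_threshold
        A patient is "positive" for a pattern when its proportion is >=
        this value.
    hl_fraction
        A pattern is characteristic of a subgroup when its
        Hodges-Lehmann statistic strictly exceeds hl_fraction times the
        subgroup's maximum statistic.
    knn_map
        Number of discovery neighbors in the similarity-weighted vote
        that maps an external patient to a subgroup.
    random_seed
        Seed for every stochastic step (clustering, layouts).
    sparsify_epsilon
        Edge weights below this value are dropped from the cellular
        graph; 0 keeps the exact dense complete graph.
    """

    alpha: float = 0.01
    h: int = 2
    tau: float = 0.01
    k_pheno: int = 100
    k_star: int = 30
    min_cells: int = 500
    positivity_threshold: float = 0.01
    hl_fraction: float = 0.5
    knn_map: int = 3
    random_seed: int = 0
    sparsify_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (isinstance(self.h, int) and self.h >= 1):
            raise ValueError("h must be an integer >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        for name in ("k_pheno", "k_star", "min_cells", "knn_map"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.positivity_threshold <= 0:
            raise ValueError("positivity_threshold must be > 0")
        if not (0 < self.hl_fraction <= 1):
            raise ValueError("hl_fraction must be in (0, 1]")
        if self.sparsify_epsilon < 0:
            raise ValueError("sparsify_epsilon must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
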