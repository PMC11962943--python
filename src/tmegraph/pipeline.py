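"""End-to-end orchestration: fit a discovery cohort, map external cohorts, comparators.

``fit_discovery`` runs the whole chain — patient filtering, Gaussian
cellular graphs, subtree embeddings, pooled pattern discovery, patient
histograms, cosine kernel, k★-NN/IoU population graph, Louvain subgroups,
characteristic-pattern identification, and survival reports — and returns
one result object that can be serialized to a model directory and reloaded
for mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, io, mapping, patterns, population, softwl, survival
from .cellular_graph import CellularGraph, build_graph
from .config import RunConfig
from .io import CellTable, ClinicalTable, PhenotypeVocabulary

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Everything produced by fitting the discovery cohort."""

    config: RunConfig
    model: softwl.PatternModel
    histograms: pd.DataFrame  # patients × patterns
    proportions: pd.DataFrame
    kernel: pd.DataFrame  # patients × patients
    pop_graph: population.PopulationGraph
    subgroups: pd.Series
    characteristic: patterns.CharacteristicReport | None
    survival_report: pd.DataFrame | None
    logrank: tuple[float, int, float] | None
    subtree_labels: np.ndarray  # pooled, aligned with subtree_patients
    subtree_patients: pd.Series
    phenotype_centroids: mapping.PhenotypeCentroids | None = None


def cohort_graphs(cells: CellTable, config: RunConfig) -> list[CellularGraph]:
    return [
        build_graph(cells.for_patient(pid), alpha=config.alpha,
                    sparsify_epsilon=config.sparsify_epsilon)
        for pid in cells.patient_ids
    ]


def cohort_embeddings(
    graphs: list[CellularGraph], config: RunConfig
) -> tuple[np.ndarray, pd.Series]:
    """Pooled subtree embeddings and the patient id of each pooled row."""
    blocks = [softwl.compute_embeddings(g, h=config.h) for g in graphs]
    owners = pd.Series(
        np.concatenate([[g.patient_id] * g.n_cells for g in graphs])
    )
    return np.vstack(blocks), owners


def fit_discovery(
    cells: CellTable,
    clinical: ClinicalTable | None,
    config: RunConfig | None = None,
    shared_antigens: list[str] | None = None,
) -> FitResult:
    """Fit the full bi-level graph model on a discovery cohort."""
    config = config or RunConfig()
    cells = io.filter_patients(cells, config.min_cells)
    if len(cells) == 0:
        raise ValueError("no patients left after the minimum-cell filter")
    graphs = cohort_graphs(cells, config)
    embeddings, owners = cohort_embeddings(graphs, config)
    labels, model = softwl.cluster_subtrees(
        embeddings,
        k_pheno=config.k_pheno,
        seed=config.random_seed,
        vocabulary=cells.vocabulary,
        h=config.h,
        alpha=config.alpha,
    )
    logger.info("discovered %d patterns (modularity %.3f)", model.n_patterns,
                model.modularity or float("nan"))
    histograms = softwl.pattern_histograms(labels, owners, model.n_patterns)
    K = softwl.kernel_matrix(histograms)
    pop = population.build_population_graph(K, k_star=min(config.k_star, len(K) - 1))
    subgroups = population.detect_communities(pop, seed=config.random_seed)
    proportions = patterns.normalize_histograms(histograms)
    characteristic = None
    if subgroups.nunique() >= 2:
        characteristic = patterns.characteristic_patterns(
            proportions, subgroups, config.hl_fraction
        )
    report = None
    logrank = None
    if clinical is not None:
        clin = clinical.aligned(list(histograms.index))
        if subgroups.nunique() >= 2:
            report, logrank = survival.subgroup_survival_report(
                clin["survival_time"].to_numpy(),
                clin["event"].to_numpy(),
                subgroups,
            )
    centroids = None
    if shared_antigens:
        centroids = mapping.fit_phenotype_centroids(cells, shared_antigens)
    return FitResult(
        config=config,
        model=model,
        histograms=histograms,
        proportions=proportions,
        kernel=K,
        pop_graph=pop,
        subgroups=subgroups,
        characteristic=characteristic,
        survival_report=report,
        logrank=logrank,
        subtree_labels=labels,
        subtree_patients=owners,
        phenotype_centroids=centroids,
    )


def map_cohort(
    external_cells: CellTable,
    fit: FitResult,
    min_cells: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Project an external cohort onto a fitted model.

    External phenotypes must already live in the model vocabulary (run
    :func:`tmegraph.mapping.map_cell_phenotypes` first when they do not).
    Returns (pattern histograms, subgroup assignments).
    """
    config = fit.config
    if min_cells is not None:
        external_cells = io.filter_patients(external_cells, min_cells)
    if len(external_cells) == 0:
        raise ValueError("external cohort is empty")
    graphs = cohort_graphs(external_cells, config)
    embeddings, owners = cohort_embeddings(graphs, config)
    labels = mapping.map_subtrees_to_patterns(embeddings, fit.model)
    histograms = softwl.pattern_histograms(labels, owners, fit.model.n_patterns)
    subgroups = mapping.map_patients_to_subgroups(
        histograms, fit.histograms, fit.subgroups, knn_map=config.knn_map
    )
    return histograms, subgroups


def comparator_profiles(
    cells: CellTable,
    scheme: str,
    config: RunConfig | None = None,
    fit: FitResult | None = None,
) -> pd.DataFrame:
    """Patient feature matrix φ(G) for a comparator scheme."""
    config = config or RunConfig()
    if scheme not in baselines.SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {baselines.SCHEMES}")
    pids = cells.patient_ids
    if scheme == "cell_abundance":
        rows = [baselines.cell_abundance(cells.for_patient(p)) for p in pids]
        cols = list(cells.vocabulary.names)
    elif scheme == "pairwise_proximity":
        rows = [
            baselines.pairwise_proximity(cells.for_patient(p), alpha=config.alpha)
            for p in pids
        ]
        cols = baselines.proximity_pair_names(cells.vocabulary)
    elif scheme == "category_abundance":
        if fit is None:
            raise ValueError("category_abundance requires a fitted pattern model")
        rows = []
        for p in pids:
            mask = (fit.subtree_patients == p).to_numpy()
            rows.append(
                baselines.category_abundance(
                    fit.subtree_labels[mask], fit.model.category_of_pattern
                )
            )
        cols = list(patterns.NICHE_CATEGORIES)
    else:  # wl_accumulated / wl_last
        graphs = cohort_graphs(cells, config)
        mode = "accumulated" if scheme == "wl_accumulated" else "last"
        mat = baselines.wl_profiles(graphs, h=config.h, mode=mode)
        rows = list(mat)
        cols = [f"color_{k}" for k in range(mat.shape[1])]
    return pd.DataFrame(np.asarray(rows, dtype=float), index=pids, columns=cols)


def fit_comparator(
    cells: CellTable,
    clinical: ClinicalTable | None,
    scheme: str,
    config: RunConfig | None = None,
    fit: FitResult | None = None,
):
    """Swap φ(G); keep population graph, communities, and survival identical."""
    config = config or RunConfig()
    cells = io.filter_patients(cells, config.min_cells)
    profiles = comparator_profiles(cells, scheme, config, fit)
    keep = profiles.index[(profiles.to_numpy() ** 2).sum(axis=1) > 0]
    if len(keep) < len(profiles):
        logger.warning("dropping %d patients with all-zero %s features",
                       len(profiles) - len(keep), scheme)
        profiles = profiles.loc[keep]
    K = softwl.kernel_matrix(profiles)
    pop = population.build_population_graph(K, k_star=min(config.k_star, len(K) - 1))
    subgroups = population.detect_communities(pop, seed=config.random_seed)
    report = None
    logrank = None
    if clinical is not None and subgroups.nunique() >= 2:
        clin = clinical.aligned(list(profiles.index))
        report, logrank = survival.subgroup_survival_report(
            clin["survival_time"].to_numpy(), clin["event"].to_numpy(), subgroups
        )
    return profiles, K, subgroups, report, logrank


# ---------------------------------------------------------------------------
# model directory serialization


def save_fit(fit: FitResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_matrix_tsv(fit.model.signature_frame(), outdir / "signatures.tsv")
    io.write_matrix_tsv(fit.histograms, outdir / "histograms.tsv")
    io.write_matrix_tsv(fit.kernel, outdir / "kernel.tsv")
    io.write_matrix_tsv(
        fit.pop_graph.edge_list().set_index("patient_i"), outdir / "population_edges.tsv"
    )
    io.write_assignments(fit.subgroups, outdir / "subgroups.tsv")
    if fit.characteristic is not None:
        fit.characteristic.to_frame().to_csv(
            outdir / "characteristic_patterns.tsv", sep="\t", index=False
        )
    if fit.survival_report is not None:
        io.write_matrix_tsv(fit.survival_report, outdir / "survival_report.tsv")
    vocab_frame = fit.model.vocabulary.to_frame()
    vocab_frame["pattern_category"] = ""
    vocab_frame.to_csv(outdir / "vocabulary.tsv", sep="\t", index=False)
    meta = {
        "config": fit.config.to_dict(),
        "n_patterns": fit.model.n_patterns,
        "pattern_categories": (
            list(fit.model.category_of_pattern)
            if fit.model.category_of_pattern is not None else None
        ),
        "modularity_patterns": fit.model.modularity,
        "modularity_population": fit.pop_graph.modularity,
        "logrank": list(fit.logrank) if fit.logrank else None,
        "tie_handling": "efron",
    }
    io.write_json(meta, outdir / "model.json")
    if fit.phenotype_centroids is not None:
        io.write_matrix_tsv(
            fit.phenotype_centroids.to_frame(), outdir / "phenotype_centroids.tsv"
        )
        (outdir / "shared_antigens.txt").write_text(
            "\n".join(fit.phenotype_centroids.shared_antigens) + "\n"
        )
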