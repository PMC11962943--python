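"""Synthetic spatial cohorts with planted niches, subgroups, and survival signal.

The generator emulates the structure the pipeline assumes in real tissue:
recurring local cell patterns (niche archetypes) whose abundance differs by
patient subgroup and predicts survival.  Cells are a marked planar point
pattern per patient: niche centers placed uniformly with a minimum
separation, members scattered isotropic-Gaussian around each center with
phenotypes drawn from the archetype's mixture, plus a Poisson number of
uniform background cells with uniform phenotypes.  Survival times are
exponential with a subgroup-specific hazard, censored by an independent
exponential clock.  Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellTable, ClinicalTable, PhenotypeVocabulary

DEFAULT_VOCABULARY = PhenotypeVocabulary(
    names=("tumor_ck", "tumor_basal", "t_cell", "b_cell", "fibroblast", "endothelial"),
    category_of={
        "tumor_ck": "tumor",
        "tumor_basal": "tumor",
        "t_cell": "immune",
        "b_cell": "immune",
        "fibroblast": "stromal",
        "endothelial": "stromal",
    },
)


@dataclass(frozen=True)
class Archetype:
    """A recurring niche: phenotype mixture, spatial extent, and occupancy."""

    name: str
    mixture: dict[str, float]  # phenotype -> probability, sums to 1
    radius_um: float = 30.0
    cells_per_niche: int = 40

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"archetype {self.name!r}: mixture sums to {total}")
        if self.radius_um <= 0 or self.cells_per_niche < 1:
            raise ValueError("radius and cells_per_niche must be positive")


#: compact niches (radius 12 µm, 8 cells) whose mixtures spread over all six
#: phenotypes — one dominant, one co-dominant, four minor — so neighborhood
#: composition varies in several directions at comparable scale
DEFAULT_ARCHETYPES = (
    Archetype(
        "tumor_core",
        {"tumor_ck": 0.50, "tumor_basal": 0.20, "t_cell": 0.10, "b_cell": 0.05,
         "fibroblast": 0.10, "endothelial": 0.05},
        radius_um=12.0, cells_per_niche=8,
    ),
    Archetype(
        "immune_aggregate",
        {"t_cell": 0.50, "b_cell": 0.20, "tumor_ck": 0.10, "tumor_basal": 0.05,
         "endothelial": 0.10, "fibroblast": 0.05},
        radius_um=12.0, cells_per_niche=8,
    ),
    Archetype(
        "stromal_tract",
        {"fibroblast": 0.50, "endothelial": 0.20, "tumor_basal": 0.10,
         "b_cell": 0.10, "tumor_ck": 0.05, "t_cell": 0.05},
        radius_um=12.0, cells_per_niche=8,
    ),
)

#: subgroup rows × archetype columns; each subgroup is dominated by one archetype
DEFAULT_SUBGROUP_PROFILES = (
    (0.90, 0.05, 0.05),
    (0.05, 0.90, 0.05),
    (0.05, 0.05, 0.90),
)


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated cohort.

    Defaults plant a clearly separated study: 60 patients in 3 balanced
    subgroups, 3 niche archetypes with distinct dominant phenotypes,
    5 niches of 8 cells per patient on a 700 µm image, ~8 background
    cells, and subgroup hazards 0.08 / 0.03 / 0.01 per month with an
    exponential censoring clock of rate 0.015.
    """

    n_patients: int = 60
    n_subgroups: int = 3
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    subgroup_profiles: tuple[tuple[float, ...], ...] = DEFAULT_SUBGROUP_PROFILES
    niches_per_patient: int = 5
    image_size_um: float = 700.0
    background_rate: float = 8.0
    hazards: tuple[float, ...] = (0.08, 0.03, 0.01)
    censoring_rate: float = 0.015
    seed: int = 0
    vocabulary: PhenotypeVocabulary = DEFAULT_VOCABULARY
    with_expression: bool = False
    n_antigens: int = 8
    expression_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subgroups != len(self.subgroup_profiles):
            raise ValueError("one mixture profile per subgroup required")
        if self.n_subgroups != len(self.hazards):
            raise ValueError("one hazard per subgroup required")
        for profile in self.subgroup_profiles:
            if len(profile) != len(self.archetypes):
                raise ValueError("profile length must match number of archetypes")
            if not np.isclose(sum(profile), 1.0):
                raise ValueError("subgroup profiles must sum to 1")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be > 0")
        for arch in self.archetypes:
            for phen in arch.mixture:
                if phen not in self.vocabulary.names:
                    raise ValueError(f"archetype phenotype {phen!r} not in vocabulary")


@dataclass
class SimulatedCohort:
    """Generated cohort plus its planted ground truth."""

    cells: CellTable
    clinical: ClinicalTable
    config: SimConfig
    patient_subgroup: pd.Series  # patient_id -> 1-based subgroup
    cell_truth: pd.DataFrame  # per cell: niche_id (-1 = background), archetype


def _place_niche_centers(
    rng: np.random.Generator, n: int, size: float, min_sep: float
) -> np.ndarray:
    """Uniform centers with pairwise separation >= min_sep (rejection sampling)."""
    margin = min_sep / 2
    if size <= 2 * margin:
        raise ValueError("image too small for the requested niches")
    centers: list[np.ndarray] = []
    for _ in range(5000):
        cand = rng.uniform(margin, size - margin, size=2)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
            if len(centers) == n:
                return np.array(centers)
    raise ValueError(
        f"could not place {n} niches with separation {min_sep} in a {size} µm image"
    )


def _phenotype_expression_centroids(config: SimConfig) -> np.ndarray:
    """Deterministic well-separated expression archetype per phenotype."""
    m = len(config.vocabulary)
    centroids = np.zeros((m, config.n_antigens))
    for k in range(m):
        centroids[k, k % config.n_antigens] = 2.0
        centroids[k, (k + 1) % config.n_antigens] = 1.0 if k % 2 else 0.5
    return centroids


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a full cohort (cells, clinical, planted truth) from ``config``."""
    rng = np.random.default_rng(config.seed)
    vocab = config.vocabulary
    names = vocab.names
    mixtures = np.array(
        [[a.mixture.get(p, 0.0) for p in names] for a in config.archetypes]
    )
    profiles = np.array(config.subgroup_profiles)
    expr_centroids = _phenotype_expression_centroids(config)

    cell_rows = []
    expr_rows = []
    truth_rows = []
    clinical_rows = []
    subgroup_of = {}
    for p in range(config.n_patients):
        pid = f"patient_{p + 1:03d}"
        subgroup = p % config.n_subgroups + 1  # balanced assignment
        subgroup_of[pid] = subgroup
        radius = max(a.radius_um for a in config.archetypes)
        centers = _place_niche_centers(
            rng, config.niches_per_patient, config.image_size_um, 3.0 * radius
        )
        niche_arch = rng.choice(
            len(config.archetypes), size=config.niches_per_patient,
            p=profiles[subgroup - 1],
        )
        for niche_id, (center, arch_idx) in enumerate(zip(centers, niche_arch)):
            arch = config.archetypes[arch_idx]
            sigma = arch.radius_um / 2.0  # Gaussian niche: sigma = radius / 2
            pos = rng.normal(center, sigma, size=(arch.cells_per_niche, 2))
            phen = rng.choice(len(names), size=arch.cells_per_niche, p=mixtures[arch_idx])
            for (x, y), c in zip(pos, phen):
                cell_rows.append((pid, f"{pid}_img1", float(x), float(y), names[c]))
                truth_rows.append((pid, niche_id, arch.name))
                if config.with_expression:
                    expr_rows.append(
                        expr_centroids[c]
                        + rng.normal(0, config.expression_noise, config.n_antigens)
                    )
        n_bg = int(rng.poisson(config.background_rate))
        if n_bg:
            pos = rng.uniform(0, config.image_size_um, size=(n_bg, 2))
            phen = rng.integers(0, len(names), size=n_bg)
            for (x, y), c in zip(pos, phen):
                cell_rows.append((pid, f"{pid}_img1", float(x), float(y), names[c]))
                truth_rows.append((pid, -1, "background"))
                if config.with_expression:
                    expr_rows.append(
                        expr_centroids[c]
                        + rng.normal(0, config.expression_noise, config.n_antigens)
                    )
        event_time = rng.exponential(1.0 / config.hazards[subgroup - 1])
        censor_time = (
            rng.exponential(1.0 / config.censoring_rate)
            if config.censoring_rate > 0
            else np.inf
        )
        clinical_rows.append(
            {
                "patient_id": pid,
                "survival_time": float(min(event_time, censor_time)),
                "event": int(event_time <= censor_time),
                "subtype": f"subtype_{subgroup}",
                "age": float(np.round(rng.uniform(35, 85), 1)),
            }
        )

    cells_df = pd.DataFrame(
        cell_rows, columns=["patient_id", "image_id", "x", "y", "phenotype"]
    )
    expr_df = None
    if config.with_expression:
        expr_df = pd.DataFrame(
            np.asarray(expr_rows), columns=[f"antigen_{k + 1}" for k in range(config.n_antigens)]
        )
    cells = CellTable(cells_df, vocab, expr_df)
    clinical = ClinicalTable(pd.DataFrame(clinical_rows).set_index("patient_id"))
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "niche_id", "archetype"])
    return SimulatedCohort(
        cells=cells,
        clinical=clinical,
        config=config,
        patient_subgroup=pd.Series(subgroup_of, name="subgroup"),
        cell_truth=truth,
    )


def worked_example_cohort() -> SimulatedCohort:
    """Tiny fixed three-patient cohort with hand-checkable intermediate values.

    Two phenotypes; patient geometries are chosen so that edge weights hit
    round values (distance 10 µm -> weight e^-1 at alpha = 0.01) and
    pattern histograms are easy to verify by hand.
    """
    vocab = PhenotypeVocabulary(
        names=("tumor_ck", "t_cell"),
        category_of={"tumor_ck": "tumor", "t_cell": "immune"},
    )
    rows = []
    # patient 1: pure tumor pair 10 µm apart plus an isolated tumor cell
    rows += [
        ("wp1", "wp1_img1", 0.0, 0.0, "tumor_ck"),
        ("wp1", "wp1_img1", 10.0, 0.0, "tumor_ck"),
        ("wp1", "wp1_img1", 500.0, 500.0, "tumor_ck"),
    ]
    # patient 2: mixed tumor/immune pair 10 µm apart plus isolated immune cell
    rows += [
        ("wp2", "wp2_img1", 0.0, 0.0, "tumor_ck"),
        ("wp2", "wp2_img1", 0.0, 10.0, "t_cell"),
        ("wp2", "wp2_img1", 400.0, 400.0, "t_cell"),
    ]
    # patient 3: immune triplet on an equilateral triangle (side 10 µm), two images
    rows += [
        ("wp3", "wp3_img1", 0.0, 0.0, "t_cell"),
        ("wp3", "wp3_img1", 10.0, 0.0, "t_cell"),
        ("wp3", "wp3_img1", 5.0, 5.0 * np.sqrt(3.0), "t_cell"),
        ("wp3", "wp3_img2", 0.0, 0.0, "tumor_ck"),
    ]
    cells_df = pd.DataFrame(rows, columns=["patient_id", "image_id", "x", "y", "phenotype"])
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": ["wp1", "wp2", "wp3"],
                "survival_time": [24.0, 60.0, 48.0],
                "event": [1, 0, 1],
                "subtype": ["subtype_1", "subtype_2", "subtype_2"],
            }
        ).set_index("patient_id")
    )
    config = SimConfig(
        n_patients=3, n_subgroups=3, hazards=(0.05, 0.02, 0.02),
        subgroup_profiles=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
        vocabulary=DEFAULT_VOCABULARY, seed=0,
    )
    return SimulatedCohort(
        cells=CellTable(cells_df, vocab),
        clinical=clinical,
        config=config,
        patient_subgroup=pd.Series({"wp1": 1, "wp2": 2, "wp3": 3}, name="subgroup"),
        cell_truth=pd.DataFrame(
            {
                "patient_id": cells_df["patient_id"],
                "niche_id": -1,
                "archetype": "hand_placed",
            }
        ),
    )
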