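"""Domain containers and readers/writers for cell, clinical, and matrix data.

Cell tables are plain CSV/TSV, one row per cell, with configurable column
names (defaults: ``patient_id,image_id,x,y,phenotype``); any further numeric
columns can be declared as antigen-expression channels.  Clinical tables are
keyed by ``patient_id``.  All matrices are written as labeled TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("tumor", "immune", "stromal")

#: canonical cell-table column order
CELL_COLUMNS = ("patient_id", "image_id", "x", "y", "phenotype")

DEFAULT_SCHEMA = {c: c for c in CELL_COLUMNS}


@dataclass(frozen=True)
class PhenotypeVocabulary:
    """Ordered set of cell phenotype labels with tumor/immune/stromal categories.

    The order is fixed at construction and drives every one-hot encoding and
    signature column downstream.
    """

    names: tuple[str, ...]
    category_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("vocabulary must contain at least one phenotype")
        if len(set(self.names)) != len(self.names):
            raise ValueError("phenotype names must be unique")
        for name in self.names:
            cat = self.category_of.get(name)
            if cat not in CATEGORIES:
                raise ValueError(
                    f"phenotype {name!r} has invalid category {cat!r}; "
                    f"expected one of {CATEGORIES}"
                )

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def codes(self, phenotypes: Iterable[str]) -> np.ndarray:
        """Integer codes in vocabulary order; raises on unknown labels."""
        lut = {n: i for i, n in enumerate(self.names)}
        try:
            return np.fromiter((lut[p] for p in phenotypes), dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise ValueError(f"unknown phenotype {exc.args[0]!r}") from exc

    def one_hot(self, phenotypes: Iterable[str]) -> np.ndarray:
        codes = self.codes(phenotypes)
        out = np.zeros((codes.size, len(self)), dtype=float)
        out[np.arange(codes.size), codes] = 1.0
        return out

    def category_codes(self) -> np.ndarray:
        """Category index (0=tumor, 1=immune, 2=stromal) per phenotype."""
        return np.array([CATEGORIES.index(self.category_of[n]) for n in self.names])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"phenotype": self.names,
             "category": [self.category_of[n] for n in self.names]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeVocabulary":
        return cls(tuple(df["phenotype"]), dict(zip(df["phenotype"], df["category"])))


def default_vocabulary(names: Sequence[str]) -> PhenotypeVocabulary:
    """Vocabulary with all phenotypes assigned the ``stromal`` category.

    Used when building a vocabulary from data without category annotations;
    category-dependent analyses should supply real categories.
    """
    return PhenotypeVocabulary(tuple(names), {n: "stromal" for n in names})


@dataclass
class CellTable:
    """Per-cell records of a cohort: positions in µm, phenotype, optional expression.

    ``cells`` holds the canonical columns; ``expression``, when present, is a
    DataFrame aligned row-for-row with ``cells`` whose columns are antigen
    names shared by every cell.
    """

    cells: pd.DataFrame
    vocabulary: PhenotypeVocabulary
    expression: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table missing columns: {missing}")
        xy = self.cells[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise ValueError(f"non-finite coordinate at row {bad}")
        self.vocabulary.codes(self.cells["phenotype"])  # validates membership
        if self.expression is not None:
            if len(self.expression) != len(self.cells):
                raise ValueError("expression table must align with cell table")
            self.expression = self.expression.reset_index(drop=True)
        self.cells = self.cells.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def patient_ids(self) -> list[str]:
        return list(pd.unique(self.cells["patient_id"]))

    def cells_per_patient(self) -> pd.Series:
        return self.cells.groupby("patient_id", sort=False).size()

    def for_patient(self, patient_id: str) -> "CellTable":
        mask = (self.cells["patient_id"] == patient_id).to_numpy()
        expr = self.expression[mask] if self.expression is not None else None
        return CellTable(self.cells[mask], self.vocabulary, expr)

    def subset_patients(self, patient_ids: Iterable[str]) -> "CellTable":
        keep = set(patient_ids)
        mask = self.cells["patient_id"].isin(keep).to_numpy()
        expr = self.expression[mask] if self.expression is not None else None
        return CellTable(self.cells[mask], self.vocabulary, expr)


@dataclass
class ClinicalTable:
    """Per-patient clinical records: survival time (months), event flag, covariates."""

    data: pd.DataFrame  # indexed by patient_id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate patient_id {dup!r} in clinical table")
        if "survival_time" in self.data.columns:
            t = self.data["survival_time"].dropna()
            if (t < 0).any():
                raise ValueError("survival_time must be nonnegative")
        if "event" in self.data.columns:
            ev = self.data["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise ValueError("event must be 0/1")

    def __len__(self) -> int:
        return len(self.data)

    def aligned(self, patient_ids: Sequence[str]) -> pd.DataFrame:
        missing = [p for p in patient_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"patients missing from clinical table: {missing[:5]}")
        return self.data.loc[list(patient_ids)]


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    vocabulary: PhenotypeVocabulary | None = None,
    expression_columns: Sequence[str] | None = None,
    allow_new_phenotypes: bool = False,
) -> CellTable:
    """Read and validate a per-cell CSV/TSV.

    Parameters
    ----------
    schema
        Maps canonical names (``patient_id, image_id, x, y, phenotype``) to
        the file's column names.  Unmapped canonical names use themselves.
    vocabulary
        Required unless ``allow_new_phenotypes`` is set, in which case the
        vocabulary is built from the data (sorted labels, category
        ``stromal`` placeholder).
    expression_columns
        Numeric antigen columns to load as the expression matrix.
    """
    raw = _read_table(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    cells = raw[[colmap[c] for c in CELL_COLUMNS]].copy()
    cells.columns = list(CELL_COLUMNS)
    for axis in ("x", "y"):
        coord = pd.to_numeric(cells[axis], errors="coerce")
        if coord.isna().any():
            row = int(coord.index[coord.isna()][0])
            raise ValueError(f"{path}: non-numeric or missing {axis!r} at row {row}")
        cells[axis] = coord.astype(float)
    cells["patient_id"] = cells["patient_id"].astype(str)
    cells["image_id"] = cells["image_id"].astype(str)
    cells["phenotype"] = cells["phenotype"].astype(str)
    if vocabulary is None:
        if not allow_new_phenotypes:
            raise ValueError("a vocabulary is required unless allow_new_phenotypes=True")
        vocabulary = default_vocabulary(sorted(cells["phenotype"].unique()))
    expr = None
    if expression_columns:
        missing = [c for c in expression_columns if c not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing antigen columns {missing}")
        expr = raw[list(expression_columns)].astype(float)
    return CellTable(cells, vocabulary, expr)


def read_clinical_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> ClinicalTable:
    raw = _read_table(path)
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    if "patient_id" not in raw.columns:
        raise ValueError(f"{path}: missing patient_id column")
    raw["patient_id"] = raw["patient_id"].astype(str)
    return ClinicalTable(raw.set_index("patient_id"))


# ---------------------------------------------------------------------------
# filtering


def filter_patients(cells: CellTable, min_cells: int = 500) -> CellTable:
    """Keep patients with at least ``min_cells`` cells summed over all images.

    Idempotent; excluded patient ids are logged.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    counts = cells.cells_per_patient()
    keep = counts.index[counts >= min_cells]
    dropped = counts.index.difference(keep)
    if len(dropped):
        logger.info(
            "filter_patients: excluded %d patients with < %d cells: %s",
            len(dropped), min_cells, list(dropped),
        )
    return cells.subset_patients(keep)


# ---------------------------------------------------------------------------
# artifact writers / readers (labeled TSV + YAML/JSON sidecars)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_assignments(assignments: pd.Series, path: str | Path, value_name: str = "subgroup") -> None:
    """Two-column TSV: patient_id and its assigned label."""
    df = assignments.rename(value_name).rename_axis("patient_id").reset_index()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path, value_name: str = "subgroup") -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return df.set_index("patient_id")[value_name]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write cells (and expression columns, if any) to one CSV at full precision."""
    df = table.cells.copy()
    if table.expression is not None:
        df = pd.concat([df, table.expression], axis=1)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # repr-roundtrip float format so read-back is bit-exact
    df.to_csv(path, index=False, float_format="%.17g")


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.rename_axis("patient_id").to_csv(path, float_format="%.17g")
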