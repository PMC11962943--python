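"""Characteristic-pattern identification and niche categorization.

A pattern is *characteristic* of a subgroup when its Hodges-Lehmann
statistic — the median of all pairwise differences between in-group and
out-group patient proportions — strictly exceeds half the subgroup's
maximum statistic.  Patterns are categorized as tumor / immune / stromal
niches when one phenotype category carries at least half the signature
mass, otherwise as interface niches (mixed composition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CATEGORIES, PhenotypeVocabulary

logger = logging.getLogger(__name__)

NICHE_CATEGORIES = CATEGORIES + ("interface",)


def normalize_histograms(histograms: pd.DataFrame) -> pd.DataFrame:
    """Per-patient pattern proportions: each row divided by its total count."""
    totals = histograms.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"patient {bad!r} has a zero-count histogram")
    return histograms.div(totals, axis=0)


def hodges_lehmann(in_group: np.ndarray, out_group: np.ndarray) -> float:
    """Median of all pairwise differences (in - out) over the full grid."""
    a = np.asarray(in_group, dtype=float)
    b = np.asarray(out_group, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(np.median(a[:, None] - b[None, :]))


@dataclass
class CharacteristicReport:
    """Hodges-Lehmann statistics and selected characteristic patterns per subgroup."""

    statistics: pd.DataFrame  # subgroups × patterns
    hl_fraction: float
    selected: dict[str, list[str]]  # subgroup -> selected pattern names
    thresholds: pd.Series  # subgroup -> hl_fraction * max statistic

    def to_frame(self) -> pd.DataFrame:
        long = self.statistics.stack().rename("hl_statistic").rename_axis(
            ["subgroup", "pattern"]
        ).reset_index()
        long["selected"] = [
            p in self.selected[str(g)] for g, p in zip(long["subgroup"], long["pattern"])
        ]
        return long


def select_characteristic(
    statistics: pd.DataFrame, hl_fraction: float = 0.5
) -> CharacteristicReport:
    """Select patterns whose statistic strictly exceeds ``hl_fraction`` × subgroup max.

    A subgroup whose maximum statistic is <= 0 selects nothing (flagged in
    the log): no pattern is enriched there.
    """
    selected: dict[str, list[str]] = {}
    thresholds = {}
    for group, row in statistics.iterrows():
        gmax = row.max()
        thr = hl_fraction * gmax
        thresholds[str(group)] = thr
        if gmax <= 0:
            logger.warning("subgroup %s: no positively enriched pattern", group)
            selected[str(group)] = []
        else:
            selected[str(group)] = list(row.index[row > thr])
    return CharacteristicReport(
        statistics=statistics,
        hl_fraction=hl_fraction,
        selected=selected,
        thresholds=pd.Series(thresholds, name="threshold"),
    )


def characteristic_patterns(
    proportions: pd.DataFrame, subgroups: pd.Series, hl_fraction: float = 0.5
) -> CharacteristicReport:
    """Full per-subgroup report from patient proportions and subgroup labels."""
    stats = {}
    for group in sorted(subgroups.unique()):
        in_ids = subgroups.index[subgroups == group]
        out_ids = subgroups.index[subgroups != group]
        if len(out_ids) == 0:
            raise ValueError("need at least two subgroups")
        stats[str(group)] = {
            pat: hodges_lehmann(
                proportions.loc[in_ids, pat].to_numpy(),
                proportions.loc[out_ids, pat].to_numpy(),
            )
            for pat in proportions.columns
        }
    statistics = pd.DataFrame.from_dict(stats, orient="index")[proportions.columns]
    return select_characteristic(statistics, hl_fraction)


def categorize_patterns(
    signatures: np.ndarray,
    vocabulary: PhenotypeVocabulary,
    interface_cutoff: float = 0.5,
) -> np.ndarray:
    """Assign each pattern a niche category from its signature's category mass.

    Signature mass is summed per phenotype category and normalized; the
    pattern is the argmax category when that share is >= ``interface_cutoff``
    and an ``interface`` niche otherwise.
    """
    S = np.asarray(signatures, dtype=float)
    cat_codes = vocabulary.category_codes()
    masses = np.zeros((S.shape[0], len(CATEGORIES)))
    for k in range(len(CATEGORIES)):
        masses[:, k] = S[:, cat_codes == k].sum(axis=1)
    totals = masses.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("zero-mass signature")
    shares = masses / totals[:, None]
    best = shares.argmax(axis=1)
    out = np.array(
        [
            CATEGORIES[b] if shares[i, b] >= interface_cutoff else "interface"
            for i, b in enumerate(best)
        ],
        dtype=object,
    )
    return out


def stratify_by_pattern(
    proportions: pd.DataFrame, pattern: str, positivity_threshold: float = 0.01
) -> pd.Series:
    """Positive/negative patient split on one pattern's proportion (positive iff >= threshold)."""
    if pattern not in proportions.columns:
        raise KeyError(f"unknown pattern {pattern!r}")
    positive = proportions[pattern] >= positivity_threshold
    if positive.all() or (~positive).all():
        logger.warning(
            "stratify_by_pattern: %s yields a one-sided split (%d positive of %d)",
            pattern, int(positive.sum()), len(positive),
        )
    return positive.rename("positive")
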