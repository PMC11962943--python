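"""Comparator patient representations sharing the downstream kernel pipeline.

Alternative feature vectors φ(G) swapped into the cosine-similarity kernel:
phenotype abundance, mean pairwise phenotype proximity, niche-category
abundance, and the classic Weisfeiler-Lehman subtree kernel on binarized
graphs (color refinement shared across all graphs, with either accumulated
or last-iteration color counts).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cellular_graph import CellularGraph, binarize_graph
from .io import CellTable, PhenotypeVocabulary
from .patterns import NICHE_CATEGORIES

logger = logging.getLogger(__name__)

SCHEMES = ("cell_abundance", "pairwise_proximity", "category_abundance",
           "wl_accumulated", "wl_last")


def cell_abundance(cells: CellTable) -> np.ndarray:
    """Histogram of cell phenotypes (length m, vocabulary order)."""
    codes = cells.vocabulary.codes(cells.cells["phenotype"])
    return np.bincount(codes, minlength=len(cells.vocabulary)).astype(float)


def pairwise_proximity(cells: CellTable, alpha: float = 0.01) -> np.ndarray:
    """Mean Gaussian proximity per unordered phenotype pair, length m(m-1)/2.

    Averages exp(-alpha d²) over all cross-phenotype cell pairs within the
    same image (cross-image weights are zero by construction, so such pairs
    are excluded from both numerator and count).  Pairs with no cell pair
    present are reported as 0 and logged.
    """
    vocab = cells.vocabulary
    m = len(vocab)
    df = cells.cells
    codes = vocab.codes(df["phenotype"])
    xy = df[["x", "y"]].to_numpy(dtype=float)
    images = df["image_id"].to_numpy()
    sums = np.zeros((m, m))
    counts = np.zeros((m, m), dtype=np.int64)
    for img in np.unique(images):
        sel = images == img
        c, p = codes[sel], xy[sel]
        for a, b in itertools.combinations(range(m), 2):
            pa, pb = p[c == a], p[c == b]
            if len(pa) == 0 or len(pb) == 0:
                continue
            w = np.exp(-alpha * cdist(pa, pb) ** 2)
            sums[a, b] += w.sum()
            counts[a, b] += w.size
    out = np.zeros(m * (m - 1) // 2)
    for k, (a, b) in enumerate(itertools.combinations(range(m), 2)):
        if counts[a, b] == 0:
            logger.warning(
                "pairwise_proximity: no (%s, %s) cell pairs; proximity set to 0",
                vocab.names[a], vocab.names[b],
            )
        else:
            out[k] = sums[a, b] / counts[a, b]
    return out


def proximity_pair_names(vocabulary: PhenotypeVocabulary) -> list[str]:
    return [f"{a}|{b}" for a, b in itertools.combinations(vocabulary.names, 2)]


def category_abundance(
    pattern_labels: np.ndarray, category_of_pattern: np.ndarray
) -> np.ndarray:
    """Histogram over the four niche categories of one patient's subtrees.

    ``pattern_labels`` are 1-based pattern ids; ``category_of_pattern[c-1]``
    is the niche category of pattern c.
    """
    labels = np.asarray(pattern_labels)
    cats = np.asarray(category_of_pattern)
    out = np.zeros(len(NICHE_CATEGORIES))
    for k, cat in enumerate(NICHE_CATEGORIES):
        patterns = np.flatnonzero(cats == cat) + 1
        out[k] = np.isin(labels, patterns).sum()
    return out


# ---------------------------------------------------------------------------
# classic WL subtree kernel on binarized graphs


@dataclass
class ColorTable:
    """Global relabeling table shared by every graph in the cohort.

    Colors are consecutive integers; ``per_iteration[h]`` lists the colors
    first minted at refinement iteration h, so feature vectors can be laid
    out per iteration.
    """

    table: dict[object, int] = field(default_factory=dict)
    per_iteration: list[list[int]] = field(default_factory=list)

    def intern(self, key: object, iteration: int) -> int:
        while len(self.per_iteration) <= iteration:
            self.per_iteration.append([])
        if key not in self.table:
            color = len(self.table)
            self.table[key] = color
            self.per_iteration[iteration].append(color)
        return self.table[key]


def wl_color_refinement(
    graphs: list[tuple[np.ndarray, np.ndarray]], h: int = 2
) -> tuple[list[np.ndarray], ColorTable]:
    """WL color refinement run jointly over a cohort of binary graphs.

    Each graph is (boolean adjacency without self-loops, integer initial
    labels).  Iteration 0 interns the initial labels; iteration t relabels
    each node by (previous color, sorted multiset of neighbor colors).  Two
    nodes share a color at iteration t iff their depth-t rooted subtrees
    are isomorphic.  Returns per-graph arrays of shape (h+1, N).
    """
    table = ColorTable()
    colorings = []
    for adj, labels in graphs:
        labels = np.asarray(labels)
        n = labels.size
        colors = np.empty((h + 1, n), dtype=np.int64)
        colors[0] = [table.intern(("init", int(l)), 0) for l in labels]
        colorings.append(colors)
    adjacency = [np.asarray(adj, dtype=bool) for adj, _ in graphs]
    for t in range(1, h + 1):
        for colors, adj in zip(colorings, adjacency):
            prev = colors[t - 1]
            for v in range(len(prev)):
                key = (int(prev[v]), tuple(sorted(int(c) for c in prev[adj[v]])))
                colors[t, v] = table.intern(key, t)
    return colorings, table


def wl_features(
    colorings: list[np.ndarray], table: ColorTable, mode: str = "accumulated"
) -> np.ndarray:
    """Per-graph color-count features from a joint refinement.

    ``accumulated`` concatenates color counts over iterations 0..h;
    ``last`` keeps only the final iteration's colors.
    """
    if mode not in {"accumulated", "last"}:
        raise ValueError(f"mode must be 'accumulated' or 'last', got {mode!r}")
    if mode == "accumulated":
        cols = [c for it in table.per_iteration for c in it]
    else:
        cols = list(table.per_iteration[-1])
    pos = {c: k for k, c in enumerate(cols)}
    iters = range(len(table.per_iteration)) if mode == "accumulated" else [len(table.per_iteration) - 1]
    out = np.zeros((len(colorings), len(cols)))
    for g, colors in enumerate(colorings):
        for t in iters:
            for c in colors[t]:
                if int(c) in pos:
                    out[g, pos[int(c)]] += 1
    return out


def wl_profiles(
    graphs: list[CellularGraph], h: int = 2, threshold: float = 0.01,
    mode: str = "accumulated",
) -> np.ndarray:
    """Convenience: binarize a cohort of cellular graphs and build WL features."""
    binary = [
        (binarize_graph(g, threshold), g.phenotype_codes) for g in graphs
    ]
    colorings, table = wl_color_refinement(binary, h=h)
    return wl_features(colorings, table, mode=mode)
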