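"""Pairwise morphological dissimilarity and patristic distance.

Dissimilarity follows the MORD convention: for each pair of taxa, only
characters scored in both are compared; the dissimilarity is the mean
per-character difference over those characters.  An unordered character
differs (1) when the two state sets are disjoint and matches (0) when they
intersect, so polymorphisms sharing a state count as matches.  An ordered
character contributes the minimum absolute state difference between the two
sets, rescaled by that character's observed state range, keeping every
character's contribution in [0, 1].  Pairs with no comparable characters
are undefined (NaN) and are dropped before curve fitting, never imputed.

Patristic morphological distance between two taxa is the sum of branch
lengths (expected character changes) on the tree path connecting them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix, MatrixValidationError
from .trees import ChangesTree, TimeTree

__all__ = [
    "DistanceMatrix",
    "mord_dissimilarity",
    "patristic_distances",
    "build_pair_table",
    "filter_pairs_by_divergence",
    "write_pair_table",
    "read_pair_table",
]

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["taxon_a", "taxon_b", "D", "P", "mrca_age", "group_a", "group_b"]


@dataclass
class DistanceMatrix:
    """Symmetric taxon-pair distances; NaN marks undefined entries."""

    taxa: list
    values: np.ndarray
    kind: str  # "dissimilarity" | "patristic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def subset(self, names) -> "DistanceMatrix":
        idx = [self.taxa.index(n) for n in names]
        return DistanceMatrix(list(names), self.values[np.ix_(idx, idx)], self.kind)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.taxa, columns=self.taxa).to_csv(path)


# ---------------------------------------------------------------------------
# MORD dissimilarity
# ---------------------------------------------------------------------------

def _encode_bitmasks(matrix: CharacterMatrix, char_idx) -> np.ndarray:
    """(n_taxa, n_sel) uint32 bitmask of state sets; 0 = not scored."""
    out = np.zeros((matrix.n_taxa, len(char_idx)), dtype=np.uint32)
    for i, row in enumerate(matrix.cells):
        for col, j in enumerate(char_idx):
            cell = row[j]
            if isinstance(cell, frozenset):
                mask = 0
                for s in cell:
                    mask |= 1 << s
                out[i, col] = mask
    return out


def mord_dissimilarity(matrix: CharacterMatrix, partition: str = None) -> DistanceMatrix:
    """Maximum observable rescaled distance between all taxon pairs."""
    if matrix.n_taxa < 2:
        raise MatrixValidationError("dissimilarity needs at least 2 taxa")
    if partition is not None:
        char_idx = matrix.char_indices_for_partition(partition)
        if not char_idx:
            raise MatrixValidationError(f"no characters carry partition {partition!r}")
    else:
        char_idx = list(range(matrix.n_chars))

    unordered = [j for j in char_idx if not matrix.ordered[j]]
    ordered = [j for j in char_idx if matrix.ordered[j]]

    n = matrix.n_taxa
    diff_sum = np.zeros((n, n))
    comp_sum = np.zeros((n, n))

    if unordered:
        A = _encode_bitmasks(matrix, unordered)
        scored = A != 0
        comp = scored[:, None, :] & scored[None, :, :]
        disjoint = (A[:, None, :] & A[None, :, :]) == 0
        diff_sum += np.sum(comp & disjoint, axis=2)
        comp_sum += np.sum(comp, axis=2)

    for j in ordered:
        rng = matrix.state_range(j)
        lo = np.full(n, np.nan)
        hi = np.full(n, np.nan)
        for i, row in enumerate(matrix.cells):
            cell = row[j]
            if isinstance(cell, frozenset):
                lo[i], hi[i] = min(cell), max(cell)
        scored = ~np.isnan(lo)
        comp = scored[:, None] & scored[None, :]
        # min |a-b| over the two sets, assuming contiguous coding within range
        gap = np.maximum(lo[:, None] - hi[None, :], lo[None, :] - hi[:, None])
        gap = np.maximum(gap, 0.0)
        scaled = np.zeros((n, n)) if rng == 0 else gap / rng
        diff_sum += np.where(comp, scaled, 0.0)
        comp_sum += comp

    with np.errstate(invalid="ignore", divide="ignore"):
        D = diff_sum / comp_sum
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(matrix.taxa), D, "dissimilarity")


def dissimilarity_from_states(states: np.ndarray, scored: np.ndarray, taxa=None):
    """MORD for fully resolved (singleton-state) matrices given as arrays.

    ``states`` is (n_taxa, n_chars) integer states; ``scored`` the boolean
    scored mask.  This is the fast path used by null simulations.
    """
    comp = scored[:, None, :] & scored[None, :, :]
    diff = states[:, None, :] != states[None, :, :]
    comp_sum = comp.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(comp, diff, False).sum(axis=2) / comp_sum
    np.fill_diagonal(D, 0.0)
    if taxa is None:
        return D
    return DistanceMatrix(list(taxa), D, "dissimilarity")


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

def patristic_distances(tree: ChangesTree) -> DistanceMatrix:
    """Sum of branch lengths on the path between every pair of tips."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    labels = tree.taxon_labels
    tx = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tx[labels[i]], tx[labels[j]])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out, "patristic")


# ---------------------------------------------------------------------------
# Pair table
# ---------------------------------------------------------------------------

def build_pair_table(
    D: DistanceMatrix,
    P: DistanceMatrix,
    time_tree: TimeTree = None,
    metadata: pd.DataFrame = None,
    scope=None,
) -> pd.DataFrame:
    """Join dissimilarity, patristic distance, and MRCA age per taxon pair.

    Rows whose dissimilarity is undefined are dropped (count logged).
    """
    names = list(scope) if scope is not None else list(D.taxa)
    missing_d = set(names) - set(D.taxa)
    missing_p = set(names) - set(P.taxa)
    if missing_d or missing_p:
        raise ValueError(
            f"scope taxa absent: {sorted(missing_d | missing_p)}"
        )
    Dm = D.subset(names).values
    Pm = P.subset(names).values
    if time_tree is not None:
        extra = set(names) - set(time_tree.taxon_labels)
        if extra:
            raise ValueError(f"taxa absent from time tree: {sorted(extra)}")
        ages = time_tree.mrca_age_matrix(names)
    else:
        ages = np.full((len(names), len(names)), np.nan)

    rows = []
    n_dropped = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = Dm[i, j]
            if np.isnan(d):
                n_dropped += 1
                continue
            ga = gb = None
            if metadata is not None and "clade" in metadata.columns:
                ga = metadata["clade"].get(names[i])
                gb = metadata["clade"].get(names[j])
            rows.append((names[i], names[j], d, Pm[i, j], ages[i, j], ga, gb))
    if n_dropped:
        logger.info("dropped %d pairs with undefined dissimilarity", n_dropped)
    table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if table.empty:
        warnings.warn("pair table is empty: no pair had comparable characters")
    return table


def filter_pairs_by_divergence(pairs: pd.DataFrame, window) -> pd.DataFrame:
    """Keep pairs whose MRCA age falls in the [old, young] Ma window."""
    old, young = window
    if not old > young:
        raise ValueError(f"window must be (old, young) with old > young, got {window}")
    keep = (pairs["mrca_age"] >= young) & (pairs["mrca_age"] <= old)
    return pairs.loc[keep].reset_index(drop=True)


def write_pair_table(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, columns=PAIR_COLUMNS)


def read_pair_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
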