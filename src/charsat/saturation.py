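"""Character-state saturation and evolutionary constraint.

Morphological dissimilarity D between two taxa grows with the amount of
evolutionary change separating them (patristic distance P) until homoplasy
re-explores an established state space and the relationship asymptotes —
character-state exhaustion.  A Michaelis-Menten curve

    D = Vmax * P / (Km + P)

is fitted to the (P, D) pairs of a clade; its asymptote Vmax indexes the
saturation level.  Constraint is judged against an equal-rates null: matrices
are simulated character by character under a k-state Mk process along the
changes-scaled tree (k = the character's observed state count), the
empirical missing-data mask is re-applied, and the null Vmax distribution is
built from re-fitted curves against the same patristic distances.  A clade
whose observed 84% CI falls entirely above the null's central 84% interval
shows relaxed constraint; entirely below, strengthened constraint.  84%
intervals are used because two such intervals of statistically identical
estimators overlap ~95% of the time, giving an effective 0.05 threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dissimilarity import dissimilarity_from_states, mord_dissimilarity, patristic_distances
from .matrix import INAPPLICABLE, MISSING, CharacterMatrix
from .trees import ChangesTree, TimeTree

__all__ = [
    "MichaelisMentenFit",
    "NullVmaxDistribution",
    "ConstraintCall",
    "MIN_PAIRS",
    "fit_michaelis_menten",
    "simulate_null_matrix",
    "null_vmax_distribution",
    "classify_constraint",
    "constraint_test",
    "scan_all_nodes",
    "scan_to_frame",
    "ci_overlap_calibration",
]

logger = logging.getLogger(__name__)

#: Minimum usable pairs for a 2-parameter fit with a meaningful CI.
MIN_PAIRS = 6

_Z84 = stats.norm.ppf(0.92)  # ~1.4051

#: Identifiability guard: dissimilarity is bounded by 1, so an asymptote
#: estimate this far above the data means the curve never bent within the
#: observed range and Vmax is not identifiable (fit reported unconverged).
VMAX_CAP = 10.0


@dataclass
class MichaelisMentenFit:
    vmax: float
    km: float
    vmax_ci84: tuple
    n_pairs: int
    converged: bool
    residual_ss: float

    @classmethod
    def untestable(cls, n_pairs: int = 0) -> "MichaelisMentenFit":
        return cls(np.nan, np.nan, (np.nan, np.nan), n_pairs, False, np.nan)


@dataclass
class NullVmaxDistribution:
    values: np.ndarray
    n_sims: int
    central84: tuple
    median: float
    n_failed: int = 0

    @classmethod
    def from_values(cls, values, n_failed: int = 0) -> "NullVmaxDistribution":
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            return cls(values, 0, (np.nan, np.nan), np.nan, n_failed)
        lo, hi = np.percentile(values, [8.0, 92.0])
        return cls(values, int(values.size), (float(lo), float(hi)),
                   float(np.median(values)), n_failed)


@dataclass
class ConstraintCall:
    node_id: str
    observed: MichaelisMentenFit
    null: NullVmaxDistribution
    call: str  # relaxed | strengthened | none | untestable
    n_tips: int = 0
    tips: tuple = field(default=(), repr=False)
    label: str = ""


# ---------------------------------------------------------------------------
# Michaelis-Menten fitting (log-parameterized nonlinear least squares)
# ---------------------------------------------------------------------------

def _mm(theta, P):
    vmax, km = np.exp(theta)
    return vmax * P / (km + P)


def _fit_mm_arrays(P: np.ndarray, D: np.ndarray, min_pairs: int = MIN_PAIRS) -> MichaelisMentenFit:
    """Core least-squares fit on arrays; log-parameterization keeps both
    parameters positive.  Underdetermined data yields an untestable fit."""
    P = np.asarray(P, dtype=float)
    D = np.asarray(D, dtype=float)
    ok = np.isfinite(P) & np.isfinite(D)
    P, D = P[ok], D[ok]
    n = P.size
    if n < min_pairs or np.unique(P).size < 3:
        return MichaelisMentenFit.untestable(n)
    if np.all(D <= 1e-12):  # flat-zero data: asymptote is exactly zero
        return MichaelisMentenFit(0.0, 0.0, (0.0, 0.0), n, True, 0.0)

    def resid(theta):
        return _mm(theta, P) - D

    def jac(theta):
        vmax, km = np.exp(theta)
        m = vmax * P / (km + P)
        return np.column_stack([m, -m * km / (km + P)])

    dmax = max(D.max(), 1e-6)
    starts = [
        (np.log(dmax * 1.05), np.log(max(np.median(P), 1e-6))),
        (np.log(dmax * 2.0), np.log(max(P.max(), 1e-6))),
        (np.log(dmax * 1.05), np.log(max(P.min(), 1e-6))),
    ]
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                resid, x0, jac=jac, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return MichaelisMentenFit.untestable(n)

    vmax, km = np.exp(best.x)
    if vmax > VMAX_CAP:
        return MichaelisMentenFit(float(vmax), float(km), (np.nan, np.nan),
                                  n, False, float(2 * best.cost))
    ssr = float(2 * best.cost)
    J = jac(best.x)
    dof = max(n - 2, 1)
    s2 = ssr / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se_log_vmax = np.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        return MichaelisMentenFit(vmax, km, (np.nan, np.nan), n, False, ssr)
    se_vmax = vmax * se_log_vmax  # delta method from the log scale
    ci = (vmax - _Z84 * se_vmax, vmax + _Z84 * se_vmax)
    return MichaelisMentenFit(float(vmax), float(km), ci, n, True, ssr)


def fit_michaelis_menten(pairs, min_pairs: int = MIN_PAIRS) -> MichaelisMentenFit:
    """Fit the saturation curve to a pair table (columns D, P) or to a
    ``(P, D)`` pair of arrays."""
    if isinstance(pairs, pd.DataFrame):
        P, D = pairs["P"].to_numpy(), pairs["D"].to_numpy()
    else:
        P, D = pairs
    return _fit_mm_arrays(P, D, min_pairs=min_pairs)


def _fit_mm_batch(P: np.ndarray, Dmat: np.ndarray, max_iter: int = 120):
    """Batched Levenberg-Marquardt on (log Vmax, log Km) for many curves
    sharing one abscissa.  Returns (vmax, converged) arrays.

    Used for null distributions where thousands of 2-parameter fits are
    needed; unit-tested against the scipy single-fit route.
    """
    P = np.asarray(P, dtype=float)
    Dmat = np.asarray(Dmat, dtype=float)
    S, n = Dmat.shape
    dmax = np.maximum(Dmat.max(axis=1), 1e-6)
    theta = np.column_stack([np.log(dmax * 1.05),
                             np.full(S, np.log(max(np.median(P), 1e-6)))])
    lam = np.full(S, 1e-3)
    flat = np.all(Dmat <= 1e-12, axis=1)

    def ssr_of(th):
        vmax = np.exp(th[:, 0])[:, None]
        km = np.exp(th[:, 1])[:, None]
        r = vmax * P[None, :] / (km + P[None, :]) - Dmat
        return np.sum(r * r, axis=1)

    ssr = ssr_of(theta)
    for _ in range(max_iter):
        vmax = np.exp(theta[:, 0])[:, None]
        km = np.exp(theta[:, 1])[:, None]
        m = vmax * P[None, :] / (km + P[None, :])
        r = m - Dmat
        j0 = m
        j1 = -m * km / (km + P[None, :])
        g0 = np.sum(j0 * r, axis=1)
        g1 = np.sum(j1 * r, axis=1)
        a = np.sum(j0 * j0, axis=1)
        b = np.sum(j0 * j1, axis=1)
        c = np.sum(j1 * j1, axis=1)
        a_l = a * (1 + lam)
        c_l = c * (1 + lam)
        det = a_l * c_l - b * b
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d0 = (c_l * g0 - b * g1) / det
        d1 = (a_l * g1 - b * g0) / det
        step = np.clip(np.column_stack([d0, d1]), -4.0, 4.0)
        trial = theta - step
        ssr_trial = ssr_of(trial)
        accept = ssr_trial <= ssr
        theta = np.where(accept[:, None], trial, theta)
        lam = np.where(accept, lam / 3.0, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e9)
        moved = np.max(np.abs(step), axis=1)
        ssr = np.where(accept, ssr_trial, ssr)
        if np.all(moved < 1e-10):
            break
    vmax = np.exp(theta[:, 0])
    vmax = np.where(flat, 0.0, vmax)
    converged = np.isfinite(vmax) & (vmax <= VMAX_CAP)
    return vmax, converged


# ---------------------------------------------------------------------------
# Null-matrix simulation (equal-rates Mk along the changes tree)
# ---------------------------------------------------------------------------

def _template_arrays(template: CharacterMatrix):
    """Observed-state count per character (k >= 2) and scored mask."""
    k = np.array([max(template.n_observed_states(j), 2) for j in range(template.n_chars)])
    scored = template.missing_mask()
    return k, scored


def _simulate_states(tree: ChangesTree, k: np.ndarray, rng: np.random.Generator,
                     taxa_order: list) -> np.ndarray:
    """Evolve each character under an equal-rates k-state Markov process.

    Branch lengths are expected character changes; for the k-state ER model
    with total leaving rate matched to the branch length b, the probability
    of ending in the starting state is 1/k + (k-1)/k * exp(-k b / (k-1)).
    """
    n_chars = k.size
    states = {}
    root = tree.tree.seed_node
    states[root] = rng.integers(0, k)
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        b = nd.edge.length if nd.edge.length is not None else 0.0
        parent = states[nd.parent_node]
        p_same = 1.0 / k + (k - 1.0) / k * np.exp(-k * b / (k - 1.0))
        stay = rng.random(n_chars) < p_same
        jump = (parent + rng.integers(1, k)) % k
        states[nd] = np.where(stay, parent, jump)
    by_label = {lf.taxon.label: states[lf] for lf in tree.tree.leaf_node_iter()}
    try:
        return np.vstack([by_label[t] for t in taxa_order])
    except KeyError as exc:
        raise ValueError(f"taxon {exc} missing from changes tree") from exc


def simulate_null_matrix(changes_tree: ChangesTree, template: CharacterMatrix,
                         seed) -> CharacterMatrix:
    """One equal-rates null matrix with the template's missing cells masked.

    Each character uses k = its observed state count in the template
    (invariant characters use k=2, the minimal space admitting change);
    the root state is uniform.
    """
    rng = np.random.default_rng(seed)
    k, scored = _template_arrays(template)
    states = _simulate_states(changes_tree, k, rng, list(template.taxa))
    cells = []
    for i, taxon in enumerate(template.taxa):
        row = []
        for j in range(template.n_chars):
            if scored[i, j]:
                row.append(frozenset({int(states[i, j])}))
            else:
                row.append(template.cells[i][j])  # MISSING or INAPPLICABLE
        cells.append(row)
    return CharacterMatrix(taxa=list(template.taxa), cells=cells)


def _simulated_dissimilarities(changes_tree, template, n_sims, rng):
    """(n_sims, n, n) stack of full null dissimilarity matrices."""
    k, scored = _template_arrays(template)
    taxa = list(template.taxa)
    out = np.empty((n_sims, len(taxa), len(taxa)))
    for s in range(n_sims):
        states = _simulate_states(changes_tree, k, rng, taxa)
        out[s] = dissimilarity_from_states(states, scored)
    return out


def null_vmax_distribution(changes_tree: ChangesTree, template: CharacterMatrix,
                           scope=None, n_sims: int = 1000, seed=0,
                           pair_mask: np.ndarray = None) -> NullVmaxDistribution:
    """Distribution of null-model Vmax.

    Each simulation: evolve a null matrix, compute dissimilarities within
    ``scope``, pair them with the *empirical* patristic distances, and fit
    the saturation curve.  ``pair_mask`` (boolean, n x n over scope taxa)
    optionally restricts pairs, e.g. to a divergence window.
    """
    rng = np.random.default_rng(seed)
    taxa = list(template.taxa)
    scope = list(scope) if scope is not None else taxa
    idx = np.array([taxa.index(t) for t in scope])
    P_full = patristic_distances(changes_tree).subset(taxa).values
    iu = np.triu_indices(len(scope), k=1)
    keep = np.ones(len(iu[0]), dtype=bool)
    if pair_mask is not None:
        keep &= pair_mask[iu]
    P_pairs = P_full[np.ix_(idx, idx)][iu]
    sims = _simulated_dissimilarities(changes_tree, template, n_sims, rng)
    D_pairs = sims[:, idx[:, None], idx[None, :]][:, iu[0], iu[1]]
    defined = np.all(np.isfinite(D_pairs), axis=0)
    keep &= defined
    vmax, conv = _fit_mm_batch(P_pairs[keep], D_pairs[:, keep])
    ok = conv & np.isfinite(vmax)
    n_failed = int(n_sims - ok.sum())
    if n_failed > 0.2 * n_sims:
        warnings.warn(f"{n_failed}/{n_sims} null fits failed to converge")
    return NullVmaxDistribution.from_values(vmax[ok], n_failed=n_failed)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_constraint(observed: MichaelisMentenFit, null: NullVmaxDistribution,
                        node_id: str = "", null_band: str = "central") -> ConstraintCall:
    """Compare the observed Vmax CI with the null band.

    ``central`` (default): the null band is the central 84% interval
    (8th-92nd percentiles), a symmetric two-sided reading.  ``one_sided``:
    relaxed is judged against the 84th percentile and strengthened against
    the 16th.
    """
    if not observed.converged or null.n_sims < 20:
        # too few converged null fits to place an 84% band
        return ConstraintCall(node_id, observed, null, "untestable",
                              n_tips=0)
    if null_band == "central":
        lo, hi = null.central84
    elif null_band == "one_sided":
        lo, hi = np.percentile(null.values, [16.0, 84.0])
    else:
        raise ValueError(f"unknown null_band {null_band!r}")
    ci_lo, ci_hi = observed.vmax_ci84
    if ci_lo > hi:
        call = "relaxed"
    elif ci_hi < lo:
        call = "strengthened"
    else:
        call = "none"
    return ConstraintCall(node_id, observed, null, call)


def constraint_test(matrix: CharacterMatrix, changes_tree: ChangesTree,
                    time_tree: TimeTree = None, scope=None, n_sims: int = 1000,
                    seed=0, window=None, partition: str = None,
                    min_pairs: int = MIN_PAIRS) -> ConstraintCall:
    """Full constraint pipeline for one named taxon subset.

    Observed: MORD dissimilarity vs patristic distance, Michaelis-Menten
    Vmax with an 84% CI.  Null: ``n_sims`` equal-rates simulations.  An
    optional (old, young) Ma divergence window drops pairs whose MRCA falls
    outside the study interval.
    """
    work = matrix if partition is None else matrix.subset_chars(
        matrix.char_indices_for_partition(partition))
    taxa = list(work.taxa)
    scope = list(scope) if scope is not None else taxa
    idx = [taxa.index(t) for t in scope]
    D = mord_dissimilarity(work).values[np.ix_(idx, idx)]
    P = patristic_distances(changes_tree).subset(taxa).values[np.ix_(idx, idx)]
    pair_mask = None
    if window is not None:
        if time_tree is None:
            raise ValueError("a time tree is required for a divergence window")
        old, young = window
        if not old > young:
            raise ValueError("window must be (old, young) with old > young")
        ages = time_tree.mrca_age_matrix(scope)
        pair_mask = (ages >= young) & (ages <= old)
    iu = np.triu_indices(len(scope), k=1)
    keep = np.isfinite(D[iu])
    if pair_mask is not None:
        keep &= pair_mask[iu]
    observed = _fit_mm_arrays(P[iu][keep], D[iu][keep], min_pairs=min_pairs)
    null = null_vmax_distribution(changes_tree, work, scope=scope, n_sims=n_sims,
                                  seed=seed, pair_mask=pair_mask)
    call = classify_constraint(observed, null, node_id="clade")
    call.n_tips = len(scope)
    call.tips = tuple(scope)
    return call


# ---------------------------------------------------------------------------
# Node-wise scan
# ---------------------------------------------------------------------------

def scan_all_nodes(time_tree: TimeTree, changes_tree: ChangesTree,
                   matrix: CharacterMatrix, n_sims: int = 1000, seed=0,
                   pair_window=None, min_pairs: int = MIN_PAIRS,
                   null_band: str = "central") -> list:
    """Constraint call for every internal node, without prior hypotheses.

    Each node is tested with only the tip pairs descending from it; the
    same bank of ``n_sims`` simulated null matrices supplies every node's
    null distribution.  Nodes with too few usable pairs are untestable.
    """
    taxa = list(matrix.taxa)
    missing = set(taxa) - set(time_tree.taxon_labels)
    if missing or set(taxa) - set(changes_tree.taxon_labels):
        raise ValueError("matrix taxa must all appear in both trees")
    index = {t: i for i, t in enumerate(taxa)}
    rng = np.random.default_rng(seed)

    D_emp = mord_dissimilarity(matrix).values
    P = patristic_distances(changes_tree).subset(taxa).values
    ages = time_tree.mrca_age_matrix(taxa)
    sims = _simulated_dissimilarities(changes_tree, matrix, n_sims, rng)

    window_ok = None
    if pair_window is not None:
        old, young = pair_window
        if not old > young:
            raise ValueError("pair_window must be (old, young) with old > young")
        window_ok = (ages >= young) & (ages <= old)

    calls = []
    for node in time_tree.internal_nodes():
        tips = [t for t in time_tree.tip_labels_under(node)]
        ii = np.array([index[t] for t in tips])
        n_tips = len(tips)
        iu = np.triu_indices(n_tips, k=1)
        rows, cols = ii[iu[0]], ii[iu[1]]
        keep = np.isfinite(D_emp[rows, cols])
        if window_ok is not None:
            keep &= window_ok[rows, cols]
        rows, cols = rows[keep], cols[keep]
        node_id = node.node_id
        if rows.size < min_pairs or np.unique(P[rows, cols]).size < 3:
            call = ConstraintCall(node_id, MichaelisMentenFit.untestable(rows.size),
                                  NullVmaxDistribution.from_values([]),
                                  "untestable", n_tips=n_tips, tips=tuple(tips))
            calls.append(call)
            continue
        observed = _fit_mm_arrays(P[rows, cols], D_emp[rows, cols], min_pairs=min_pairs)
        D_null = sims[:, rows, cols]
        vmax, conv = _fit_mm_batch(P[rows, cols], D_null)
        ok = conv & np.isfinite(vmax)
        null = NullVmaxDistribution.from_values(vmax[ok], n_failed=int(n_sims - ok.sum()))
        call = classify_constraint(observed, null, node_id=node_id, null_band=null_band)
        call.n_tips = n_tips
        call.tips = tuple(tips)
        calls.append(call)
    return calls


def scan_to_tsv(calls, path) -> None:
    scan_to_frame(calls).to_csv(path, sep="\t", index=False)


def scan_annotations(calls) -> dict:
    """Per-node metadata (``node_id -> {vmax, call}``) for tree export."""
    return {c.node_id: dict(call=c.call, vmax=round(c.observed.vmax, 6)
                            if np.isfinite(c.observed.vmax) else "NA")
            for c in calls}


def scan_to_frame(calls) -> pd.DataFrame:
    """Tidy scan results (one row per node), ready for TSV export."""
    rows = []
    for c in calls:
        lo, hi = c.observed.vmax_ci84
        nlo, nhi = c.null.central84
        rows.append(dict(node_id=c.node_id, clade_label=c.label, n_tips=c.n_tips,
                         vmax=c.observed.vmax, ci_lo=lo, ci_hi=hi,
                         null_lo=nlo, null_med=c.null.median, null_hi=nhi,
                         n_pairs=c.observed.n_pairs, call=c.call))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CI-overlap calibration
# ---------------------------------------------------------------------------

def ci_overlap_calibration(level: float, n_reps: int = 10000, seed=0) -> float:
    """Fraction of overlapping level-% CIs for two identical estimators.

    Draws pairs of independent normal mean estimates with equal SE and equal
    true means, builds symmetric level-% confidence intervals, and returns
    the overlap frequency.  With 84% intervals this is ~0.95 (an effective
    0.05 threshold); with 95% intervals ~0.99.
    """
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(0.5 + level / 200.0)
    # difference of two standard-normal estimates has SD sqrt(2)
    diff = rng.standard_normal(n_reps) * np.sqrt(2.0)
    return float(np.mean(np.abs(diff) <= 2.0 * z))
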