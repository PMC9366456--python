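"""Mk models of discrete trait evolution on a dated tree.

Single- and multi-regime continuous-time Markov models with equal-rates
(ER: one shared transition rate) or all-rates-different (ARD: a free rate
per ordered state pair) parameterizations.  A regime painting assigns each
branch a rate matrix, so e.g. mammal-line and reptile-line amniotes can
evolve body size under different regimes.  Likelihoods use the pruning
algorithm with per-branch transition matrices exp(Q * duration); root state
frequencies are uniform throughout (likelihood, fitting, and ancestral
reconstruction).  Model support is summarized with Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .trees import TimeTree

__all__ = [
    "MkModelSpec",
    "MkFitResult",
    "SimulatedTrait",
    "mk_loglik",
    "fit_mk",
    "fit_candidate_models",
    "akaike_weights",
    "model_comparison_table",
    "marginal_ancestral_states",
    "simulate_mk",
    "paint_regimes",
    "standard_model_set",
]

RATE_BOUNDS = (1e-8, 1e3)  # per Myr


@dataclass
class MkModelSpec:
    """Model structure: state space, parameterization, regime painting.

    ``regime_of`` maps a branch (by its child node_id) to a regime index in
    ``range(n_regimes)``; an empty mapping means a single regime everywhere.
    Free parameters: 1 (ER) or n(n-1) (ARD) per regime.
    """

    n_states: int
    parameterization: str = "ER"  # "ER" | "ARD"
    n_regimes: int = 1
    regime_of: dict = field(default_factory=dict)
    state_order: tuple = None

    def __post_init__(self):
        if self.parameterization not in ("ER", "ARD"):
            raise ValueError("parameterization must be 'ER' or 'ARD'")
        if self.state_order is None:
            self.state_order = tuple(range(self.n_states))
        if len(self.state_order) != self.n_states:
            raise ValueError("state_order length must equal n_states")
        bad = set(self.regime_of.values()) - set(range(self.n_regimes))
        if bad:
            raise ValueError(f"regime indices {sorted(bad)} out of range")

    @property
    def params_per_regime(self) -> int:
        n = self.n_states
        return 1 if self.parameterization == "ER" else n * (n - 1)

    @property
    def k(self) -> int:
        return self.params_per_regime * self.n_regimes

    def regime(self, node_id: str) -> int:
        return self.regime_of.get(node_id, 0)

    def build_q(self, rates, regime: int) -> np.ndarray:
        """Rate matrix for one regime; ARD rates are row-major off-diagonals."""
        rates = np.asarray(rates, dtype=float)
        if rates.size != self.k:
            raise ValueError(f"expected {self.k} rates, got {rates.size}")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        block = rates[regime * self.params_per_regime:(regime + 1) * self.params_per_regime]
        n = self.n_states
        Q = np.zeros((n, n))
        if self.parameterization == "ER":
            Q[:] = block[0]
        else:
            it = iter(block)
            for i in range(n):
                for j in range(n):
                    if i != j:
                        Q[i, j] = next(it)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


@dataclass
class MkFitResult:
    loglik: float
    rates: np.ndarray
    k: int
    aic: float
    converged: bool
    spec: MkModelSpec
    at_bound: bool = False

    def q_matrix(self, regime: int = 0) -> np.ndarray:
        return self.spec.build_q(self.rates, regime)


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def _transition_bank(Q: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """exp(Q*t) for a batch of durations, by eigendecomposition with an
    expm fallback for defective/ill-conditioned Q."""
    durations = np.asarray(durations, dtype=float)
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            E = np.exp(np.outer(durations, lam))
            P = np.einsum("ij,bj,jk->bik", V, E, Vinv)
            P = np.real(P)
            rowsum_err = np.max(np.abs(P.sum(axis=2) - 1.0))
            if rowsum_err < 1e-8:
                return np.clip(P, 0.0, 1.0)
    except np.linalg.LinAlgError:
        pass
    uniq, inv = np.unique(durations, return_inverse=True)
    bank = np.stack([linalg.expm(Q * t) for t in uniq])
    return np.clip(bank[inv], 0.0, 1.0)


def _edge_data(tree: TimeTree, spec: MkModelSpec, rates):
    """Per-branch transition matrices keyed by child node."""
    branches = tree.branches()
    durations = np.array([tree.branch_duration(nd) for nd in branches])
    regimes = np.array([spec.regime(nd.node_id) for nd in branches])
    P = np.empty((len(branches), spec.n_states, spec.n_states))
    for r in range(spec.n_regimes):
        sel = regimes == r
        if sel.any():
            P[sel] = _transition_bank(spec.build_q(rates, r), durations[sel])
    return {nd: P[i] for i, nd in enumerate(branches)}


class _FlatTree:
    """Postorder-flattened tree reused across likelihood evaluations."""

    def __init__(self, tree: TimeTree, spec: MkModelSpec, trait: dict):
        nodes = list(tree.tree.postorder_node_iter())
        self.index = {nd: i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = self.index[tree.tree.seed_node]
        self.is_leaf = np.array([nd.is_leaf() for nd in nodes])
        self.parent = np.array([self.index[nd.parent_node] if nd.parent_node else -1
                                for nd in nodes])
        has_edge = [nd for nd in nodes if nd.parent_node is not None]
        self.edge_child = np.array([self.index[nd] for nd in has_edge])
        self.durations = np.array([tree.branch_duration(nd) for nd in has_edge])
        self.regimes = np.array([spec.regime(nd.node_id) for nd in has_edge])
        self.edge_of_child = np.full(self.n_nodes, -1)
        self.edge_of_child[self.edge_child] = np.arange(len(has_edge))
        n = spec.n_states
        self.tips = np.ones((self.n_nodes, n))
        for nd in nodes:
            if nd.is_leaf():
                label = nd.taxon.label
                if label not in trait:
                    raise ValueError(f"tip {label!r} has no trait state")
                value = trait[label]
                if not (value is None or (isinstance(value, str) and value == "?")):
                    vec = np.zeros(n)
                    vec[_state_index(spec, value)] = 1.0
                    self.tips[self.index[nd]] = vec
        self.spec = spec
        self.internal = np.nonzero(~self.is_leaf)[0]
        self.children = {i: np.nonzero(self.parent == i)[0] for i in self.internal}
        # level scheduling: nodes grouped by height so the pruning pass is a
        # short sequence of batched edge updates instead of a per-node loop
        height = np.zeros(self.n_nodes, dtype=int)
        for i in self.internal:  # postorder: children precede parents
            height[i] = height[self.children[i]].max() + 1
        self.levels = []
        for h in range(1, height.max() + 1):
            nodes_h = np.nonzero((height == h) & ~self.is_leaf)[0]
            if nodes_h.size == 0:
                continue
            loc = {n: i for i, n in enumerate(nodes_h)}
            child_rows, edge_rows, parent_loc = [], [], []
            for n in nodes_h:
                for c in self.children[n]:
                    child_rows.append(c)
                    edge_rows.append(self.edge_of_child[c])
                    parent_loc.append(loc[n])
            child_rows = np.array(child_rows)
            edge_rows = np.array(edge_rows)
            parent_loc = np.array(parent_loc)
            slots = []
            seen = np.zeros(nodes_h.size, dtype=int)
            slot_of = np.empty(parent_loc.size, dtype=int)
            for e, p in enumerate(parent_loc):
                slot_of[e] = seen[p]
                seen[p] += 1
            for s in range(seen.max()):
                slots.append(np.nonzero(slot_of == s)[0])
            self.levels.append((nodes_h, child_rows, edge_rows, parent_loc, slots))

    def transition_bank(self, rates):
        spec = self.spec
        P = np.empty((len(self.edge_child), spec.n_states, spec.n_states))
        for r in range(spec.n_regimes):
            sel = self.regimes == r
            if sel.any():
                P[sel] = _transition_bank(spec.build_q(rates, r), self.durations[sel])
        return P

    def loglik(self, rates) -> float:
        spec = self.spec
        P = self.transition_bank(rates)
        down = np.empty((self.n_nodes, spec.n_states))
        down[self.is_leaf] = self.tips[self.is_leaf]
        logscale = 0.0
        for nodes_h, child_rows, edge_rows, parent_loc, slots in self.levels:
            contrib = np.einsum("eij,ej->ei", P[edge_rows], down[child_rows])
            acc = np.ones((nodes_h.size, spec.n_states))
            for sel in slots:
                acc[parent_loc[sel]] *= contrib[sel]
            peaks = acc.max(axis=1)
            if np.any(peaks <= 0):
                return -np.inf
            down[nodes_h] = acc / peaks[:, None]
            logscale += np.log(peaks).sum()
        lik = down[self.root].mean()
        return -np.inf if lik <= 0 else float(np.log(lik) + logscale)


def _state_index(spec: MkModelSpec, value):
    if value in spec.state_order:
        return spec.state_order.index(value)
    return int(value)


def _tip_partials(tree: TimeTree, trait: dict, spec: MkModelSpec):
    partials = {}
    for lf in tree.tree.leaf_node_iter():
        label = lf.taxon.label
        if label not in trait:
            raise ValueError(f"tip {label!r} has no trait state")
        vec = np.zeros(spec.n_states)
        value = trait[label]
        if value is None or (isinstance(value, str) and value == "?"):
            vec[:] = 1.0  # uninformative tip
        else:
            vec[_state_index(spec, value)] = 1.0
        partials[lf] = vec
    return partials


def _prune(tree: TimeTree, trait: dict, spec: MkModelSpec, rates):
    """Post-order partial likelihoods with running log-scale factors."""
    Pmap = _edge_data(tree, spec, rates)
    partials = _tip_partials(tree, trait, spec)
    logscale = 0.0
    down = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            down[nd] = partials[nd]
            continue
        vec = np.ones(spec.n_states)
        for child in nd.child_nodes():
            vec = vec * (Pmap[child] @ down[child])
        peak = vec.max()
        if peak <= 0:
            return None, Pmap, down  # impossible data under this model
        vec = vec / peak
        logscale += np.log(peak)
        down[nd] = vec
    return logscale, Pmap, down


def mk_loglik(tree: TimeTree, trait: dict, spec: MkModelSpec, rates) -> float:
    """Log-likelihood of tip states under the painted Mk model (pruning
    algorithm, uniform root frequencies)."""
    np.asarray(rates, dtype=float)
    return _FlatTree(tree, spec, trait).loglik(rates)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_mk(tree: TimeTree, trait: dict, spec: MkModelSpec, n_starts: int = 5,
           seed=0, bounds=RATE_BOUNDS, warm_starts=None, maxiter: int = 500) -> MkFitResult:
    """Maximize the Mk likelihood by multi-start bounded optimization on
    log rates (ARD likelihood surfaces are multimodal).

    ``warm_starts``: optional rate vectors (natural scale) used as extra
    starting points, e.g. a simpler nested model's fitted rates.
    """
    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log(bounds[0]), np.log(bounds[1])
    flat = _FlatTree(tree, spec, trait)

    def neg(x):
        val = flat.loglik(np.exp(x))
        return 1e10 if not np.isfinite(val) else -val

    total_span = max(tree.root_age - min(nd.age for nd in tree.tree.leaf_node_iter()), 1e-6)
    heuristic = np.log(np.full(spec.k, 1.0 / total_span))
    starts = [heuristic]
    for warm in warm_starts or []:
        warm = np.asarray(warm, dtype=float)
        if warm.size == spec.k:
            starts.append(np.log(np.clip(warm, bounds[0], bounds[1])))
            starts.append(np.log(np.clip(warm, bounds[0], bounds[1]))
                          + rng.normal(0, 0.3, spec.k))
    while len(starts) < max(n_starts, 1):
        starts.append(rng.uniform(np.log(1e-4), np.log(1.0), size=spec.k))

    best = None
    any_success = False
    for x0 in starts:
        x0 = np.clip(x0, log_lo, log_hi)
        res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                bounds=[(log_lo, log_hi)] * spec.k,
                                options=dict(maxiter=maxiter, ftol=1e-10))
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    ll = -best.fun
    # a rate within two decades of a bound is effectively pinned there
    at_bound = bool(np.any(best.x <= log_lo + np.log(100)) or
                    np.any(best.x >= log_hi - np.log(100)))
    return MkFitResult(loglik=ll, rates=rates, k=spec.k, aic=2 * spec.k - 2 * ll,
                       converged=any_success, spec=spec, at_bound=at_bound)


def fit_candidate_models(tree: TimeTree, trait: dict, painting: dict,
                         n_states: int = 4, state_order=None, seed=0,
                         n_starts: int = 3) -> dict:
    """Fit the standard four-model set with hierarchical warm starts.

    The ER fit seeds the ARD fits (all off-diagonals at the shared rate);
    each single-regime solution, tiled across regimes, seeds its
    multi-regime counterpart.  Returns ``{model name: MkFitResult}``.
    """
    models = standard_model_set(n_states, painting, state_order=state_order)
    fits = {}
    fits["single_regime_ER"] = fit_mk(tree, trait, models["single_regime_ER"],
                                      n_starts=n_starts, seed=seed)
    q = fits["single_regime_ER"].rates[0]
    n_off = n_states * (n_states - 1)
    fits["single_regime_ARD"] = fit_mk(
        tree, trait, models["single_regime_ARD"], n_starts=n_starts, seed=seed,
        warm_starts=[np.full(n_off, q)])
    fits["multi_regime_ER"] = fit_mk(
        tree, trait, models["multi_regime_ER"], n_starts=n_starts, seed=seed,
        warm_starts=[np.full(2, q)])
    fits["multi_regime_ARD"] = fit_mk(
        tree, trait, models["multi_regime_ARD"], n_starts=n_starts, seed=seed,
        warm_starts=[np.tile(fits["single_regime_ARD"].rates, 2),
                     np.full(2 * n_off, q)])
    return fits


def akaike_weights(aics) -> np.ndarray:
    """w_i = exp(-dAIC_i/2) normalized over the candidate set."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ValueError("Akaike weights need at least two models")
    if not np.all(np.isfinite(aics)):
        raise ValueError("non-finite AIC value")
    rel = np.exp(-(aics - aics.min()) / 2.0)
    return rel / rel.sum()


def model_comparison_table(fits: dict) -> pd.DataFrame:
    """One row per model: log-likelihood, k, AIC, Akaike weight."""
    names = list(fits)
    aics = [fits[n].aic for n in names]
    w = akaike_weights(aics)
    return pd.DataFrame({
        "model": names,
        "loglik": [fits[n].loglik for n in names],
        "k": [fits[n].k for n in names],
        "aic": aics,
        "akaike_weight": w,
    })


# ---------------------------------------------------------------------------
# Ancestral states
# ---------------------------------------------------------------------------

def marginal_ancestral_states(tree: TimeTree, trait: dict, spec: MkModelSpec,
                              rates) -> dict:
    """Marginal posterior state probabilities per internal node.

    Standard up/down algorithm: the down pass collects likelihoods of data
    below each node, the up pass those of data elsewhere; their product,
    normalized, is the marginal.  Returns ``{node_id: probability vector}``.
    """
    logscale, Pmap, down = _prune(tree, trait, spec, rates)
    if logscale is None:
        raise ValueError("data impossible under the supplied model/rates")
    n = spec.n_states
    root = tree.tree.seed_node
    up = {root: np.full(n, 1.0 / n)}
    out = {}
    for nd in tree.tree.preorder_node_iter():
        if nd is not root:
            parent = nd.parent_node
            above = up[parent].copy()
            for sib in parent.child_nodes():
                if sib is nd:
                    continue
                above = above * (Pmap[sib] @ down[sib])
            vec = above @ Pmap[nd]
            peak = vec.max()
            up[nd] = vec / peak if peak > 0 else vec
        if not nd.is_leaf():
            marg = up[nd] * down[nd]
            total = marg.sum()
            if total <= 0:
                raise ValueError(f"zero marginal at node {nd.node_id}")
            out[nd.node_id] = marg / total
    return out


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrait:
    tip_states: dict
    node_states: dict
    n_changes: dict
    histories: dict  # node_id -> [(time since branch start, new state), ...]

    def states_as(self, spec: MkModelSpec) -> dict:
        return {t: spec.state_order[s] for t, s in self.tip_states.items()}


def _stationary(Q: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.append(np.zeros(n), 1.0)
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def simulate_mk(tree: TimeTree, spec: MkModelSpec, rates, root_state=None,
                root_dist: str = "uniform", seed=0) -> SimulatedTrait:
    """Forward (Gillespie) simulation retaining the full change history."""
    rng = np.random.default_rng(seed)
    n = spec.n_states
    Qs = [spec.build_q(rates, r) for r in range(spec.n_regimes)]
    root = tree.tree.seed_node
    if root_state is not None:
        s0 = _state_index(spec, root_state)
    elif root_dist == "uniform":
        s0 = int(rng.integers(0, n))
    elif root_dist == "stationary":
        s0 = int(rng.choice(n, p=_stationary(Qs[0])))
    else:
        raise ValueError("root_dist must be 'uniform' or 'stationary'")
    node_states = {root.node_id: s0}
    state_at = {root: s0}
    n_changes, histories, tip_states = {}, {}, {}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        Q = Qs[spec.regime(nd.node_id)]
        duration = tree.branch_duration(nd)
        s = state_at[nd.parent_node]
        t, events = 0.0, []
        while True:
            out_rate = -Q[s, s]
            if out_rate <= 0:
                break
            t += rng.exponential(1.0 / out_rate)
            if t >= duration:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(n, p=probs))
            events.append((t, s))
        state_at[nd] = s
        node_states[nd.node_id] = s
        n_changes[nd.node_id] = len(events)
        histories[nd.node_id] = events
        if nd.is_leaf():
            tip_states[nd.taxon.label] = s
    return SimulatedTrait(tip_states, node_states, n_changes, histories)


# ---------------------------------------------------------------------------
# Regime painting and the standard candidate set
# ---------------------------------------------------------------------------

def paint_regimes(tree: TimeTree, tip_groups: dict, groups, background=None) -> dict:
    """Branch painting by clade membership of descendant tips.

    A branch takes group g's regime iff every descendant tip maps to g
    (the clade's stem branch therefore paints with the clade).  Branches
    ancestral to several groups, or subtending unassigned tips, take the
    ``background`` group's regime (default: the first listed group).
    Returns ``{node_id: regime index}`` with regimes indexed by ``groups``.
    """
    groups = list(groups)
    background = background if background is not None else groups[0]
    if background not in groups:
        raise ValueError(f"background group {background!r} not in groups")
    painting = {}
    for nd in tree.branches():
        tips = tree.tip_labels_under(nd)
        seen = {tip_groups.get(t) for t in tips}
        if len(seen) == 1 and (g := next(iter(seen))) in groups:
            painting[nd.node_id] = groups.index(g)
        else:
            painting[nd.node_id] = groups.index(background)
    return painting


def standard_model_set(n_states: int, painting: dict, n_regimes: int = 2,
                       state_order=None) -> dict:
    """The four-model candidate set: {single, multi} x {ER, ARD}."""
    return {
        "single_regime_ER": MkModelSpec(n_states, "ER", state_order=state_order),
        "single_regime_ARD": MkModelSpec(n_states, "ARD", state_order=state_order),
        "multi_regime_ER": MkModelSpec(n_states, "ER", n_regimes=n_regimes,
                                       regime_of=dict(painting), state_order=state_order),
        "multi_regime_ARD": MkModelSpec(n_states, "ARD", n_regimes=n_regimes,
                                        regime_of=dict(painting), state_order=state_order),
    }
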