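"""Synthetic datasets with the statistical structure the analyses assume.

Generates (i) dated birth-death trees with fossil tips rooted ~320 Ma,
(ii) discrete character matrices evolved under equal-rates Mk with
clade-specific accessible-state restriction (small k forces homoplasy and a
low saturation asymptote — the operational meaning of strong constraint),
(iii) per-branch evolutionary rates declining through time, and (iv) a
4-category body-size trait evolving under regime-dependent transition rates
(the mammal-line regime permits no decreases).  Every generator stores its
ground truth so downstream calls can be scored, and is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .matrix import MISSING, CharacterMatrix
from .metadata import SIZE_CATEGORIES
from .mk import MkModelSpec, paint_regimes, simulate_mk
from .trees import ChangesTree, TimeTree, _assign_node_ids

__all__ = [
    "TreeConfig",
    "CharacterConfig",
    "MissingnessConfig",
    "SizeTraitConfig",
    "SyntheticScenario",
    "GroundTruth",
    "simulate_tree",
    "assign_clades",
    "simulate_constrained_matrix",
    "generate_rate_burst_tree",
    "simulate_size_dataset",
    "export_dataset",
]


@dataclass
class TreeConfig:
    n_tips: int = 98          # total tips, extinct lineages included
    birth_rate: float = 0.13  # per lineage per Myr
    death_rate: float = 0.03
    root_age: float = 320.0   # Ma
    tip_min_age: float = 272.0  # youngest tips sit at the end of the window
    split_at_root: bool = True  # root divides two major clades, as in crown groups
    stem_fraction: float = 0.1  # fraction of the window spent on each clade's stem


@dataclass
class CharacterConfig:
    n_chars: int = 366
    k_background: int = 6            # accessible states outside constrained clades
    clade_k: dict = field(default_factory=dict)  # clade label -> restricted k
    base_rate: float = 0.01          # expected changes per character per Myr at the root
    rate_profile: str = "exponential"  # "constant" | "exponential"
    half_life: float = 20.0          # Myr; rate halves every half-life under decline
    group_rate_multipliers: dict = field(default_factory=dict)
    changes_noise_sigma: float = 0.0  # lognormal sd emulating branch-length estimation error


@dataclass
class MissingnessConfig:
    fraction: float = 0.45
    mode: str = "mcar"  # "mcar" | "taxon_biased"


@dataclass
class SizeTraitConfig:
    n_states: int = 4
    synapsid_up: float = 0.04    # per Myr, any smaller -> larger transition
    synapsid_down: float = 0.0   # the mammal-line regime forbids decreases
    reptile_up: float = 0.02     # reptile-line regime is bidirectional,
    reptile_down: float = 0.08   # biased toward returns to smaller sizes
    groups: tuple = ("Synapsida", "Reptilia")


@dataclass
class SyntheticScenario:
    seed: int = 0
    tree: TreeConfig = field(default_factory=TreeConfig)
    characters: CharacterConfig = field(default_factory=CharacterConfig)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    size_trait: SizeTraitConfig = field(default_factory=SizeTraitConfig)

    def __post_init__(self):
        if self.characters.k_background < 2 or any(
                k < 2 for k in self.characters.clade_k.values()):
            raise ValueError("accessible state counts must be >= 2")
        if self.characters.k_background > 10 or any(
                k > 10 for k in self.characters.clade_k.values()):
            raise ValueError("at most 10 states (digit symbols 0-9)")
        if not 0 <= self.missingness.fraction < 1:
            raise ValueError("missing fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    branch_rates: dict = field(default_factory=dict)       # node_id -> true rate
    regime_of: dict = field(default_factory=dict)          # node_id -> clade label
    clade_k: dict = field(default_factory=dict)            # clade label -> accessible k
    n_changes: dict = field(default_factory=dict)          # node_id -> realized changes (all chars)
    trait_rates: np.ndarray = None                         # true rate vector (size trait)
    trait_history: dict = field(default_factory=dict)      # node_id -> state


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _bd_subtree(cfg: TreeConfig, target: int, rng, max_attempts: int) -> dendropy.Tree:
    """Birth-death tree conditioned on total tip count (extinct retained)."""
    m = max(2, target - int(round(target * cfg.death_rate / max(cfg.birth_rate, 1e-9) * 0.5)))
    for _ in range(max_attempts):
        try:
            cand = birthdeath.birth_death_tree(
                birth_rate=cfg.birth_rate, death_rate=cfg.death_rate,
                num_extant_tips=m, is_retain_extinct_tips=True, rng=rng)
        except Exception:
            continue
        total = len(cand.leaf_nodes())
        if total == target:
            return cand
        m = max(2, m + (target - total))
    raise RuntimeError(f"could not attain {target} tips in {max_attempts} attempts")


def _scale_depths(root, crown_span: float) -> None:
    """Rescale the subtree below ``root`` so its deepest tip sits crown_span
    time units below it; records relative depth on each node."""
    root.depth = 0.0
    max_depth = 0.0
    for nd in root.preorder_iter():
        if nd is not root:
            nd.depth = nd.parent_node.depth + (nd.edge.length or 0.0)
            max_depth = max(max_depth, nd.depth)
    scale = crown_span / max_depth if max_depth > 0 else 1.0
    for nd in root.preorder_iter():
        nd.depth *= scale
        if nd is not root and nd.edge.length is not None:
            nd.edge.length *= scale


def simulate_tree(scenario: SyntheticScenario, seed=None, max_attempts: int = 500) -> TimeTree:
    """Dated birth-death tree with fossil tips, rooted at the stated age.

    With ``split_at_root`` (default) the root divides two birth-death
    subtrees of near-equal size — the two major lineages of a crown group —
    each on a stem taking ``stem_fraction`` of the window.  Extinct
    lineages persist as fossil tips; the youngest tips sit at
    ``tip_min_age``.
    """
    cfg = scenario.tree
    rng = random.Random(scenario.seed if seed is None else seed)
    span = cfg.root_age - cfg.tip_min_age
    if cfg.split_at_root and cfg.n_tips >= 4:
        n1 = cfg.n_tips // 2
        sub1 = _bd_subtree(cfg, n1, rng, max_attempts)
        sub2 = _bd_subtree(cfg, cfg.n_tips - n1, rng, max_attempts)
        stem = cfg.stem_fraction * span
        tree = dendropy.Tree()
        for sub in (sub1, sub2):
            _scale_depths(sub.seed_node, span - stem)
            sub.seed_node.edge.length = stem
            tree.seed_node.add_child(sub.seed_node)
        tree.seed_node.depth = 0.0
        for child in tree.seed_node.child_nodes():
            for nd in child.preorder_iter():
                nd.depth += stem
        tree.update_taxon_namespace()
    else:
        tree = _bd_subtree(cfg, cfg.n_tips, rng, max_attempts)
        _scale_depths(tree.seed_node, span)

    namespace = dendropy.TaxonNamespace()
    for i, lf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = namespace.new_taxon(f"t{i:03d}")
        lf.taxon = taxon
    tree.taxon_namespace = namespace
    for nd in tree.preorder_node_iter():
        nd.age = cfg.root_age - nd.depth
        del nd.depth
        nd.rate = None
    _assign_node_ids(tree)
    return TimeTree(tree=tree, root_age=cfg.root_age, has_rates=False)


def assign_clades(time_tree: TimeTree, names=("Synapsida", "Reptilia")) -> dict:
    """Label the two largest root-child clades; remaining tips are outgroup."""
    children = sorted(time_tree.tree.seed_node.child_nodes(),
                      key=lambda nd: -len(nd.leaf_nodes()))
    tip_groups = {t: "outgroup" for t in time_tree.taxon_labels}
    for name, child in zip(names, children):
        for lf in child.leaf_iter():
            tip_groups[lf.taxon.label] = name
    return tip_groups


def _branch_rate(cfg: CharacterConfig, root_age: float, mid_age: float) -> float:
    if cfg.rate_profile == "constant":
        return cfg.base_rate
    if cfg.rate_profile == "exponential":
        return cfg.base_rate * 0.5 ** ((root_age - mid_age) / cfg.half_life)
    raise ValueError(f"unknown rate profile {cfg.rate_profile!r}")


def _paint_by_clade(time_tree: TimeTree, tip_groups: dict) -> dict:
    """node_id -> clade label when all descendant tips share it, else 'background'."""
    painting = {}
    for nd in time_tree.branches():
        seen = {tip_groups.get(t) for t in time_tree.tip_labels_under(nd)}
        painting[nd.node_id] = seen.pop() if len(seen) == 1 else "background"
    return painting


def generate_rate_burst_tree(time_tree: TimeTree, scenario: SyntheticScenario,
                             tip_groups: dict = None):
    """Attach declining-through-time branch rates (early burst).

    Each branch's rate is the profile evaluated at its midpoint age times
    any multiplicative group effect.  Returns (TimeTree, GroundTruth).
    """
    cfg = scenario.characters
    tip_groups = tip_groups or assign_clades(time_tree)
    painting = _paint_by_clade(time_tree, tip_groups)
    out = time_tree.copy()
    truth = GroundTruth(regime_of=painting)
    for nd in out.branches():
        mid_age = 0.5 * (nd.parent_node.age + nd.age)
        rate = _branch_rate(cfg, out.root_age, mid_age)
        rate *= cfg.group_rate_multipliers.get(painting[nd.node_id], 1.0)
        nd.rate = rate
        truth.branch_rates[nd.node_id] = rate
    out.has_rates = True
    return out, truth


# ---------------------------------------------------------------------------
# Constrained character matrices
# ---------------------------------------------------------------------------

def _evolve_characters(time_tree, expected_changes, k_of_branch, n_chars, rng):
    """ER Mk via the embedded jump chain: the number of state changes on a
    branch with expected-change length b is Poisson(b), each jump uniform
    over the other accessible states.  Returns tip states and per-branch
    realized change counts."""
    root = time_tree.tree.seed_node
    k_root = max(k_of_branch.values()) if k_of_branch else 2
    states = {root: rng.integers(0, k_root, size=n_chars)}
    n_changes = {}
    tip_states = {}
    for nd in time_tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        k = k_of_branch[nd.node_id]
        s = states[nd.parent_node] % k  # collapse into the accessible set
        b = expected_changes[nd.node_id]
        jumps = rng.poisson(b, size=n_chars)
        n_changes[nd.node_id] = int(jumps.sum())
        remaining = jumps.copy()
        while remaining.max() > 0:
            live = remaining > 0
            step = rng.integers(1, k, size=n_chars)
            s = np.where(live, (s + step) % k, s)
            remaining = np.maximum(remaining - 1, 0)
        states[nd] = s
        if nd.is_leaf():
            tip_states[nd.taxon.label] = s
    return tip_states, n_changes


def _missing_mask(n_taxa, n_chars, cfg: MissingnessConfig, rng) -> np.ndarray:
    """True where the cell is scored."""
    if cfg.fraction == 0:
        return np.ones((n_taxa, n_chars), dtype=bool)
    if cfg.mode == "mcar":
        return rng.random((n_taxa, n_chars)) >= cfg.fraction
    if cfg.mode == "taxon_biased":
        # worse-sampled fossil taxa: per-taxon missingness from a beta
        # distribution with the stated mean
        a = 2.0
        b = a * (1.0 - cfg.fraction) / cfg.fraction
        per_taxon = rng.beta(a, b, size=n_taxa)
        return rng.random((n_taxa, n_chars)) >= per_taxon[:, None]
    raise ValueError(f"unknown missingness mode {cfg.mode!r}")


def simulate_constrained_matrix(time_tree: TimeTree, scenario: SyntheticScenario,
                                seed=None, tip_groups: dict = None):
    """Character matrix under clade-specific constraint.

    Characters evolve under equal-rates Mk; branches inside a constrained
    clade move within a restricted accessible-state set (``clade_k``),
    others within ``k_background`` states.  The true per-branch expected
    change counts form the returned ChangesTree.  Missingness is applied
    last.  Returns (CharacterMatrix, ChangesTree, GroundTruth).
    """
    cfg = scenario.characters
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    tip_groups = tip_groups or assign_clades(time_tree)
    painting = _paint_by_clade(time_tree, tip_groups)
    k_of_branch = {nid: cfg.clade_k.get(clade, cfg.k_background)
                   for nid, clade in painting.items()}

    expected, rates = {}, {}
    for nd in time_tree.branches():
        mid_age = 0.5 * (nd.parent_node.age + nd.age)
        rate = _branch_rate(cfg, time_tree.root_age, mid_age)
        rate *= cfg.group_rate_multipliers.get(painting[nd.node_id], 1.0)
        rates[nd.node_id] = rate
        expected[nd.node_id] = rate * time_tree.branch_duration(nd)

    tip_states, n_changes = _evolve_characters(
        time_tree, expected, k_of_branch, cfg.n_chars, rng)

    taxa = list(time_tree.taxon_labels)
    scored = _missing_mask(len(taxa), cfg.n_chars, scenario.missingness, rng)
    cells = []
    for i, t in enumerate(taxa):
        row = [frozenset({int(s)}) if scored[i, j] else MISSING
               for j, s in enumerate(tip_states[t])]
        cells.append(row)
    matrix = CharacterMatrix(taxa=taxa, cells=cells)

    clone = dendropy.Tree(time_tree.tree)
    for nd_old, nd_new in zip(time_tree.tree.preorder_node_iter(),
                              clone.preorder_node_iter()):
        nd_new.node_id = nd_old.node_id
        if nd_old.parent_node is not None:
            length = expected[nd_old.node_id]
            if cfg.changes_noise_sigma > 0:
                length *= rng.lognormal(0.0, cfg.changes_noise_sigma)
            nd_new.edge.length = length
    changes_tree = ChangesTree(tree=clone)

    truth = GroundTruth(branch_rates=rates, regime_of=painting,
                        clade_k={**{g: cfg.k_background for g in set(painting.values())},
                                 **cfg.clade_k},
                        n_changes=n_changes)
    return matrix, changes_tree, truth


# ---------------------------------------------------------------------------
# Body-size trait
# ---------------------------------------------------------------------------

def size_rate_vector(cfg: SizeTraitConfig) -> np.ndarray:
    """True ARD rates for the two regimes, row-major off-diagonals.

    Regime 0 (mammal-line): smaller->larger transitions at ``synapsid_up``,
    larger->smaller at ``synapsid_down`` (zero by default).  Regime 1
    (reptile-line): bidirectional.
    """
    n = cfg.n_states
    blocks = []
    for up, down in ((cfg.synapsid_up, cfg.synapsid_down),
                     (cfg.reptile_up, cfg.reptile_down)):
        block = []
        for i in range(n):
            for j in range(n):
                if i != j:
                    block.append(up if j > i else down)
        blocks.extend(block)
    return np.array(blocks)


def simulate_size_dataset(time_tree: TimeTree, scenario: SyntheticScenario,
                          seed=None, tip_groups: dict = None):
    """Simulate the 4-category body-size trait under two regimes.

    The mammal-line regime is upper-triangular (sizes never decrease along
    a lineage); the reptile-line regime is bidirectional.  Returns
    (trait table DataFrame, MkModelSpec, GroundTruth).
    """
    cfg = scenario.size_trait
    use_seed = scenario.seed if seed is None else seed
    tip_groups = tip_groups or assign_clades(time_tree)
    painting = paint_regimes(time_tree, tip_groups, list(cfg.groups),
                             background=cfg.groups[1])
    spec = MkModelSpec(cfg.n_states, "ARD", n_regimes=2, regime_of=painting,
                       state_order=tuple(SIZE_CATEGORIES[:cfg.n_states]))
    rates = size_rate_vector(cfg)
    sim = simulate_mk(time_tree, spec, rates, root_state=0, seed=use_seed)
    table = pd.DataFrame({
        "taxon": list(sim.tip_states),
        "size_category": [spec.state_order[s] for s in sim.tip_states.values()],
        "clade": [tip_groups.get(t) for t in sim.tip_states],
    })
    truth = GroundTruth(regime_of={nid: cfg.groups[r] for nid, r in painting.items()},
                        trait_rates=rates, trait_history=sim.node_states)
    return table, spec, truth


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_dataset(outdir, scenario: SyntheticScenario, time_tree: TimeTree,
                   matrix: CharacterMatrix = None, changes_tree: ChangesTree = None,
                   metadata: pd.DataFrame = None, truth: GroundTruth = None) -> None:
    """Write the generated artifacts plus a provenance record."""
    from pathlib import Path

    from .matrix import write_nexus_matrix
    from .trees import write_tree

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tree(time_tree, outdir / "time_tree.nwk")
    if matrix is not None:
        write_nexus_matrix(matrix, outdir / "matrix.nex")
    if changes_tree is not None:
        write_tree(changes_tree, outdir / "changes_tree.nwk")
    if metadata is not None:
        metadata.to_csv(outdir / "metadata.csv")
    if truth is not None:
        rows = [dict(node_id=nid, true_rate=r) for nid, r in truth.branch_rates.items()]
        pd.DataFrame(rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(asdict(scenario), fh, indent=2, default=str)
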