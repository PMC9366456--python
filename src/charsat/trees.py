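"""Time-calibrated and change-scaled trees.

``TimeTree`` wraps a rooted dendropy tree with node ages in Ma (time
increasing into the past; the root is oldest, fossil tips need not be
contemporaneous).  Per-branch relative rates of character evolution may be
attached from MrBayes-style comment annotations.

``ChangesTree`` shares the topology of a reference ``TimeTree`` but its
branch lengths are expected character-state changes, the currency of
patristic morphological distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "ChangesTree",
    "TreeValidationError",
    "read_annotated_tree",
    "read_changes_tree",
    "write_tree",
]


class TreeValidationError(ValueError):
    pass


def _load_dendropy_tree(path=None, data=None, schema=None) -> dendropy.Tree:
    kwargs = dict(extract_comment_metadata=True)
    if data is not None:
        src = dict(data=data)
        schemas = [schema] if schema else ["newick", "nexus"]
    else:
        src = dict(path=str(path))
        if schema:
            schemas = [schema]
        else:
            lowered = str(path).lower()
            schemas = ["nexus", "newick"] if lowered.endswith((".nex", ".nexus", ".tre")) else ["newick", "nexus"]
    last = None
    for sch in schemas:
        try:
            return dendropy.Tree.get(schema=sch, **src, **kwargs)
        except Exception as exc:
            last = exc
    raise TreeValidationError(f"cannot parse tree: {last}")


def _assign_node_ids(tree: dendropy.Tree) -> None:
    """Stable preorder ids: tips keep their labels, internals get N0, N1, ..."""
    counter = itertools.count()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.node_id = nd.taxon.label if nd.taxon else f"T{next(counter)}"
        else:
            nd.node_id = f"N{next(counter)}"


@dataclass
class TimeTree:
    """Rooted, dated tree with optional per-branch rates.

    Node ages live on ``node.age`` (Ma); the rate of the branch subtending a
    node lives on ``node.rate`` (``None`` when unannotated).
    """

    tree: dendropy.Tree
    root_age: float
    has_rates: bool = False

    def __post_init__(self):
        self._validate()

    def _validate(self):
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None and nd.age > nd.parent_node.age + 1e-9:
                raise TreeValidationError(
                    f"node {nd.node_id} age {nd.age} exceeds parent age "
                    f"{nd.parent_node.age}"
                )

    # -- basic accessors ----------------------------------------------
    @property
    def taxon_labels(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def node_age(self, node) -> float:
        return node.age

    def internal_nodes(self):
        return [nd for nd in self.tree.preorder_node_iter() if not nd.is_leaf()]

    def branches(self):
        """All (child) nodes that subtend a branch, preorder."""
        return [nd for nd in self.tree.preorder_node_iter() if nd.parent_node is not None]

    def branch_duration(self, node) -> float:
        return node.parent_node.age - node.age

    def tip_labels_under(self, node) -> tuple:
        return tuple(lf.taxon.label for lf in node.leaf_iter())

    def find_node(self, node_id: str):
        for nd in self.tree.preorder_node_iter():
            if nd.node_id == node_id:
                return nd
        raise KeyError(node_id)

    # -- ages of most recent common ancestors -------------------------
    def mrca_age_matrix(self, labels=None):
        """Symmetric matrix of MRCA ages for all pairs of the given tips.

        Computed in one postorder sweep: a pair's MRCA is the node whose
        children first bring the two tips together.
        """
        if labels is None:
            labels = self.taxon_labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        out = np.zeros((n, n))
        tipsets = {}
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                lab = nd.taxon.label
                tipsets[nd] = [index[lab]] if lab in index else []
                continue
            child_sets = [tipsets.pop(c) for c in nd.child_nodes()]
            for a_set, b_set in itertools.combinations(child_sets, 2):
                for i in a_set:
                    for j in b_set:
                        out[i, j] = out[j, i] = nd.age
            merged = [i for s in child_sets for i in s]
            tipsets[nd] = merged
        return out

    def copy(self) -> "TimeTree":
        clone = dendropy.Tree(self.tree)
        for nd_old, nd_new in zip(
            self.tree.preorder_node_iter(), clone.preorder_node_iter()
        ):
            nd_new.age = nd_old.age
            nd_new.rate = getattr(nd_old, "rate", None)
            nd_new.node_id = nd_old.node_id
        return TimeTree(tree=clone, root_age=self.root_age, has_rates=self.has_rates)


@dataclass
class ChangesTree:
    """Tree whose branch lengths are expected character-state changes."""

    tree: dendropy.Tree

    def __post_init__(self):
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeValidationError(f"negative branch length {edge.length}")
        _assign_node_ids(self.tree)

    @property
    def taxon_labels(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def check_congruent(self, reference: TimeTree) -> None:
        """Require identical leaf sets and identical unrooted bipartitions."""
        if set(self.taxon_labels) != set(reference.taxon_labels):
            raise TreeValidationError("leaf sets differ from reference tree")

        def clades(tree):
            out = set()
            for nd in tree.preorder_internal_node_iter():
                if nd.parent_node is None:
                    continue
                out.add(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
            return out

        if clades(self.tree) != clades(reference.tree):
            raise TreeValidationError("topology incongruent with reference tree")


def _ages_from_lengths(tree: dendropy.Tree, root_age=None) -> float:
    """Set node.age from branch lengths; anchor at a stated root age or at
    the deepest tip (depth of the longest root-to-tip path maps to age 0)."""
    tree.seed_node.depth = 0.0
    max_depth = 0.0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            length = nd.edge.length if nd.edge.length is not None else 0.0
            if length < 0:
                raise TreeValidationError(f"negative branch length {length}")
            nd.depth = nd.parent_node.depth + length
            max_depth = max(max_depth, nd.depth)
    anchor = root_age if root_age is not None else max_depth
    for nd in tree.preorder_node_iter():
        nd.age = anchor - nd.depth
        del nd.depth
    return anchor


def read_annotated_tree(
    path=None,
    rate_key: str = "rate",
    root_age=None,
    data=None,
    schema=None,
    require_rates: bool = False,
) -> TimeTree:
    """Read a NEXUS/Newick tree, deriving node ages and per-branch rates.

    Rates are taken from MrBayes-style comment metadata (``[&rate=...]``)
    under ``rate_key``; they are treated as relative (per-character per-Myr
    up to a constant).  Ages are anchored at ``root_age`` when given,
    otherwise the deepest tip is placed at 0 Ma.
    """
    tree = _load_dendropy_tree(path=path, data=data, schema=schema)
    anchor = _ages_from_lengths(tree, root_age=root_age)
    _assign_node_ids(tree)
    n_rates = 0
    for nd in tree.preorder_node_iter():
        val = nd.annotations.get_value(rate_key) if nd.annotations else None
        if val is None:
            nd.rate = None
        else:
            nd.rate = float(val)
            if nd.rate < 0:
                raise TreeValidationError(f"negative branch rate {nd.rate}")
            n_rates += 1
    if require_rates and n_rates == 0:
        raise TreeValidationError(
            f"tree carries no '{rate_key}' branch-rate annotations"
        )
    return TimeTree(tree=tree, root_age=anchor, has_rates=n_rates > 0)


def read_changes_tree(path=None, data=None, schema=None, reference: TimeTree = None) -> ChangesTree:
    """Read a tree whose branch lengths are expected character changes."""
    tree = _load_dendropy_tree(path=path, data=data, schema=schema)
    ct = ChangesTree(tree=tree)
    if reference is not None:
        ct.check_congruent(reference)
    return ct


def set_tip_ages_from_ranges(time_tree: TimeTree, ranges: dict) -> None:
    """Adjust tip ages to the midpoints of first-appearance ranges.

    ``ranges`` maps tip label to an (oldest Ma, youngest Ma) interval; tips
    not listed keep their tree-derived age.  A midpoint older than the
    parent node is rejected.
    """
    for lf in time_tree.tree.leaf_node_iter():
        if lf.taxon.label in ranges:
            old, young = ranges[lf.taxon.label]
            mid = 0.5 * (old + young)
            if lf.parent_node is not None and mid > lf.parent_node.age + 1e-9:
                raise TreeValidationError(
                    f"tip {lf.taxon.label} midpoint age {mid} exceeds parent age"
                )
            lf.age = mid


def write_tree(obj, path, schema: str = "newick", annotations=None) -> None:
    """Write a TimeTree/ChangesTree; optional per-node annotation mapping
    ``node_id -> {key: value}`` is embedded as comment metadata."""
    tree = obj.tree if hasattr(obj, "tree") else obj
    clone = dendropy.Tree(tree)
    if annotations:
        for nd_old, nd_new in zip(tree.preorder_node_iter(), clone.preorder_node_iter()):
            meta = annotations.get(getattr(nd_old, "node_id", None))
            if meta:
                for key, value in sorted(meta.items()):
                    nd_new.annotations.add_new(key, value)
    clone.write(path=str(path), schema=schema, suppress_annotations=annotations is None)
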