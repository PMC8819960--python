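"""Rooted phylogenetic trees and their alignment with abundance tables.

The test only uses tree *topology*: internal nodes define groups of
descendant taxa whose abundances are accumulated into extra features.
Branch lengths are carried through parsing but never used.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import dendropy
import pandas as pd

__all__ = [
    "PhyloTree",
    "TreeError",
    "AlignmentError",
    "read_newick",
    "parse_newick",
    "align",
]


class TreeError(ValueError):
    """Structural or format problem with a phylogenetic tree."""


class AlignmentError(ValueError):
    """Tree and abundance table cannot be aligned."""


class PhyloTree:
    """A rooted tree over named nodes.

    Parameters
    ----------
    children : mapping of node id -> sequence of child ids
        Only internal nodes appear as keys; leaves are ids that occur as
        children (or the root itself, for a single-leaf tree) but never
        as keys.
    root : str
        Identifier of the root node.
    branch_lengths : mapping of node id -> float, optional
        Length of the edge above each node (absent for the root). Not
        used by the test statistic.

    Invariants (validated at construction): exactly one root, every
    non-root node has exactly one parent, the graph is acyclic and every
    node is reachable from the root, and leaf labels are unique.
    """

    __slots__ = ("children", "parent", "root", "branch_lengths", "_preorder", "_leaves")

    def __init__(
        self,
        children: Mapping[str, Sequence[str]],
        root: str,
        branch_lengths: Mapping[str, float] | None = None,
    ):
        self.children = {k: tuple(v) for k, v in children.items()}
        self.root = root
        self.branch_lengths = dict(branch_lengths) if branch_lengths else {}

        parent: dict[str, str] = {}
        for node, kids in self.children.items():
            for c in kids:
                if c in parent:
                    raise TreeError(f"node {c!r} has more than one parent")
                parent[c] = node
        self.parent = parent

        if root in parent:
            raise TreeError(f"declared root {root!r} has a parent")
        for node in self.children:
            if node != root and node not in parent:
                raise TreeError(
                    f"multiple roots: {node!r} has children but no parent"
                )

        # preorder traversal also detects unreachable nodes / cycles
        order: list[str] = []
        stack = [root]
        seen: set[str] = set()
        while stack:
            node = stack.pop()
            if node in seen:
                raise TreeError(f"cycle detected at node {node!r}")
            seen.add(node)
            order.append(node)
            stack.extend(reversed(self.children.get(node, ())))
        all_nodes = set(parent) | set(self.children) | {root}
        if seen != all_nodes:
            missing = sorted(all_nodes - seen)
            raise TreeError(f"nodes unreachable from root: {missing}")
        self._preorder = tuple(order)
        self._leaves = tuple(n for n in order if n not in self.children)
        if len(set(self._leaves)) != len(self._leaves):
            raise TreeError("leaf labels are not unique")

    # ------------------------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        """All node ids in preorder."""
        return self._preorder

    @property
    def leaves(self) -> tuple[str, ...]:
        """Leaf ids in preorder (left-to-right) order."""
        return self._leaves

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        """Internal node ids (root included) in preorder."""
        return tuple(n for n in self._preorder if n in self.children)

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def descendant_leaves(self, node: str) -> tuple[str, ...]:
        """Leaves below ``node`` (the node itself if it is a leaf)."""
        if node not in self.children:
            if node not in self.parent and node != self.root:
                raise KeyError(node)
            return (node,)
        out: list[str] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            kids = self.children.get(cur)
            if kids is None:
                out.append(cur)
            else:
                stack.extend(reversed(kids))
        return tuple(out)

    # ------------------------------------------------------------------
    def prune_to_leaves(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to the leaves in ``keep``.

        Internal nodes left with a single child are suppressed (their
        accumulated feature would exactly duplicate the child's), keeping
        the child's identifier. Surviving internal nodes keep their ids,
        so accumulated values over their descendant sets are unchanged.
        """
        keep_set = set(keep)
        unknown = keep_set - set(self._leaves)
        if unknown:
            raise AlignmentError(f"not leaves of this tree: {sorted(unknown)}")
        if not keep_set:
            raise AlignmentError("cannot prune to an empty leaf set")

        def build(node: str) -> str | None:
            kids = self.children.get(node)
            if kids is None:
                return node if node in keep_set else None
            new_kids = [c for c in (build(k) for k in kids) if c is not None]
            if not new_kids:
                return None
            if len(new_kids) == 1 and node != self.root:
                return new_kids[0]  # suppress unary node
            new_children[node] = tuple(new_kids)
            return node

        new_children: dict[str, tuple[str, ...]] = {}
        new_root = build(self.root)
        assert new_root is not None
        # a root left unary with an internal child: suppress downward
        while new_root in new_children and len(new_children[new_root]) == 1:
            only = new_children.pop(new_root)[0]
            new_root = only
        bl = {
            n: self.branch_lengths[n]
            for ns in new_children.values()
            for n in ns
            if n in self.branch_lengths
        }
        return PhyloTree(new_children, new_root, bl)

    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        def render(node: str) -> str:
            kids = self.children.get(node)
            bl = self.branch_lengths.get(node)
            suffix = "" if bl is None else f":{bl:g}"
            if kids is None:
                return f"{node}{suffix}"
            inner = ",".join(render(k) for k in kids)
            return f"({inner}){suffix}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PhyloTree {self.n_leaves} leaves, "
            f"{len(self.internal_nodes)} internal nodes>"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.root == other.root and self.children == other.children

    def __hash__(self):  # pragma: no cover
        return hash((self.root, tuple(sorted(self.children.items()))))


# ----------------------------------------------------------------------
def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    # assign deterministic preorder ids to unlabeled internal nodes
    children: dict[str, tuple[str, ...]] = {}
    branch_lengths: dict[str, float] = {}
    names: dict[int, str] = {}
    leaf_labels: set[str] = set()
    counter = 0
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None:
                raise TreeError("tree contains an unlabeled leaf")
            if label in leaf_labels:
                raise TreeError(f"duplicate leaf label {label!r}")
            leaf_labels.add(label)
            names[id(nd)] = label
        else:
            names[id(nd)] = f"node{counter}"
            counter += 1
    for nd in dtree.preorder_node_iter():
        name = names[id(nd)]
        if nd.edge.length is not None and nd.parent_node is not None:
            branch_lengths[name] = float(nd.edge.length)
        if not nd.is_leaf():
            children[name] = tuple(names[id(c)] for c in nd.child_nodes())
    clash = leaf_labels & set(children)
    if clash:
        raise TreeError(
            f"leaf labels collide with generated internal-node ids: {sorted(clash)}"
        )
    root = names[id(dtree.seed_node)]
    return PhyloTree(children, root, branch_lengths)


def parse_newick(newick: str) -> PhyloTree:
    """Parse a single rooted Newick string into a :class:`PhyloTree`.

    Unlabeled internal nodes receive deterministic identifiers
    ``node0, node1, ...`` in preorder (``node0`` is the root).
    """
    trees = dendropy.TreeList()
    try:
        trees.read(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"could not parse Newick input: {exc}") from exc
    if len(trees) == 0:
        raise TreeError("input contains no tree")
    if len(trees) > 1:
        raise TreeError(f"input contains {len(trees)} trees; expected exactly one")
    return _from_dendropy(trees[0])


def read_newick(path) -> PhyloTree:
    """Read one rooted tree from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


class Alignment(NamedTuple):
    """Result of aligning a tree with an abundance table."""

    tree: PhyloTree
    table: pd.DataFrame
    dropped_taxa: tuple[str, ...]  # table columns absent from the tree
    dropped_leaves: tuple[str, ...]  # tree leaves absent from the table


def align(tree: PhyloTree, table: pd.DataFrame) -> Alignment:
    """Restrict ``tree`` and ``table`` to their shared taxa.

    The tree is pruned to the shared leaf set (suppressing unary internal
    nodes) and the table's columns are reordered to the pruned tree's
    leaf order. Taxa present on only one side are reported as dropped.
    """
    taxa = set(table.columns)
    leaves = set(tree.leaves)
    shared = taxa & leaves
    if not shared:
        raise AlignmentError(
            "tree leaves and table taxa share no identifiers; "
            "check taxon naming between the two inputs"
        )
    pruned = tree.prune_to_leaves(shared) if shared != leaves else tree
    ordered = table.loc[:, list(pruned.leaves)]
    return Alignment(
        tree=pruned,
        table=ordered,
        dropped_taxa=tuple(c for c in table.columns if c not in shared),
        dropped_leaves=tuple(l for l in tree.leaves if l not in shared),
    )
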