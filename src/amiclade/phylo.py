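"""Gene-tree computations used by the selection algorithm.

A :class:`FamilyTree` is a rooted tree whose leaves are gene IDs.  Every
internal node induces a *subfamily*: the set of genes descending from it;
nodes further from the root induce more closely related subfamilies.  All
distances here are counts of internal nodes, never branch lengths (branch
lengths, if present in the Newick input, are ignored).

The leaf-to-leaf distance d(i, j) counts every internal node on the unique
path between leaves i and j, including the MRCA and excluding the leaves
themselves, so siblings are at distance 1.  d(i, i) is 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy


class TreeError(ValueError):
    """Structural problem with a tree or a tree query."""


@dataclass(eq=False)
class Node:
    """One tree node; leaves carry a label, internal nodes an integer ID."""

    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    label: str | None = None  # leaf label (gene_id); None for internal
    node_id: int | None = None  # stable postorder ID; None for leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.label})"
        return f"Internal(id={self.node_id}, n_children={len(self.children)})"


class FamilyTree:
    """Rooted gene tree with deterministic integer IDs on internal nodes.

    Internal node IDs are assigned by post-order traversal (children in the
    order they appear in the Newick string), so numbering is a pure function
    of topology and leaf labels; the root always receives the largest ID.
    Multifurcating nodes are accepted.
    """

    def __init__(self, root: Node):
        self.root = root
        self._leaves: dict[str, Node] = {}
        self._internal: list[Node] = []
        self._number(root)
        if len(self._leaves) < 2:
            raise TreeError("a family tree needs at least 2 leaves")

    def _number(self, root: Node) -> None:
        counter = 0
        seen: set[str] = set()

        def walk(node: Node) -> None:
            nonlocal counter
            if node.is_leaf:
                if node.label is None:
                    raise TreeError("unlabeled leaf")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
                self._leaves[node.label] = node
                return
            for child in node.children:
                walk(child)
            node.node_id = counter
            counter += 1
            self._internal.append(node)

        walk(root)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "FamilyTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )

        def convert(dnode) -> Node:
            kids = dnode.child_nodes()
            if not kids:
                label = None
                if dnode.taxon is not None:
                    label = dnode.taxon.label
                elif dnode.label:
                    label = dnode.label
                if label is None:
                    raise TreeError("leaf without a label in Newick input")
                return Node(label=label.replace(" ", "_"))
            node = Node(children=[convert(k) for k in kids])
            for c in node.children:
                c.parent = node
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return node.label  # type: ignore[return-value]
            return "(" + ",".join(fmt(c) for c in node.children) + ")"

        return fmt(self.root) + ";"

    # -- basic queries -----------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaves)

    @property
    def internal_nodes(self) -> list[Node]:
        """Internal nodes in ID (post-order) order."""
        return list(self._internal)

    def node(self, node_id: int) -> Node:
        try:
            return self._internal[node_id]
        except IndexError:
            raise TreeError(f"no internal node with ID {node_id}") from None

    def leaf(self, gene_id: str) -> Node:
        try:
            return self._leaves[gene_id]
        except KeyError:
            raise TreeError(f"unknown gene {gene_id!r}") from None

    def preorder_internal(self) -> list[Node]:
        """Internal nodes root→leaves; children visited in node-ID order."""
        out: list[Node] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                return
            out.append(node)
            kids = [c for c in node.children if not c.is_leaf]
            for c in sorted(kids, key=lambda n: n.node_id):
                walk(c)

        walk(self.root)
        return out

    def ancestors(self, node: Node) -> list[Node]:
        """Strict ancestors of ``node``, nearest first."""
        out = []
        cur = node.parent
        while cur is not None:
            out.append(cur)
            cur = cur.parent
        return out

    def _depth(self, node: Node) -> int:
        d = 0
        cur = node
        while cur.parent is not None:
            d += 1
            cur = cur.parent
        return d


# ---------------------------------------------------------------------------
# operations


def subfamily(tree: FamilyTree, node: Node | int) -> set[str]:
    """Leaf labels of the subtree rooted at an internal node."""
    if isinstance(node, int):
        node = tree.node(node)
    if node.is_leaf:
        raise TreeError("subfamily() requires an internal node, got a leaf")
    out: set[str] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.add(n.label)  # type: ignore[arg-type]
        else:
            stack.extend(n.children)
    return out


def mrca(tree: FamilyTree, genes: Iterable[str]) -> Node:
    """Deepest node whose subfamily contains every gene in ``genes``."""
    genes = list(genes)
    if len(genes) < 2:
        raise TreeError("mrca() needs at least 2 genes")
    paths = []
    for g in genes:
        leaf = tree.leaf(g)
        path = [leaf] + tree.ancestors(leaf)
        paths.append(list(reversed(path)))  # root .. leaf
    anc = None
    for level in zip(*paths):
        first = level[0]
        if all(n is first for n in level):
            anc = first
        else:
            break
    assert anc is not None and not anc.is_leaf
    return anc


def leaf_distance(tree: FamilyTree, i: str, j: str) -> int:
    """Number of internal nodes on the path between leaves i and j.

    Counts every internal node on the path including the MRCA; leaves are
    excluded.  Siblings are therefore at distance 1.  Returns 0 for i == j.
    """
    if i == j:
        tree.leaf(i)  # still validate
        return 0
    a = mrca(tree, [i, j])
    dist = 1  # the MRCA itself
    for g in (i, j):
        cur = tree.leaf(g).parent
        while cur is not a:
            dist += 1
            cur = cur.parent  # type: ignore[assignment]
    return dist


def monophyletic_partition(
    tree: FamilyTree, targets: Iterable[str]
) -> list[set[str]]:
    """Partition ``targets`` into maximal monophyletic blocks.

    Each block is exactly the full leaf set of some subtree (a leaf counts
    as its own subtree); the partition uses the minimum possible number of
    blocks.  Blocks are returned ordered by their smallest member gene ID.
    A multifurcating node's subtree qualifies only as a whole — no grouping
    of a strict subset of its children.
    """
    targets = set(targets)
    if not targets:
        raise TreeError("monophyletic_partition() needs >= 1 target")
    for g in targets:
        tree.leaf(g)

    blocks: list[set[str]] = []

    def walk(node: Node) -> tuple[set[str], bool]:
        """Return (target leaves below node, whether all leaves are targets)."""
        if node.is_leaf:
            hit = node.label in targets
            return ({node.label} if hit else set()), hit
        child_results = [walk(c) for c in node.children]
        below = set().union(*(r[0] for r in child_results))
        pure = below and all(r[1] for r in child_results)
        return below, bool(pure)

    def emit(node: Node) -> None:
        below, pure = walk(node)
        if not below:
            return
        if pure:
            blocks.append(below)
            return
        for c in node.children:
            emit(c)

    emit(tree.root)
    return sorted(blocks, key=min)


def cluster_distance(tree: FamilyTree, A: Iterable[str], B: Iterable[str]) -> int:
    """min over i in A, j in B of leaf_distance(i, j)."""
    A, B = set(A), set(B)
    if not A or not B:
        raise TreeError("clusters must be non-empty")
    if A & B:
        raise TreeError(f"clusters overlap: {sorted(A & B)}")
    return min(leaf_distance(tree, i, j) for i in A for j in B)


def dump_node_numbering(tree: FamilyTree) -> str:
    """Debug TSV of internal node IDs and their subfamilies."""
    lines = ["node_id\tn_leaves\tsubfamily"]
    for n in tree.internal_nodes:
        fam = sorted(subfamily(tree, n))
        lines.append(f"{n.node_id}\t{len(fam)}\t{','.join(fam)}")
    return "\n".join(lines) + "\n"
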