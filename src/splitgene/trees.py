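"""Phylogenetic tree structure and Newick I/O.

Trees are stored rooted for traversal purposes but interpreted as unrooted
by the tests that consume them (the root is just another vertex).  Internal
branches may carry a support value in [0, 1]; Newick internal-node labels are
parsed as supports, with the common 0-100 dialect auto-normalized.
"""

from __future__ import annotations

from typing import Iterator

import dendropy


class TreeNode:
    """Node of a (possibly multifurcating) phylogenetic tree."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<TreeNode {self.name or 'internal'}>"


class PhyloTree:
    """A rooted container for an (un)rooted tree with branch supports."""

    def __init__(self, root: TreeNode):
        self.root = root

    # ---- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find_leaf(self, name: str) -> TreeNode:
        for n in self.postorder():
            if n.is_leaf and n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def copy(self) -> "PhyloTree":
        def _copy(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.support)
            for c in node.children:
                new.add_child(_copy(c))
            return new
        return PhyloTree(_copy(self.root))

    # ---- shape edits ---------------------------------------------------
    def suppress_root_bifurcation(self) -> "PhyloTree":
        """Contract an artificial degree-2 root (rooted -> unrooted view).

        If the root has exactly two children, one child is merged into the
        other side: branch lengths are summed and the surviving edge keeps
        whichever support was set (they describe the same bipartition).
        Modifies the tree in place and returns it.
        """
        root = self.root
        while len(root.children) == 2:
            a, b = root.children
            # merge into the internal child; if both leaves, nothing to do
            keep, move = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                break
            root.remove_child(keep)
            root.remove_child(move)
            for c in list(keep.children):
                keep.remove_child(c)
                root.add_child(c)
            if keep.length is not None or move.length is not None:
                move.length = (move.length or 0.0) + (keep.length or 0.0)
            if move.support is None:
                move.support = keep.support
            root.add_child(move)
            root.name = root.name or keep.name
        return self

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions of the unrooted tree.

        Each is canonicalized as the frozenset of leaf names on the side not
        containing the lexicographically smallest leaf.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        below: dict[int, frozenset] = {}
        out: set[frozenset] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
                continue
            clade = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = clade
            if node is self.root:
                continue
            side = clade if anchor not in clade else all_leaves - clade
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def support_of_bipartition(self) -> dict[frozenset, float | None]:
        """Map each non-trivial bipartition to the support of its branch."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        below: dict[int, frozenset] = {}
        out: dict[frozenset, float | None] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
                continue
            clade = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = clade
            if node is self.root:
                continue
            side = clade if anchor not in clade else all_leaves - clade
            if 1 < len(side) < len(all_leaves) - 1:
                out[side] = node.support
        return out


def _normalize_support(value: float) -> float:
    # Tree builders emit supports either in [0,1] or as percentages.
    return value / 100.0 if value > 1.0 else value


def _from_dendropy(dnode) -> TreeNode:
    length = dnode.edge.length
    name = None
    support = None
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon else dnode.label
    else:
        label = dnode.label
        if label is not None:
            try:
                support = _normalize_support(float(label))
            except ValueError:
                name = label
    node = TreeNode(name=name, length=length, support=support)
    for c in dnode.child_nodes():
        node.add_child(_from_dendropy(c))
    if node.children and support is not None and not (0.0 <= support <= 1.0):
        raise ValueError(f"support {support} outside [0,1]")
    return node


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick tree from a string."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error classes
        pos = getattr(exc, "column", None)
        where = f" near character {pos}" if pos is not None else ""
        raise ValueError(f"Newick parse error{where}: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    tree = PhyloTree(root)
    names = tree.leaf_names()
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in Newick tree")
    for n in tree.postorder():
        if n.length is not None and n.length < 0:
            raise ValueError(f"negative branch length {n.length}")
    return tree


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _fmt(x: float) -> str:
    return format(x, ".10g")


def to_newick(tree: PhyloTree) -> str:
    def _ser(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(_ser(c) for c in node.children) + ")"
            if node.support is not None:
                s += _fmt(node.support)
            elif node.name:
                s += node.name
        if node.length is not None and node.parent is not None:
            s += ":" + _fmt(node.length)
        return s
    return _ser(tree.root) + ";"


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
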