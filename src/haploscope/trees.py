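"""Light-weight phylogenetic tree container.

Trees are stored rooted for traversal but represent unrooted genealogies:
an unrooted binary tree on n leaves is held with a trifurcating root
(n >= 3) or a two-child root (n == 2).  Newick text is parsed with
dendropy and converted into this structure; serialisation is a direct
recursive writer.  All likelihood and parsimony code in this package is
root-placement invariant, so the internal rooting is arbitrary.
"""

from __future__ import annotations

import io as _io
from typing import Iterator, Optional

import dendropy


class NewickParseError(ValueError):
    """Raised when Newick text cannot be parsed."""


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length:g}, deg={len(self.children)})"


class Tree:
    """Rooted container for an (implicitly unrooted) phylogeny."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ walks
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def edges(self) -> list[Node]:
        """Each non-root node identifies the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def n_leaves(self) -> int:
        return len(self.leaves())

    # ------------------------------------------------------------------ copy
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    # --------------------------------------------------------------- rooting
    def reroot_at(self, node: Node) -> None:
        """Re-root in place at ``node`` (must belong to this tree).

        Branch lengths follow the edges they annotate; the former root, if
        left with a single child, is suppressed (its edge lengths merged).
        """
        if node is self.root:
            return
        # Reverse the parent chain from node up to the old root; each edge
        # keeps its length but is re-attributed to its new child end.
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        orig_len = [p.length for p in path]
        for i, (child, parent) in enumerate(zip(path, path[1:])):
            parent.children.remove(child)
            child.add_child(parent)
            parent.length = orig_len[i]
        node.parent = None
        node.length = 0.0
        self.root = node
        self._suppress_unifurcations()

    def _suppress_unifurcations(self) -> None:
        for n in list(self.postorder()):
            if n.parent is not None and len(n.children) == 1:
                child = n.children[0]
                child.length += n.length
                parent = n.parent
                idx = parent.children.index(n)
                parent.children[idx] = child
                child.parent = parent
        if len(self.root.children) == 1 and not self.root.is_leaf:
            only = self.root.children[0]
            if only.children:
                for c in only.children:
                    c.length += 0.0
                only.parent = None
                only.length += self.root.length
                self.root = only

    def unroot(self) -> None:
        """Collapse a two-child root into a trifurcation (n >= 3 leaves)."""
        if len(self.root.children) != 2:
            return
        a, b = self.root.children
        donor = a if a.children else b
        if not donor.children:
            return  # two-leaf tree: nothing to collapse
        keeper = b if donor is a else a
        keeper.length += donor.length
        self.root.children = [keeper]
        for c in donor.children:
            self.root.children.append(c)
            c.parent = self.root

    # --------------------------------------------------------------- newick
    def newick(self, precision: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node.parent is not None:
                core += f":{node.length:.{precision}g}"
            return core

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.newick()})"

    # --------------------------------------------------------------- splits
    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions of the unrooted topology.

        Each split is normalised as the side NOT containing the
        lexicographically smallest leaf label.
        """
        all_labels = frozenset(self.leaf_labels())
        anchor = min(all_labels)
        below: dict[int, frozenset] = {}
        result: set[frozenset] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
            if node.parent is not None and 1 < len(below[id(node)]) < len(all_labels) - 1:
                side = below[id(node)]
                if anchor in side:
                    side = all_labels - side
                result.add(side)
        return result


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Symmetric-difference (RF) distance between two unrooted topologies."""
    sa, sb = a.splits(), b.splits()
    return len(sa ^ sb)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Leaf labels are preserved; absent branch lengths default to 0.  A
    malformed string (unbalanced parentheses, dangling commas) raises
    :class:`NewickParseError` carrying dendropy's position information.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick string")
    if stripped.count("(") != stripped.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs "
            f"{stripped.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Tree(convert(dtree.seed_node))
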