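"""Rooted phylogeny container with Newick I/O, rerooting, and NNI.

Newick parsing and writing are delegated to dendropy; the in-memory
structure is a minimal parent/child tree tuned for the pruning recursion
(postorder traversal, local rearrangement, rerooting along a branch).
"""

from __future__ import annotations

import warnings
from os import PathLike

import dendropy

__all__ = ["TreeNode", "PhyloTree", "read_tree", "parse_newick"]


class TreeError(ValueError):
    pass


class TreeNode:
    """One node of a rooted phylogeny; ``length`` is the branch above it."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} len={self.length:.4g}>"


class PhyloTree:
    """A rooted tree with branch lengths in expected substitutions per site."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.root.parent = None
        self._validate()

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if node.length < 0:
                raise TreeError(f"negative branch length on {node.label!r}: {node.length}")

    # -- traversal -----------------------------------------------------
    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> TreeNode:
        for node in self.postorder():
            if node.label == label:
                return node
        available = sorted(n.label for n in self.postorder() if n.label)
        raise TreeError(f"no node labelled {label!r}; available labels: {available}")

    def branches(self) -> list[TreeNode]:
        """All nodes that carry a branch (everything but the root)."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[TreeNode]:
        """Child nodes of internal (non-pendant) edges."""
        return [
            n for n in self.postorder()
            if n.parent is not None and not n.is_leaf
        ]

    # -- copy / rerooting ---------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.label, node.length)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return PhyloTree(clone(self.root))

    def rerooted_at_edge(self, child_label: str, fraction: float = 0.5) -> "PhyloTree":
        """Return a copy rooted on the branch above the labelled node.

        The branch is split at ``fraction`` of its length (measured from
        the child end). Under a reversible model the likelihood is
        invariant to this operation (the pulley principle).
        """
        tree = self.copy()
        child = tree.find(child_label)
        if child.parent is None:
            raise TreeError("cannot reroot on the root itself")
        old_parent = child.parent
        new_root = TreeNode(None, 0.0)
        below = child.length * fraction
        above = child.length - below
        old_parent.children.remove(child)
        new_root.add_child(child)
        child.length = below
        # walk from old_parent back to the old root, reversing parent links
        path = []
        node = old_parent
        while node is not None:
            path.append(node)
            node = node.parent
        new_root.add_child(old_parent)
        prev_length = above
        for i, node in enumerate(path):
            parent = path[i + 1] if i + 1 < len(path) else None
            node_length = node.length
            node.length = prev_length
            prev_length = node_length
            if parent is not None:
                parent.children.remove(node)
                node.add_child(parent)
        new_tree = PhyloTree(new_root)
        return new_tree._suppress_unifurcations()

    def _suppress_unifurcations(self) -> "PhyloTree":
        changed = True
        while changed:
            changed = False
            for node in self.postorder():
                if node.parent is not None and len(node.children) == 1:
                    only = node.children[0]
                    only.length += node.length
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = only
                    only.parent = parent
                    changed = True
                    break
        if len(self.root.children) == 1:
            only = self.root.children[0]
            only.parent = None
            only.length = 0.0
            self.root = only
        return self

    # -- Newick --------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            label = node.label or ""
            if node.is_leaf:
                body = label
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
            if node.parent is None:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def write(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is not None:
                warnings.warn("branch without length parsed as 0", stacklevel=3)
            length = 0.0
        node = TreeNode(label, length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return PhyloTree(convert(dtree.seed_node))


def parse_newick(newick: str) -> PhyloTree:
    """Parse a Newick string into a rooted :class:`PhyloTree`."""
    dtree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return _from_dendropy(dtree)


def read_tree(path: str | PathLike, expected_leaves: list[str] | None = None) -> PhyloTree:
    """Read a rooted Newick tree; optionally check leaves against an alignment.

    A trifurcating root is accepted. When ``expected_leaves`` is given the
    leaf set must match exactly; the error reports both set differences.
    """
    with open(path) as fh:
        text = fh.read().strip()
    if not text:
        raise TreeError(f"empty tree file: {path}")
    tree = parse_newick(text)
    if expected_leaves is not None:
        have = set(tree.leaf_labels())
        want = set(expected_leaves)
        if have != want:
            raise TreeError(
                "tree/alignment name mismatch; "
                f"only in tree: {sorted(have - want)}; only in alignment: {sorted(want - have)}"
            )
    return tree
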