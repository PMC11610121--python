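"""Phylogenetic tree container and Newick I/O.

Trees are rooted, possibly multifurcating, with non-negative branch lengths
measured in expected substitutions per site. All per-node dynamic programs in
this package run over :class:`TreeNode` objects; Newick text is parsed with
dendropy and converted into this lightweight structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "TreeNode",
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "root_on_branch_midpoint",
    "mammal_fixture_newick",
    "mammal_fixture_tree",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


@dataclass
class TreeNode:
    """A node of a rooted phylogeny.

    Parameters
    ----------
    id : str
        Stable unique label. Leaf labels come from the Newick taxa; unlabeled
        internal nodes receive deterministic preorder labels ``N0, N1, ...``.
    branch_length : float
        Length of the branch above this node (0 for the root).
    """

    id: str
    branch_length: float = 0.0
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    auto_label: bool = False  # label was generated, omitted on write

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id!r}, b={self.branch_length})"


class PhyloTree:
    """Rooted phylogeny with cached traversals and total tree length ``tau``."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()

    def _index(self) -> None:
        self.nodes: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            self.nodes.append(node)
            stack.extend(reversed(node.children))
        labels = [n.id for n in self.nodes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate node labels: {dupes}")
        self.by_id = {n.id: n for n in self.nodes}
        self.leaves = [n for n in self.nodes if n.is_leaf]
        self.leaf_names = {n.id for n in self.leaves}

    @property
    def tau(self) -> float:
        """Total tree length: sum of branch lengths over non-root nodes."""
        return sum(n.branch_length for n in self.nodes if not n.is_root)

    def preorder(self) -> list[TreeNode]:
        return list(self.nodes)

    def postorder(self) -> list[TreeNode]:
        return list(reversed(self.nodes))

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes if not n.is_leaf]

    def mrca(self, labels) -> TreeNode:
        """Most recent common ancestor of the given leaf labels."""
        labels = set(labels)
        if not labels:
            raise ValueError("mrca of an empty label set")
        missing = labels - set(self.by_id)
        if missing:
            raise KeyError(f"unknown leaves: {sorted(missing)}")
        paths = []
        for lab in labels:
            node = self.by_id[lab]
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for rank in range(min(len(p) for p in paths)):
            candidates = {id(p[rank]) for p in paths}
            if len(candidates) == 1:
                mrca = paths[0][rank]
            else:
                break
        return mrca

    def leaf_set(self, node: TreeNode) -> frozenset[str]:
        """Leaf labels of the clade below (and including) ``node``."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.id)
            stack.extend(n.children)
        return frozenset(out)

    def path_length_to_root(self, node: TreeNode) -> float:
        total = 0.0
        while not node.is_root:
            total += node.branch_length
            node = node.parent
        return total

    def copy(self) -> "PhyloTree":
        def clone(n: TreeNode) -> TreeNode:
            m = TreeNode(n.id, n.branch_length, auto_label=n.auto_label)
            for c in n.children:
                m.add_child(clone(c))
            return m

        return PhyloTree(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.nodes)} nodes, tau={self.tau:.4g})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths default to 0 when absent; internal labels are preserved
    when present and generated (``N<k>`` in preorder) otherwise.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    counter = [0]

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label, auto = dnode.taxon.label, False
        elif dnode.label:
            label, auto = dnode.label, False
        else:
            label, auto = f"N{counter[0]}", True
            counter[0] += 1
        bl = dnode.edge.length
        node = TreeNode(label, float(bl) if bl is not None else 0.0,
                        auto_label=auto)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.branch_length = 0.0
    return PhyloTree(root)


def write_newick(tree: PhyloTree, include_auto_labels: bool = False) -> str:
    """Serialize a tree to Newick, preserving explicit internal labels."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        label = "" if (node.auto_label and not include_auto_labels) else node.id
        if node.is_leaf:
            body = node.id
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")" + label
        if is_root:
            return body
        return f"{body}:{node.branch_length:.10g}"

    return fmt(tree.root, True) + ";"


def root_on_branch_midpoint(tree: PhyloTree, clade_a, clade_b) -> PhyloTree:
    """Place the root at the midpoint of the branch joining two sister clades.

    The two clades must be subtrees joined by a single branch (either both
    children of the current root, or one the parent of the other). The total
    tree length tau is conserved; each half of the joining path receives half
    of its length. Returns a new tree; the input is not modified.
    """
    tree = tree.copy()
    clade_a, clade_b = frozenset(clade_a), frozenset(clade_b)
    if clade_a | clade_b != tree.leaf_names or clade_a & clade_b:
        raise ValueError("clades must partition the leaf set")
    node_a = tree.mrca(clade_a)
    node_b = tree.mrca(clade_b)
    a_mono = tree.leaf_set(node_a) == clade_a
    b_mono = tree.leaf_set(node_b) == clade_b
    root = tree.root

    if (a_mono and b_mono and node_a.parent is root and node_b.parent is root
            and len(root.children) == 2):
        # already rooted on the joining branch: rebalance to the midpoint
        half = (node_a.branch_length + node_b.branch_length) / 2.0
        node_a.branch_length = half
        node_b.branch_length = half
        return PhyloTree(root)

    # otherwise one side must be a rooted clade and the other its complement
    # (the joining branch is the edge above that clade's MRCA)
    if a_mono and not node_a.is_root:
        node_b = node_a.parent
    elif b_mono and not node_b.is_root:
        node_a = node_b
        node_b = node_a.parent
    else:
        raise ValueError("clades are not joined by a single branch")
    # reroot on the edge node_b -> node_a; reverse all edges from node_b upward
    path = []
    n = node_b
    while n is not None:
        path.append(n)
        n = n.parent
    old_bl = {id(n): n.branch_length for n in path}
    half = node_a.branch_length / 2.0
    taken = {n.id for n in tree.nodes}
    root_label = "root" if "root" not in taken else "root_mid"
    new_root = TreeNode(root_label)
    node_b.children.remove(node_a)
    node_a.parent = None
    new_root.add_child(node_a)
    node_a.branch_length = half
    for child, parent in zip(path, path[1:]):
        parent.children.remove(child)
    new_root.add_child(node_b)
    node_b.branch_length = half
    for child, parent in zip(path, path[1:]):
        child.add_child(parent)
        parent.branch_length = old_bl[id(child)]
    old_root = path[-1]
    if len(old_root.children) == 1:
        only = old_root.children[0]
        grand = old_root.parent
        grand.children[grand.children.index(old_root)] = only
        only.parent = grand
        only.branch_length += old_root.branch_length
    return PhyloTree(new_root)


#: Six-taxon eutherian fixture topology with lineage-average branch lengths.
mammal_fixture_newick = (
    "((((Human:0.004,Chimp:0.006)HomoPan:0.002,Gorilla:0.014)Homininae:0.015,"
    "Macaque:0.021)Catarrhini:0.109,(Mouse:0.041,Rat:0.045)Murinae:0.092)root;"
)


def mammal_fixture_tree(midpoint_root: bool = True) -> PhyloTree:
    """The six-taxon mammal tree used throughout the simulation study.

    With ``midpoint_root=True`` (default) the root is placed at the midpoint
    of the branch joining the Catarrhini (primates) and Murinae (rodents)
    clades, conserving total tree length.
    """
    tree = parse_newick(mammal_fixture_newick)
    if midpoint_root:
        primates = {"Human", "Chimp", "Gorilla", "Macaque"}
        rodents = {"Mouse", "Rat"}
        tree = root_on_branch_midpoint(tree, primates, rodents)
    return tree
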