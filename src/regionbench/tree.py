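"""Phylogenetic tree container with newick serialization.

A deliberately small node-based tree: enough to hold the output of
neighbor-joining and UPGMA, carry bootstrap supports, restrict to a leaf
subset, and serialize to newick.  Anything fancier (rerooting strategies,
ladderizing, drawing) is out of scope.

Branch lengths are in whatever units the producing algorithm used
(substitutions/site for sequence trees, plain distance for ANI dendrograms).
Support values, when present, are percentages in [0, 100] and are written as
internal node labels, the convention most tree viewers expect.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

from .errors import InvalidArgument, NewickParseError

__all__ = ["TreeNode", "Tree", "parse_newick", "write_newick_string"]


class TreeNode:
    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name: Optional[str] = None,
                 length: Optional[float] = None,
                 support: Optional[float] = None,
                 children: Optional[list["TreeNode"]] = None):
        self.name = name
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def copy(self) -> "TreeNode":
        node = TreeNode(self.name, self.length, self.support)
        node.children = [c.copy() for c in self.children]
        return node


class Tree:
    """A (possibly rooted) tree over uniquely labeled leaves."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidArgument(f"duplicate leaf labels: {dupes}")

    # -- basic accessors ---------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    # -- distances ---------------------------------------------------------

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf (missing lengths count as 0)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length or 0.0
            if node.is_leaf:
                depths[node.name] = acc
            for c in node.children:
                walk(c, acc)

        # the root's own length (if any) is not part of any path
        for c in self.root.children:
            walk(c, 0.0)
        if self.root.is_leaf:
            depths[self.root.name] = 0.0
        return depths

    def pairwise_distances(self) -> tuple[list[str], "object"]:
        """Patristic distance matrix as (labels, ndarray)."""
        import numpy as np

        labels = sorted(self.leaf_names())
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                below = {index[node.name]: 0.0}
            else:
                below = {}
                parts = []
                for c in walk_children(node):
                    parts.append(c)
                for i, part in enumerate(parts):
                    for other in parts[i + 1:]:
                        for a, da in part.items():
                            for b, db in other.items():
                                d = da + db
                                dist[a, b] = dist[b, a] = d
                    below.update(part)
            blen = node.length or 0.0
            return {k: v + blen for k, v in below.items()}

        def walk_children(node: TreeNode):
            return [walk(c) for c in node.children]

        walk(self.root)
        return labels, dist

    # -- editing -----------------------------------------------------------

    def restrict(self, keep: Iterable[str]) -> "Tree":
        """Prune to the given leaf set, suppressing unifurcations.

        Branch lengths along collapsed paths are summed; supports on
        collapsed nodes are dropped.
        """
        keep = set(keep)
        missing = keep - set(self.leaf_names())
        if missing:
            raise InvalidArgument(f"labels not in tree: {sorted(missing)}")

        def rebuild(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                if node.name in keep:
                    return TreeNode(node.name, node.length, node.support)
                return None
            kids = [k for k in (rebuild(c) for c in node.children) if k]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                return child
            return TreeNode(node.name, node.length, node.support, kids)

        root = rebuild(self.root)
        if root is None:
            raise InvalidArgument("restriction removed every leaf")
        if not root.is_leaf and len(root.children) == 1:
            root = root.children[0]
            root.length = None
        return Tree(root, self.rooted)

    def unrooted(self) -> "Tree":
        """Collapse a bifurcating root so split extraction sees one edge.

        A rooted dendrogram's root edge carries no grouping information; the
        two root children are fused into a single multifurcation, which is the
        standard way to place rooted and unrooted trees in one split universe.
        """
        root = self.root.copy()
        if len(root.children) == 2:
            a, b = root.children
            if not b.is_leaf:
                a, b = b, a  # fold the non-leaf child up if possible
            if not a.is_leaf:
                merged = list(a.children) + [b]
                extra = a.length or 0.0
                if b.length is not None or extra:
                    b.length = (b.length or 0.0) + extra
                root = TreeNode(root.name, None, None, merged)
        return Tree(root, rooted=False)

    # -- serialization -----------------------------------------------------

    def newick(self, *, support_as_label: bool = True) -> str:
        return write_newick_string(self, support_as_label=support_as_label)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.n_leaves()} leaves, rooted={self.rooted})"


# ---------------------------------------------------------------------------
# newick serialization


def _fmt_length(x: Optional[float]) -> str:
    return "" if x is None else f":{x:.10g}"


def _fmt_support(x: Optional[float]) -> str:
    if x is None:
        return ""
    if float(x).is_integer():
        return str(int(x))
    return f"{x:.6g}"


def write_newick_string(tree: Tree, *, support_as_label: bool = True) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}{_fmt_length(node.length)}"
        inner = ",".join(render(c) for c in node.children)
        label = node.name or ""
        if support_as_label and node.support is not None:
            label = _fmt_support(node.support)
        return f"({inner}){label}{_fmt_length(node.length)}"

    return render(tree.root) + ";"


def parse_newick(text: str, rooted: Optional[bool] = None) -> Tree:
    """Parse one newick string into a :class:`Tree`.

    Internal node labels that parse as numbers are interpreted as bootstrap
    supports (the common support-as-label dialect); other labels are kept as
    node names.  Parsing itself is delegated to dendropy; its errors are
    re-raised as :class:`NewickParseError` with position information.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"newick parse failure: {exc}") from exc

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        length = dnode.edge.length
        if children:
            name = dnode.label
            support = None
            if name is not None:
                try:
                    support = float(name)
                    name = None
                except ValueError:
                    pass
            return TreeNode(name, length, support, children)
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return TreeNode(label, length)

    root = convert(dtree.seed_node)
    if rooted is None:
        rooted = len(root.children) == 2
    return Tree(root, rooted=rooted)
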