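"""Phylogenetic tree structure, Newick serialization and outgroup rooting.

Branch supports are properties of edges: each node carries the length and
support of the edge connecting it to its parent.  An unrooted tree is stored
rooted at an arbitrary (usually trifurcating) node with ``rooted=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["Node", "PhyloTree", "root_with_outgroup", "unroot"]


@dataclass(eq=False)
class Node:
    name: str | None = None
    length: float | None = None  # branch length of the edge to the parent
    support: float | None = None  # support of the edge to the parent
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.walk() if n.is_leaf())


class PhyloTree:
    """Tree with branch lengths and optional per-edge bootstrap supports."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]  # type: ignore[misc]

    def find_leaf(self, name: str) -> Node:
        for n in self.root.leaves():
            if n.name == name:
                return n
        raise KeyError(f"no leaf named {name!r}")

    # -- bipartitions -----------------------------------------------------

    def splits(self) -> dict[frozenset, Node]:
        """Canonical nontrivial leaf bipartitions, keyed to the child node of
        the defining edge.

        Each split is represented by the side NOT containing the
        lexicographically smallest leaf, so representations agree across
        rootings.  At a rooted root, the two child edges define the same
        split; the first encountered wins.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, Node] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf():
                continue
            below = frozenset(leaf.name for leaf in node.leaves())
            side = all_leaves - below if anchor in below else below
            if 2 <= len(side) <= len(all_leaves) - 2 and side not in out:
                out[side] = node
        return out

    def split_set(self) -> frozenset[frozenset]:
        return frozenset(self.splits().keys())

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths between every leaf pair (name-sorted keys)."""
        dists: dict[tuple[str, str], float] = {}

        def below(node: Node) -> list[tuple[str, float]]:
            if node.is_leaf():
                return [(node.name, 0.0)]  # type: ignore[list-item]
            merged: list[tuple[str, float]] = []
            for child in node.children:
                sub = [(nm, d + (child.length or 0.0)) for nm, d in below(child)]
                for nm_a, d_a in merged:
                    for nm_b, d_b in sub:
                        key = (nm_a, nm_b) if nm_a < nm_b else (nm_b, nm_a)
                        dists[key] = d_a + d_b
                merged.extend(sub)
            return merged

        below(self.root)
        return dists

    # -- Newick -----------------------------------------------------------

    def newick(
        self,
        include_supports: bool = True,
        min_support: float | None = None,
        clamp_negative: bool = False,
    ) -> str:
        """Serialize with 6-decimal branch lengths; supports become integer
        internal-node labels (optionally hidden below ``min_support``)."""

        def fmt(node: Node, is_root: bool) -> str:
            if node.is_leaf():
                label = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = f"({inner})"
                if include_supports and node.support is not None and not is_root:
                    if min_support is None or node.support >= min_support:
                        label += str(int(round(node.support)))
            if node.length is not None and not is_root:
                length = node.length
                if clamp_negative and length < 0:
                    length = 0.0
                label += f":{length:.6f}"
            return label

        return fmt(self.root, True) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: bool | None = None) -> "PhyloTree":
        text = text.strip()
        if not text.endswith(";"):
            raise ValueError("Newick string must end with ';'")
        s = text[:-1]
        pos = 0

        def parse() -> Node:
            nonlocal pos
            node = Node()
            if pos < len(s) and s[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse())
                    if pos >= len(s):
                        raise ValueError("unbalanced parentheses")
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                    raise ValueError(f"unexpected character {s[pos]!r} at {pos}")
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            label = s[start:pos].strip()
            if label:
                if node.is_leaf():
                    node.name = label
                else:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",()":
                    pos += 1
                node.length = float(s[start:pos])
            return node

        root = parse()
        if pos != len(s):
            raise ValueError(f"trailing characters in Newick at {pos}")
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)


# ---------------------------------------------------------------------------
# rerooting


def _adjacency(tree: PhyloTree) -> dict[int, list[tuple[Node, float | None, float | None]]]:
    adj: dict[int, list[tuple[Node, float | None, float | None]]] = {}
    for node in tree.root.walk():
        adj.setdefault(id(node), [])
        for child in node.children:
            adj[id(node)].append((child, child.length, child.support))
            adj.setdefault(id(child), []).append((node, child.length, child.support))
    return adj


def _rebuild(
    node: Node,
    parent: Node | None,
    adj: dict[int, list[tuple[Node, float | None, float | None]]],
    length: float | None,
    support: float | None,
) -> Node:
    new = Node(name=node.name, length=length, support=support)
    for nb, l, s in adj[id(node)]:
        if nb is not parent:
            new.children.append(_rebuild(nb, node, adj, l, s))
    return new


def _suppress_unifurcations(node: Node) -> None:
    for child in node.children:
        _suppress_unifurcations(child)
    if len(node.children) == 1 and node.name is None:
        only = node.children[0]
        node.name = only.name
        node.children = only.children
        node.length = (node.length or 0.0) + (only.length or 0.0)
        if only.support is not None:
            node.support = only.support


def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root on the outgroup's pendant edge (split at its midpoint).

    Supports stay attached to the same bipartitions: rerooting only reorients
    edges, and each edge keeps its support through the rebuild.
    """
    leaf = tree.find_leaf(outgroup)  # raises KeyError for unknown taxa
    adj = _adjacency(tree)
    neighbors = adj[id(leaf)]
    if len(neighbors) != 1:
        raise ValueError(f"outgroup {outgroup!r} is not a pendant leaf")
    attach, pend_len, pend_sup = neighbors[0]
    half = None if pend_len is None else pend_len / 2.0

    root = Node()
    root.children.append(Node(name=leaf.name, length=half))
    root.children.append(_rebuild(attach, leaf, adj, half, pend_sup))
    for child in root.children:
        _suppress_unifurcations(child)
    return PhyloTree(root, rooted=True)


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a rooted tree's bifurcating root into a trifurcation."""
    if not tree.rooted or len(tree.root.children) != 2:
        return PhyloTree(tree.root, rooted=False)
    a, b = tree.root.children
    internal = b if not b.is_leaf() else a
    other = a if internal is b else b
    joined = (a.length or 0.0) + (b.length or 0.0)
    adj = _adjacency(tree)
    new_root = Node()
    for nb, l, s in adj[id(internal)]:
        if nb is tree.root:
            continue
        new_root.children.append(_rebuild(nb, internal, adj, l, s))
    carried = other.support if other.support is not None else internal.support
    new_root.children.append(
        _rebuild(other, tree.root, adj, joined, carried)
    )
    for child in new_root.children:
        _suppress_unifurcations(child)
    return PhyloTree(new_root, rooted=False)
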