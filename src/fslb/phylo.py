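"""Trees, bipartitions and patristic distances.

The tree model is deliberately small: a rooted node structure used purely as a
storage/traversal convenience, with *all* split and distance logic treating the
tree as unrooted.  Branch lengths are expected numbers of substitutions per
site; a missing length is an error wherever lengths matter (a long-branch score
is meaningless without them), never silently zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloError",
    "MissingBranchLengthError",
    "Bipartition",
    "Node",
    "PhyloTree",
    "splits_compatible",
]


class PhyloError(ValueError):
    """Invalid tree operation or malformed tree."""


class MissingBranchLengthError(PhyloError):
    """An edge required a branch length that was not present."""


# ---------------------------------------------------------------------------
# Bipartitions


class Bipartition:
    """An unrooted split: two complementary, non-empty tip-label sets.

    Equality and hashing are invariant to which side is given first.  A
    "clade" in unrooted analyses is shorthand for one side of a split, and
    support values attach to the split, not to either side.
    """

    __slots__ = ("_sides", "_universe")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise PhyloError("both sides of a bipartition must be non-empty")
        if a & b:
            raise PhyloError(f"bipartition sides overlap: {sorted(a & b)}")
        self._sides = frozenset((a, b))
        self._universe = a | b

    @property
    def sides(self) -> tuple[frozenset, frozenset]:
        pair = sorted(self._sides, key=lambda s: sorted(s))
        if len(pair) == 1:  # degenerate: cannot happen (sides disjoint, non-empty)
            raise PhyloError("bipartition has identical sides")
        return pair[0], pair[1]

    @property
    def universe(self) -> frozenset:
        return self._universe

    def side_of(self, label: str) -> frozenset:
        for s in self._sides:
            if label in s:
                return s
        raise KeyError(label)

    def is_trivial(self) -> bool:
        return min(len(s) for s in self._sides) <= 1

    def restrict(self, universe: Iterable[str]) -> Optional["Bipartition"]:
        """Restrict to a smaller taxon universe; None if a side empties."""
        u = frozenset(universe)
        a, b = self.sides
        a, b = a & u, b & u
        if not a or not b:
            return None
        return Bipartition(a, b)

    def __eq__(self, other) -> bool:
        return isinstance(other, Bipartition) and self._sides == other._sides

    def __hash__(self) -> int:
        return hash(self._sides)

    def __repr__(self) -> str:
        a, b = self.sides
        return f"Bipartition({set(sorted(a))!r} | {set(sorted(b))!r})"


def splits_compatible(a: Bipartition, b: Bipartition) -> bool:
    """Four-point compatibility: can one tree display both splits?

    Splits on different universes are first restricted to the shared taxa;
    fully disjoint universes are rejected.  Two splits are compatible iff at
    least one of the four pairwise side intersections is empty.
    """
    shared = a.universe & b.universe
    if not shared:
        raise PhyloError("bipartitions have disjoint taxon universes")
    if a.universe != b.universe:
        ra, rb = a.restrict(shared), b.restrict(shared)
        if ra is None or rb is None:
            return True  # one split vanishes on the shared universe
        a, b = ra, rb
    a1, a2 = a.sides
    b1, b2 = b.sides
    return not a1 & b1 or not a1 & b2 or not a2 & b1 or not a2 & b2


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None  # length of the edge above this node
    support: Optional[float] = None  # support attached to the edge above
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        self.children.append(child)
        return child


class PhyloTree:
    """Tip-labelled tree with branch lengths.

    Stored rooted (at an arbitrary node) but treated as unrooted by every
    split/distance operation.  Tip labels must be unique and non-empty;
    polytomies are allowed.
    """

    def __init__(self, root: Node):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if any(not lbl for lbl in labels):
            raise PhyloError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PhyloError(f"duplicate tip labels: {dupes}")
        for node in self.preorder():
            if node.length is not None and (not np.isfinite(node.length) or node.length < 0):
                raise PhyloError(f"edge above {node.label or '<internal>'} has invalid length {node.length}")

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.preorder() if n.is_leaf)

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_tips(self) -> int:
        return sum(1 for _ in self.leaves())

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse Newick (quoted labels and polytomies allowed).

        Numeric internal-node labels are read as edge support values, the
        convention most bootstrap-annotated trees follow.
        """
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise PhyloError(f"malformed Newick: {exc}") from exc

        def convert(dnode) -> Node:
            node = Node()
            if dnode.is_leaf():
                node.label = dnode.taxon.label if dnode.taxon else dnode.label
            else:
                raw = dnode.label
                if raw is not None:
                    try:
                        node.support = float(raw)
                    except ValueError:
                        node.label = raw
            node.length = dnode.edge.length
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        root = convert(dtree.seed_node)
        root.length = None  # a root edge carries no information on an unrooted tree
        return cls(root)

    def to_newick(self, precision: int = 6, include_support: bool = True) -> str:
        """Serialize with fixed-precision lengths (byte-stable output)."""

        def needs_quotes(label: str) -> bool:
            return any(c in label for c in " \t()[]{}:;,'\"")

        def fmt_label(label: Optional[str]) -> str:
            if label is None:
                return ""
            if needs_quotes(label):
                return "'" + label.replace("'", "''") + "'"
            return label

        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = fmt_label(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_support and node.support is not None:
                    s += format(node.support, "g")
                else:
                    s += fmt_label(node.label)
            if node.length is not None:
                s += f":{node.length:.{precision}f}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write(self, path, precision: int = 6) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(precision=precision) + "\n")

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            return Node(node.label, node.length, node.support, [dup(c) for c in node.children])

        return PhyloTree(dup(self.root))

    def __repr__(self) -> str:
        return f"PhyloTree({self.n_tips()} tips)"

    # -- distances ---------------------------------------------------------

    def patristic_distance_matrix(self) -> pd.DataFrame:
        """Tip-to-tip path-length sums, as a symmetric labelled matrix.

        Raises :class:`MissingBranchLengthError` naming the offending edge if
        any edge on a tip path lacks a length.
        """
        tips = list(self.leaves())
        if len(tips) < 2:
            raise PhyloError("patristic distances need at least 2 tips")
        labels = [t.label for t in tips]
        index = {id(t): i for i, t in enumerate(tips)}
        n = len(tips)
        dist = np.zeros((n, n))

        def edge_length(node: Node) -> float:
            if node.length is None:
                raise MissingBranchLengthError(
                    f"edge above {node.label or 'internal node'} has no branch length"
                )
            return node.length

        # Post-order: carry up (tip index, distance-to-current-node) lists,
        # filling cross-child pairs at each internal node.
        below: dict[int, list[tuple[int, float]]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = [(index[id(node)], 0.0)]
                continue
            groups = []
            for child in node.children:
                w = edge_length(child)
                groups.append([(i, d + w) for i, d in below.pop(id(child))])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            dist[i, j] = dist[j, i] = di + dj
            below[id(node)] = [pair for g in groups for pair in g]
        return pd.DataFrame(dist, index=labels, columns=labels)

    # -- splits ------------------------------------------------------------

    def splits_of(self) -> set[Bipartition]:
        """Non-trivial splits, one per internal edge of the unrooted tree."""
        universe = frozenset(self.tip_labels)
        splits: set[Bipartition] = set()
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        for node in self.preorder():
            if node is self.root:
                continue
            side = below[id(node)]
            other = universe - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(Bipartition(side, other))
        return splits

    def split_support_map(self) -> dict[Bipartition, Optional[float]]:
        """Non-trivial splits with the support read off their edges."""
        universe = frozenset(self.tip_labels)
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            below[id(node)] = (
                frozenset([node.label])
                if node.is_leaf
                else frozenset().union(*(below[id(c)] for c in node.children))
            )
        out: dict[Bipartition, Optional[float]] = {}
        for node in self.preorder():
            if node is self.root:
                continue
            side = below[id(node)]
            other = universe - side
            if len(side) >= 2 and len(other) >= 2:
                split = Bipartition(side, other)
                prev = out.get(split)
                if prev is None:
                    out[split] = node.support
        return out

    # -- pruning -----------------------------------------------------------

    def prune_taxa(self, drop: Iterable[str]) -> "PhyloTree":
        """Remove tips, suppressing degree-2 nodes by summing their edges.

        Patristic distances among retained tips are unchanged.
        """
        drop = set(drop)
        present = set(self.tip_labels)
        unknown = drop - present
        if unknown:
            raise PhyloError(f"cannot drop taxa absent from tree: {sorted(unknown)}")
        if len(present - drop) < 2:
            raise PhyloError("pruning must leave at least 2 tips")

        def rebuild(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.label in drop:
                    return None
                return Node(node.label, node.length, node.support)
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:  # suppress the degree-2 node: merge edge lengths
                child = kids[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                return child
            return Node(node.label, node.length, node.support, kids)

        root = rebuild(self.root)
        assert root is not None
        if not root.is_leaf and len(root.children) == 1:
            # The old root survives with a single child: that child's edge lies
            # on no tip-to-tip path, so the child becomes the new root.
            root = root.children[0]
            root.length = None
        root.length = None
        return PhyloTree(root)
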