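"""Strain trees: a small rooted/unrooted tree container with Newick I/O.

Trees over strain labels are used for two things: specifying simulated
genealogies, and reporting parsimony searches and bootstrap consensus.
Unrooted trees are represented rooted at an arbitrary base; topology
comparisons always go through :meth:`Tree.bipartitions`, which is
rooting-invariant.  Internal node labels carry bootstrap support strings
(e.g. ``"87/91"`` for Camin-Sokal / Wagner percentages).
"""

from __future__ import annotations

import re
from typing import Iterator

__all__ = ["Node", "Tree", "tree_from_bipartitions"]

_UNQUOTED_OK = re.compile(r"^[^\s()\[\]{}:;,\"']+$")


class Node:
    """A tree node; leaves have a ``label``, internal nodes may carry
    a ``support`` string written as the Newick internal label."""

    __slots__ = ("label", "children", "support")

    def __init__(self, label=None, children=None, support=None):
        self.label = label
        self.children: list[Node] = children if children is not None else []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"Node({self.label!r})" if self.is_leaf else f"Node(<{len(self.children)}>)"


class Tree:
    """A tree over uniquely labeled leaves."""

    def __init__(self, root: Node):
        self.root = root
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string (branch lengths accepted and ignored)."""
        s = text.strip()
        if not s.endswith(";"):
            raise ValueError("Newick string must end with ';'")
        s = s[:-1]
        pos = 0

        def parse_label() -> str | None:
            nonlocal pos
            if pos < len(s) and s[pos] == "'":
                end = pos + 1
                out = []
                while end < len(s):
                    if s[end] == "'":
                        if end + 1 < len(s) and s[end + 1] == "'":
                            out.append("'")
                            end += 2
                            continue
                        break
                    out.append(s[end])
                    end += 1
                else:
                    raise ValueError("unterminated quoted label")
                pos = end + 1
                return "".join(out)
            m = re.match(r"[^\s()\[\]:;,]+", s[pos:])
            if not m:
                return None
            pos += m.end()
            return m.group(0)

        def skip_length():
            nonlocal pos
            if pos < len(s) and s[pos] == ":":
                pos += 1
                m = re.match(r"[-+0-9.eE]+", s[pos:])
                if not m:
                    raise ValueError(f"bad branch length at {pos}")
                pos += m.end()

        def parse_node() -> Node:
            nonlocal pos
            if pos < len(s) and s[pos] == "(":
                pos += 1
                children = [parse_node()]
                while pos < len(s) and s[pos] == ",":
                    pos += 1
                    children.append(parse_node())
                if pos >= len(s) or s[pos] != ")":
                    raise ValueError(f"expected ')' at {pos}")
                pos += 1
                sup = parse_label()
                skip_length()
                return Node(children=children, support=sup)
            label = parse_label()
            if label is None:
                raise ValueError(f"expected label at {pos}")
            skip_length()
            return Node(label=label)

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters at {pos}: {s[pos:]!r}")
        return cls(root)

    # -- traversal ----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- topology -----------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each given as the side that
        excludes the lexicographically smallest leaf label."""
        taxa = set(self.leaf_labels())
        ref = min(taxa)
        n = len(taxa)
        splits: set[frozenset] = set()
        below: dict[int, set] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.label}
            else:
                acc = set()
                for c in node.children:
                    acc |= below[id(c)]
                below[id(node)] = acc
                side = acc if ref not in acc else taxa - acc
                if 2 <= len(side) <= n - 2:
                    splits.add(frozenset(side))
        return splits

    def same_unrooted_topology(self, other: "Tree") -> bool:
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            return False
        return self.bipartitions() == other.bipartitions()

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def fmt_label(label: str) -> str:
            if _UNQUOTED_OK.match(label):
                return label
            return "'" + label.replace("'", "''") + "'"

        def fmt(node: Node) -> str:
            if node.is_leaf:
                return fmt_label(node.label)
            inner = ",".join(fmt(c) for c in node.children)
            sup = fmt_label(str(node.support)) if node.support is not None else ""
            return f"({inner}){sup}"

        return fmt(self.root) + ";"

    def __repr__(self):
        return f"Tree({self.to_newick()})"


def tree_from_bipartitions(
    splits,
    taxa: list[str],
    support: dict[frozenset, str] | None = None,
) -> Tree:
    """Build the (possibly multifurcating) tree displaying exactly the given
    pairwise-compatible bipartitions.

    ``splits`` are frozensets of leaf labels, each excluding ``taxa[0]``
    (the base taxon).  The tree is returned with a base polytomy at
    ``taxa[0]``'s attachment, the standard unrooted convention.
    """
    support = support or {}
    base = taxa[0]
    rest = [t for t in taxa if t != base]
    # items: (leafset, Node), built smallest-first so clusters nest
    items: list[tuple[set, Node]] = [({t}, Node(label=t)) for t in rest]
    for split in sorted(splits, key=lambda s: (len(s), sorted(s))):
        split = set(split)
        if base in split:
            raise ValueError("split contains the base taxon")
        members = [(ls, nd) for ls, nd in items if ls <= split]
        covered = set().union(*(ls for ls, _ in members)) if members else set()
        if covered != split:
            raise ValueError(f"incompatible split {sorted(split)}")
        node = Node(children=[nd for _, nd in members],
                    support=support.get(frozenset(split)))
        items = [(ls, nd) for ls, nd in items if not (ls <= split)]
        items.append((split, node))
        items.sort(key=lambda p: min(p[0]))
    root = Node(children=[Node(label=base)] + [nd for _, nd in items])
    return Tree(root)
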