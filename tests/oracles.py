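"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive enumeration and direct
formula transcription — and shares no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np


def least_squares_three_segments(x: np.ndarray) -> tuple[int, int]:
    """Exhaustive best 3-segment partition of x by residual sum of squares.

    Returns (first, last) probe indices (inclusive) of the middle segment.
    """
    n = len(x)
    best = None
    for i in range(1, n - 1):
        for j in range(i + 1, n):
            sse = 0.0
            for seg in (x[:i], x[i:j], x[j:]):
                sse += float(((seg - seg.mean()) ** 2).sum())
            if best is None or sse < best[0] - 1e-12:
                best = (sse, i, j)
    return best[1], best[2] - 1


def _tree_edges(node, parent_id, edges, leaves, counter):
    my_id = counter[0]
    counter[0] += 1
    if parent_id is not None:
        edges.append((parent_id, my_id))
    if not node.children:
        leaves[my_id] = node.label
    for c in node.children:
        _tree_edges(c, my_id, edges, leaves, counter)
    return my_id


def _enumerate_assignments(tree, carriers: set):
    """Yield (state vector over nodes) for every assignment with leaves
    fixed to their carrier status."""
    edges: list[tuple[int, int]] = []
    leaves: dict[int, str] = {}
    counter = [0]
    _tree_edges(tree.root, None, edges, leaves, counter)
    n_nodes = counter[0]
    internal = [i for i in range(n_nodes) if i not in leaves]
    for combo in itertools.product((0, 1), repeat=len(internal)):
        states = {}
        for i, s in zip(internal, combo):
            states[i] = s
        for i, label in leaves.items():
            states[i] = 1 if label in carriers else 0
        yield states, edges

def brute_force_wagner(tree, carriers: set) -> int:
    """Minimum state changes over all internal-node assignments."""
    best = None
    for states, edges in _enumerate_assignments(tree, carriers):
        changes = sum(states[a] != states[b] for a, b in edges)
        if best is None or changes < best:
            best = changes
    return best


def brute_force_camin_sokal(tree, carriers: set) -> int:
    """Minimum 0→1 gains with 1→0 forbidden, ancestor state 0 above the
    root: invalid if any edge loses the character; the root in state 1
    counts as a gain on the ancestor edge."""
    best = None
    for states, edges in _enumerate_assignments(tree, carriers):
        if any(states[a] == 1 and states[b] == 0 for a, b in edges):
            continue
        gains = states[0] + sum(
            states[a] == 0 and states[b] == 1 for a, b in edges
        )
        if best is None or gains < best:
            best = gains
    return best


def ia_s_reference(values: np.ndarray) -> float:
    """Standardized index of association, transcribed directly from the
    mismatch-variance formulation."""
    n, l = values.shape
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(sum(values[i, k] != values[j, k] for k in range(l)))
    dists = np.array(dists, float)
    v_d = ((dists - dists.mean()) ** 2).mean()
    v_e = 0.0
    for k in range(l):
        p = values[:, k].mean()
        v_e += (n / (n - 1)) * (1 - p * p - (1 - p) * (1 - p))
    return (v_d / v_e - 1) / (l - 1)


def genes_in_span(genes, chrom: str, start: int, end: int):
    """Naive interval scan: (gene_id, wholly|partially) for genes
    overlapping [start, end] on chrom."""
    out = []
    for g in sorted(genes, key=lambda g: g.start):
        if g.chromosome != chrom:
            continue
        if g.end < start or g.start > end:
            continue
        out.append((g.gene_id, "wholly" if start <= g.start and g.end <= end else "partially"))
    return out


def all_unrooted_topologies(labels):
    """All unrooted binary topologies over labels as cghindel Trees
    (grown by sequential edge insertion on nested tuples)."""
    from cghindel.trees import Node, Tree

    def insertions(t, x):
        yield (t, x)
        if not isinstance(t, int):
            for s in insertions(t[0], x):
                yield (s, t[1])
            for s in insertions(t[1], x):
                yield (t[0], s)

    def grow(rest, k):
        if k == len(labels):
            yield rest
            return
        for t in insertions(rest, k):
            yield from grow(t, k + 1)

    def to_tree(rest):
        def rec(t):
            if isinstance(t, int):
                return Node(label=labels[t])
            return Node(children=[rec(t[0]), rec(t[1])])

        return Tree(Node(children=[Node(label=labels[0]), rec(rest)]))

    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    yield from (to_tree(r) for r in grow((1, 2), 3))
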