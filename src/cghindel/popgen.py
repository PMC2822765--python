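"""Strain relationships from deletion markers, and multilocus LD.

Deletion loci are binary presence/absence characters.  Two parsimony
criteria score candidate strain trees:

* **Wagner** parsimony (the Fitch count for binary characters): gains and
  losses cost 1 each and no ancestral state is presumed; the count is
  independent of rooting.
* **Camin-Sokal** parsimony: deletions are derived, so only 0→1 changes are
  allowed relative to a hypothetical deletion-free ancestor.  The minimum
  number of gains for a character equals the number of maximal
  carrier-only subtrees of the rooted tree, so the score depends on where
  the ancestor attaches.  A :class:`~cghindel.trees.Tree` is scored as
  rooted at its own base; trees built by the search place the base on the
  first strain's terminal edge, and that convention is kept in output so
  reported trees rescore identically.

Tree search supports exhaustive enumeration (n ≤ 8), exact
branch-and-bound (n ≤ 12), and heuristic stepwise addition with jumbled
input orders plus nearest-neighbor-interchange refinement.  Bootstrap
support comes from resampling locus columns with replacement and taking
the majority-rule consensus; tied optimal trees contribute fractionally.

Multilocus linkage disequilibrium is measured by the standardized index
of association I_A^S = (V_D/V_e − 1)/(l − 1), where V_D is the variance of
the pairwise mismatch distances and V_e = Σ_j h_j its expectation at
linkage equilibrium; significance comes from a Monte Carlo null that
permutes each locus column independently among strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .trees import Node, Tree, tree_from_bipartitions

__all__ = [
    "PresenceAbsenceMatrix",
    "wagner_score",
    "camin_sokal_score",
    "search_most_parsimonious",
    "bootstrap_consensus",
    "BootstrapResult",
    "LDResult",
    "ia_s",
    "ia_s_permutation_test",
]


class PresenceAbsenceMatrix:
    """Binary strains × loci marker matrix.

    Rows are strains, columns are locus ids, cells are 0/1 carrier
    indicators.  Columns with no carrier are rejected: a locus nobody
    carries is not a marker.
    """

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")
        if data.index.duplicated().any() or data.columns.duplicated().any():
            raise ValueError("duplicate strain or locus labels")
        if (values.sum(axis=0) == 0).any():
            bad = data.columns[values.sum(axis=0) == 0][0]
            raise ValueError(f"locus {bad!r} has no carriers")
        self.data = data.astype(np.int8)

    @classmethod
    def from_arrays(cls, values, strains, loci) -> "PresenceAbsenceMatrix":
        return cls(pd.DataFrame(np.asarray(values), index=list(strains), columns=list(loci)))

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_strains(self) -> int:
        return self.data.shape[0]

    @property
    def n_loci(self) -> int:
        return self.data.shape[1]

    def __repr__(self):
        return f"PresenceAbsenceMatrix({self.n_strains} strains x {self.n_loci} loci)"


# ---------------------------------------------------------------------------
# scoring on Tree objects

def _leaf_states(matrix: PresenceAbsenceMatrix, weights=None):
    states = {s: matrix.values[i] for i, s in enumerate(matrix.strains)}
    w = np.ones(matrix.n_loci) if weights is None else np.asarray(weights, float)
    return states, w


def _check_leaves(tree: Tree, matrix: PresenceAbsenceMatrix):
    if set(tree.leaf_labels()) != set(matrix.strains):
        raise ValueError("tree leaves do not match matrix strains")


def wagner_score(tree: Tree, matrix: PresenceAbsenceMatrix, weights=None) -> float:
    """Sum over loci of the Fitch minimum-change count (binary trees).

    Polytomies are resolved by sequential pairwise combination, which is
    exact for binary trees and for a trifurcating base.
    """
    _check_leaves(tree, matrix)
    states, w = _leaf_states(matrix, weights)
    total = 0.0

    def rec(node: Node) -> np.ndarray:
        nonlocal total
        if node.is_leaf:
            return np.left_shift(1, states[node.label]).astype(np.uint8)
        acc = rec(node.children[0])
        for child in node.children[1:]:
            b = rec(child)
            inter = acc & b
            empty = inter == 0
            total += w[empty].sum()
            acc = np.where(empty, acc | b, inter)
        return acc

    rec(tree.root)
    out = float(total)
    return int(out) if weights is None else out


def camin_sokal_score(tree: Tree, matrix: PresenceAbsenceMatrix, weights=None) -> float:
    """Sum over loci of the minimum number of 0→1 gains with reversals
    forbidden, relative to an all-absent ancestor at the tree's root.

    Equals the number of maximal carrier-only subtrees per locus.
    """
    _check_leaves(tree, matrix)
    states, w = _leaf_states(matrix, weights)
    total = 0.0

    def rec(node: Node) -> np.ndarray:
        nonlocal total
        if node.is_leaf:
            return states[node.label] == 1
        child_pure = [rec(c) for c in node.children]
        pure = child_pure[0].copy()
        for p in child_pure[1:]:
            pure &= p
        for p in child_pure:
            total += w[p & ~pure].sum()
        return pure

    root_pure = rec(tree.root)
    total += w[root_pure].sum()
    out = float(total)
    return int(out) if weights is None else out


# ---------------------------------------------------------------------------
# fast internal scoring on nested-tuple trees
#
# A candidate tree over strains 0..n-1 is the nested tuple `rest` covering
# strains 1..n-1, with strain 0 attached at a base node above it (Newick
# "(S0, rest);").  Leaves are strain indices; internal nodes are pairs.

def _fitch_cost(rest, masks: np.ndarray, w: np.ndarray) -> float:
    total = 0.0

    def rec(t):
        nonlocal total
        if isinstance(t, int):
            return masks[t]
        a = rec(t[0])
        b = rec(t[1])
        inter = a & b
        empty = inter == 0
        total += w[empty].sum()
        return np.where(empty, a | b, inter)

    m = rec(rest)
    inter = m & masks[0]
    total += w[inter == 0].sum()
    return total


def _cs_cost(rest, carriers: np.ndarray, w: np.ndarray) -> float:
    total = 0.0

    def rec(t):
        nonlocal total
        if isinstance(t, int):
            return carriers[t]
        a = rec(t[0])
        b = rec(t[1])
        pure = a & b
        total += w[a & ~pure].sum() + w[b & ~pure].sum()
        return pure

    p_rest = rec(rest)
    p0 = carriers[0]
    root_pure = p_rest & p0
    total += w[root_pure].sum()
    total += w[p_rest & ~root_pure].sum() + w[p0 & ~root_pure].sum()
    return total


def _make_cost_fn(matrix: PresenceAbsenceMatrix, method: str, weights=None):
    """Cost over nested-tuple trees, with duplicate locus patterns folded
    into weights so bootstrap replicates only reweight."""
    w = np.ones(matrix.n_loci) if weights is None else np.asarray(weights, float)
    patterns, inverse = np.unique(matrix.values, axis=1, return_inverse=True)
    wu = np.bincount(inverse, weights=w, minlength=patterns.shape[1])
    keep = wu > 0
    patterns, wu = patterns[:, keep], wu[keep]
    if method == "wagner":
        masks = np.left_shift(1, patterns).astype(np.uint8)
        return lambda rest: _fitch_cost(rest, masks, wu)
    if method == "camin_sokal":
        carriers = patterns == 1
        return lambda rest: _cs_cost(rest, carriers, wu)
    raise ValueError(f"unknown parsimony method {method!r}")


# -- tree manipulation on nested tuples -------------------------------------

def _insertions(t, x):
    """All trees obtained by attaching leaf x on some edge of subtree t
    (including t's own parent edge)."""
    yield (t, x)
    if not isinstance(t, int):
        a, b = t
        for s in _insertions(a, x):
            yield (s, b)
        for s in _insertions(b, x):
            yield (a, s)


def _nni_neighbors(t):
    """Nearest-neighbor-interchange neighbors (2 per internal edge)."""
    if isinstance(t, int):
        return
    a, b = t
    if not isinstance(a, int):
        x, y = a
        yield ((x, b), y)
        yield ((y, b), x)
    if not isinstance(b, int):
        x, y = b
        yield (x, (y, a))
        yield (y, (x, a))
    for s in _nni_neighbors(a):
        yield (s, b)
    for s in _nni_neighbors(b):
        yield (a, s)


def _splits_key(rest, n) -> frozenset:
    """Canonical unrooted-topology key: frozenset of leafset bitmasks."""
    splits = set()

    def rec(t) -> int:
        if isinstance(t, int):
            return 1 << t
        m = rec(t[0]) | rec(t[1])
        if 2 <= bin(m).count("1") <= n - 2:
            splits.add(m)
        return m

    rec(rest)
    return frozenset(splits)


def _tuple_to_tree(rest, labels) -> Tree:
    def rec(t) -> Node:
        if isinstance(t, int):
            return Node(label=labels[t])
        return Node(children=[rec(t[0]), rec(t[1])])

    return Tree(Node(children=[Node(label=labels[0]), rec(rest)]))


def _num_topologies(n: int) -> int:
    out = 1
    for k in range(3, n):
        out *= 2 * k - 3
    return out


def _exhaustive(order, cost_fn, n):
    """Enumerate every unrooted topology; return (best_cost, [rest...])."""
    best = [np.inf, []]

    def rec(rest, k):
        if k == len(order):
            c = cost_fn(rest)
            if c < best[0] - 1e-9:
                best[0], best[1] = c, [rest]
            elif abs(c - best[0]) <= 1e-9:
                best[1].append(rest)
            return
        for t in _insertions(rest, order[k]):
            rec(t, k + 1)

    if len(order) == 2:
        return cost_fn(order[1]), [order[1]]
    rec((order[1], order[2]), 3)
    return best[0], best[1]


def _branch_and_bound(order, cost_fn, upper):
    """Exact search: prune partial trees whose cost already exceeds the
    incumbent (parsimony cost never decreases as taxa are added)."""
    best = [upper, []]

    def rec(rest, k):
        c = cost_fn(rest)
        if c > best[0] + 1e-9:
            return
        if k == len(order):
            if c < best[0] - 1e-9:
                best[0], best[1] = c, [rest]
            elif abs(c - best[0]) <= 1e-9:
                best[1].append(rest)
            return
        for t in _insertions(rest, order[k]):
            rec(t, k + 1)

    if len(order) == 2:
        return cost_fn(order[1]), [order[1]]
    rec((order[1], order[2]), 3)
    return best[0], best[1]


def _stepwise_addition(order, cost_fn):
    if len(order) == 2:
        return order[1]
    rest = (order[1], order[2])
    for x in order[3:]:
        rest = min(_insertions(rest, x), key=cost_fn)
    return rest


def _hill_climb(rest, cost_fn, max_passes: int = 100):
    cost = cost_fn(rest)
    for _ in range(max_passes):
        improved = False
        for nb in _nni_neighbors(rest):
            c = cost_fn(nb)
            if c < cost - 1e-9:
                rest, cost, improved = nb, c, True
                break
        if not improved:
            break
    return rest, cost


def _heuristic(strain_idx, cost_fn, n_jumbles, rng):
    best_cost = np.inf
    best: dict[frozenset, tuple] = {}
    n = len(strain_idx)
    rest_idx = list(strain_idx[1:])
    for _ in range(max(1, n_jumbles)):
        order = [strain_idx[0]] + [int(i) for i in rng.permutation(rest_idx)]
        rest = _stepwise_addition(order, cost_fn)
        rest, cost = _hill_climb(rest, cost_fn)
        if cost < best_cost - 1e-9:
            best_cost, best = cost, {_splits_key(rest, n): rest}
        elif abs(cost - best_cost) <= 1e-9:
            best.setdefault(_splits_key(rest, n), rest)
    return best_cost, list(best.values())


def _dedupe(rests, n):
    seen = {}
    for r in rests:
        seen.setdefault(_splits_key(r, n), r)
    return list(seen.values())


def search_most_parsimonious(
    matrix: PresenceAbsenceMatrix,
    method: str = "wagner",
    strategy: str = "branch_and_bound",
    seed: int = 0,
    n_jumbles: int = 10,
    weights=None,
) -> list[Tree]:
    """Find all tied most-parsimonious unrooted trees.

    ``exhaustive`` enumerates every topology (n ≤ 8); ``branch_and_bound``
    is exact (intended for n ≤ 12); ``heuristic`` is seeded stepwise
    addition with ``n_jumbles`` input orders plus NNI refinement.  Each
    returned tree carries its score in ``tree.score``.
    """
    n = matrix.n_strains
    if n < 4:
        raise ValueError("need at least 4 strains for tree inference")
    cost_fn = _make_cost_fn(matrix, method, weights)
    idx = list(range(n))
    if strategy == "exhaustive":
        if n > 8:
            raise ValueError(
                "exhaustive enumeration supports at most 8 strains "
                f"({_num_topologies(n)} topologies at n={n}); "
                "use branch_and_bound or heuristic"
            )
        cost, rests = _exhaustive(idx, cost_fn, n)
    elif strategy == "branch_and_bound":
        start = _stepwise_addition(idx, cost_fn)
        start, upper = _hill_climb(start, cost_fn)
        cost, rests = _branch_and_bound(idx, cost_fn, upper)
        rests = _dedupe(rests, n)
    elif strategy == "heuristic":
        rng = np.random.default_rng(seed)
        cost, rests = _heuristic(idx, cost_fn, n_jumbles, rng)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    trees = []
    for r in rests:
        t = _tuple_to_tree(r, matrix.strains)
        t.score = cost if weights is not None else int(round(cost))
        trees.append(t)
    return trees


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapResult:
    """Majority-rule consensus with per-bipartition support.

    ``archive`` holds, per replicate, the split sets of every tied
    optimal tree.  Splits are frozensets of strain labels, normalized to
    the side excluding the lexicographically smallest strain, matching
    :meth:`cghindel.trees.Tree.bipartitions`.
    """

    consensus: Tree
    support: dict[frozenset, float]
    archive: list[list[set]]
    method: str
    n_replicates: int
    strains: list[str]

    def group_frequency(self, group) -> float:
        """Percentage of replicate trees containing the bipartition that
        separates ``group`` from the rest (ties count fractionally)."""
        group = _normalize_side(frozenset(group), self.strains)
        total = 0.0
        for rep in self.archive:
            total += sum(group in splits for splits in rep) / len(rep)
        return 100.0 * total / len(self.archive)


def _normalize_side(side: frozenset, labels) -> frozenset:
    if min(labels) in side:
        return frozenset(labels) - side
    return frozenset(side)


def _label_splits(rest, labels) -> set:
    n = len(labels)
    out = set()
    for mask in _splits_key(rest, n):
        side = frozenset(labels[i] for i in range(n) if mask >> i & 1)
        out.add(_normalize_side(side, labels))
    return out


def bootstrap_consensus(
    matrix: PresenceAbsenceMatrix,
    method: str = "wagner",
    n_replicates: int = 1000,
    seed: int = 0,
    strategy: str = "heuristic",
    n_jumbles: int = 10,
) -> BootstrapResult:
    """Bootstrap over loci and majority-rule (>50%) consensus.

    Each replicate resamples the locus columns with replacement, reruns
    the parsimony search, and contributes its optimal tree(s), tied trees
    fractionally.
    """
    if matrix.n_loci < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    n = matrix.n_strains
    labels = matrix.strains
    rng = np.random.default_rng(seed)
    cost_of = lambda w: _make_cost_fn(matrix, method, w)  # noqa: E731
    idx = list(range(n))
    counts: dict[frozenset, float] = {}
    archive: list[list[set]] = []
    l = matrix.n_loci
    for _ in range(n_replicates):
        w = rng.multinomial(l, np.full(l, 1.0 / l)).astype(float)
        cost_fn = cost_of(w)
        if strategy == "heuristic":
            _, rests = _heuristic(idx, cost_fn, n_jumbles, rng)
        elif strategy == "branch_and_bound":
            start, upper = _hill_climb(_stepwise_addition(idx, cost_fn), cost_fn)
            _, rests = _branch_and_bound(idx, cost_fn, upper)
            rests = _dedupe(rests, n)
        elif strategy == "exhaustive":
            _, rests = _exhaustive(idx, cost_fn, n)
            rests = _dedupe(rests, n)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        rep_splits = [_label_splits(r, labels) for r in rests]
        archive.append(rep_splits)
        frac = 1.0 / len(rep_splits)
        for splits in rep_splits:
            for s in splits:
                counts[s] = counts.get(s, 0.0) + frac
    support = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    majority = {s: p for s, p in support.items() if p > 50.0}
    consensus = tree_from_bipartitions(
        majority.keys(), sorted(labels), {s: f"{p:.0f}" for s, p in majority.items()}
    )
    return BootstrapResult(consensus, support, archive, method, n_replicates, list(labels))


def annotate_dual_support(tree: Tree, cs: BootstrapResult, w: BootstrapResult) -> Tree:
    """Relabel a consensus tree's internal nodes as 'CS/W' support pairs."""
    taxa = sorted(tree.leaf_labels())
    ref = taxa[0]
    full = set(taxa)
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        side = {leaf.label for leaf in Tree(node).leaves()}
        if ref in side:
            side = full - side
        key = frozenset(side)
        if 2 <= len(key) <= len(taxa) - 2:
            cs_p = cs.support.get(key, 0.0)
            w_p = w.support.get(key, 0.0)
            node.support = f"{cs_p:.0f}/{w_p:.0f}"
    return tree


# ---------------------------------------------------------------------------
# multilocus linkage disequilibrium

@dataclass
class LDResult:
    """Standardized index of association and its components."""

    ia_s: float
    v_d: float
    v_e: float
    n: int
    l: int
    p_value: float | None = None
    n_permutations: int | None = None
    null_values: np.ndarray | None = field(default=None, repr=False)


def _ias_value(values: np.ndarray) -> tuple[float, float, float]:
    n, l = values.shape
    d = pdist(values, metric="cityblock")
    v_d = float(np.var(d))
    p1 = values.mean(axis=0)
    h = (n / (n - 1)) * (1.0 - p1**2 - (1.0 - p1) ** 2)
    v_e = float(h.sum())
    return (v_d / v_e - 1.0) / (l - 1), v_d, v_e


def ia_s(matrix: PresenceAbsenceMatrix) -> LDResult:
    """Standardized index of association I_A^S; 0 at linkage equilibrium."""
    values = matrix.values.astype(float)
    n, l = values.shape
    if n < 3:
        raise ValueError("need at least 3 strains")
    if l < 2:
        raise ValueError("need at least 2 loci")
    colsums = values.sum(axis=0)
    if ((colsums == 0) | (colsums == n)).any():
        raise ValueError("constant locus columns carry no LD information; drop them first")
    value, v_d, v_e = _ias_value(values)
    return LDResult(ia_s=value, v_d=v_d, v_e=v_e, n=n, l=l)


def ia_s_permutation_test(
    matrix: PresenceAbsenceMatrix, n_permutations: int = 1000, seed: int = 0
) -> LDResult:
    """Monte Carlo test of I_A^S.

    The null permutes each locus column independently among strains,
    destroying inter-locus association while preserving allele
    frequencies.  P is the +1-corrected proportion of permuted values at
    least as large as the observed one.
    """
    result = ia_s(matrix)
    rng = np.random.default_rng(seed)
    values = matrix.values.astype(float)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permuted(values, axis=0)
        null[i], _, _ = _ias_value(perm)
    exceed = int((null >= result.ia_s - 1e-12).sum())
    result.p_value = (1 + exceed) / (n_permutations + 1)
    result.n_permutations = n_permutations
    result.null_values = null
    return result
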