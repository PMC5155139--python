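"""Heuristic and exhaustive search for most-parsimonious trees.

The heuristic follows the classic two-stage recipe: random-addition
Wagner starting trees, then steepest-descent branch swapping with
subtree pruning-regrafting (SPR) followed by tree bisection-reconnection
(TBR), per replicate.  All distinct trees at the best length found are
retained (with a cap), including equal-length trees reachable across
plateaus.  Everything is deterministic given the seed.

Unrooted trees are manipulated as adjacency maps (leaves 0..n-1 carry
taxon indices); conversion to :class:`~paleobite.parsimony.trees.Tree`
happens only at the API boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix
from .scoring import _child_contribution, _leaf_costs, tree_length
from .trees import Node, Tree, strict_consensus

__all__ = ["SearchResult", "heuristic_search", "exhaustive_search",
           "enumerate_topologies", "bremer_support"]

Adj = dict[int, list[int]]


# ---------------------------------------------------------------------------
# adjacency-level plumbing

def _adj_edges(adj: Adj) -> list[tuple[int, int]]:
    return [(u, v) for u in sorted(adj) for v in adj[u] if u < v]


def _copy(adj: Adj) -> Adj:
    return {u: list(vs) for u, vs in adj.items()}


def _adj_to_tree(adj: Adj, names: list[str]) -> Tree:
    n = len(names)
    root_id = next(u for u in sorted(adj) if u >= n) if len(adj) > 2 \
        else min(adj)
    nodes = {u: Node(names[u] if u < n else None) for u in adj}
    seen = {root_id}
    stack = [root_id]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                nodes[u].add(nodes[v])
                stack.append(v)
    return Tree(nodes[root_id], rooted=False)


def _tree_to_adj(tree: Tree, names: list[str]) -> Adj:
    index = {t: i for i, t in enumerate(names)}
    adj: Adj = {}
    counter = [len(names)]

    def build(node: Node) -> int:
        if node.is_leaf:
            nid = index[node.label]
        else:
            nid = counter[0]
            counter[0] += 1
        adj.setdefault(nid, [])
        for c in node.children:
            cid = build(c)
            adj[nid].append(cid)
            adj[cid].append(nid)
        return nid

    build(tree.root)
    # suppress a degree-2 storage root (rooted representation of an
    # unrooted tree)
    for u in list(adj):
        if len(adj[u]) == 2 and u >= len(names):
            a, b = adj.pop(u)
            adj[a].remove(u)
            adj[b].remove(u)
            adj[a].append(b)
            adj[b].append(a)
    return adj


def _adj_splits(adj: Adj, n_leaves: int) -> frozenset[frozenset[int]]:
    """Canonical non-trivial splits: the side not containing leaf 0."""
    splits = set()
    for u, v in _adj_edges(adj):
        # leaves on v's side away from u
        side, stack, seen = [], [v], {u, v}
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.append(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side_set = frozenset(side)
        if 0 in side_set:
            side_set = frozenset(range(n_leaves)) - side_set
        if 2 <= len(side_set) <= n_leaves - 2:
            splits.add(side_set)
    return frozenset(splits)


# ---------------------------------------------------------------------------
# scoring adjacency trees

class _Scorer:
    """Vectorized Sankoff scorer bound to one matrix."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.leaf_costs, self.S = _leaf_costs(matrix)
        self.ordered_mask = np.asarray(matrix.ordered_flags, dtype=bool)
        self.n_leaves = matrix.n_taxa

    def score(self, adj: Adj) -> int:
        root = next((u for u in adj if u >= self.n_leaves), None)
        if root is None:  # two-leaf tree
            a, b = sorted(adj)
            merged = self.leaf_costs[a] + _child_contribution(
                self.leaf_costs[b], self.ordered_mask)
            return int(round(merged.min(axis=1).sum()))
        # iterative postorder from root
        order: list[tuple[int, int | None]] = []
        stack = [(root, None)]
        while stack:
            u, parent = stack.pop()
            order.append((u, parent))
            for v in adj[u]:
                if v != parent:
                    stack.append((v, u))
        costs: dict[int, np.ndarray] = {}
        for u, parent in reversed(order):
            if u < self.n_leaves:
                costs[u] = self.leaf_costs[u]
            else:
                total = np.zeros((self.matrix.n_char, self.S))
                for v in adj[u]:
                    if v != parent:
                        total += _child_contribution(costs[v], self.ordered_mask)
                costs[u] = total
        return int(round(costs[root].min(axis=1).sum()))


# ---------------------------------------------------------------------------
# tree surgery

def _spr_neighbors(adj: Adj, n_leaves: int):
    """Yield every SPR rearrangement of an unrooted binary tree."""
    for u in sorted(adj):
        if len(adj[u]) != 3:
            continue
        for v in sorted(adj[u]):  # prune the subtree on v's side
            rest = [w for w in adj[u] if w != v]
            a, b = rest
            # remaining tree after deleting u: connect a-b
            pruned_side, stack, seen = {v}, [v], {u, v}
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        pruned_side.add(y)
                        stack.append(y)
            base = _copy(adj)
            for w in rest:
                base[w].remove(u)
            del base[u]
            base[a].append(b)
            base[b].append(a)
            remaining = [e for e in _adj_edges(base)
                         if e[0] not in pruned_side and e[1] not in pruned_side]
            for (x, y) in remaining:
                if {x, y} == {a, b}:
                    continue  # reinsertion at the original position
                cand = _copy(base)
                cand[x].remove(y)
                cand[y].remove(x)
                cand[u] = [x, y, v]
                cand[x].append(u)
                cand[y].append(u)
                cand[v] = [u] + [w for w in adj[v] if w != u]
                yield cand


def _tbr_neighbors(adj: Adj, n_leaves: int):
    """Yield TBR rearrangements across every internal edge."""
    for (u, v) in _adj_edges(adj):
        if u < n_leaves or v < n_leaves:
            continue  # leaf edges are covered by SPR
        halves = []
        for centre, other in ((u, v), (v, u)):
            part = _copy(adj)
            part[centre] = [w for w in part[centre] if w != other]
            comp, stack, seen = {centre}, [centre], {centre, other}
            while stack:
                x = stack.pop()
                for y in part[x]:
                    if y not in seen:
                        seen.add(y)
                        comp.add(y)
                        stack.append(y)
            sub = {x: [y for y in part[x] if y in comp] for x in comp}
            # suppress the degree-2 bisection point
            if len(sub[centre]) == 2:
                a, b = sub[centre]
                sub[a].remove(centre)
                sub[b].remove(centre)
                sub[a].append(b)
                sub[b].append(a)
                del sub[centre]
                attach_edges = _adj_edges(sub)
            else:  # centre is a leaf (component of one node)
                attach_edges = []
            halves.append((sub, attach_edges, centre))
        (s1, e1, c1), (s2, e2, c2) = halves
        sites1 = e1 if e1 else [None]
        sites2 = e2 if e2 else [None]
        for site1 in sites1:
            for site2 in sites2:
                cand = {x: list(ys) for part in (s1, s2)
                        for x, ys in part.items()}
                ends = []
                for site, sub, centre, mid in ((site1, s1, c1, u),
                                               (site2, s2, c2, v)):
                    if site is None:
                        ends.append(centre)
                    else:
                        x, y = site
                        cand[x].remove(y)
                        cand[y].remove(x)
                        cand[mid] = [x, y]
                        cand[x].append(mid)
                        cand[y].append(mid)
                        ends.append(mid)
                cand[ends[0]].append(ends[1])
                cand[ends[1]].append(ends[0])
                yield cand


def _random_addition_wagner(matrix: CharacterMatrix, scorer: _Scorer,
                            rng: np.random.Generator) -> Adj:
    n = matrix.n_taxa
    order = list(rng.permutation(n))
    a, b, c = order[:3]
    hub = n  # first internal node id
    adj: Adj = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    next_id = n + 1
    for leaf in order[3:]:
        best = None
        for (x, y) in _adj_edges(adj):
            cand = _copy(adj)
            cand[x].remove(y)
            cand[y].remove(x)
            cand[next_id] = [x, y, leaf]
            cand[x].append(next_id)
            cand[y].append(next_id)
            cand[leaf] = [next_id]
            score = scorer.score(cand)
            if best is None or score < best[0]:
                best = (score, cand)
        adj = best[1]
        next_id += 1
    return adj


# ---------------------------------------------------------------------------
# public API

@dataclass
class SearchResult:
    """Outcome of a parsimony search."""

    trees: list[Tree]
    best_length: int
    n_replicates: int = 0
    suboptimal: list[tuple[int, Tree]] = field(default_factory=list)

    def consensus(self) -> Tree:
        return strict_consensus(self.trees)


def _plateau_expand(pool: dict, best_len: int, scorer: _Scorer,
                    n_leaves: int, max_trees: int) -> None:
    """Breadth-first exploration of equal-length trees via SPR moves."""
    frontier = list(pool.values())
    while frontier and len(pool) < max_trees:
        adj = frontier.pop()
        for cand in _spr_neighbors(adj, n_leaves):
            if len(pool) >= max_trees:
                break
            if scorer.score(cand) == best_len:
                key = _adj_splits(cand, n_leaves)
                if key not in pool:
                    pool[key] = cand
                    frontier.append(cand)


def heuristic_search(matrix: CharacterMatrix, n_replicates: int = 10,
                     seed: int = 0, max_trees: int = 500,
                     keep_suboptimal_within: int = 0) -> SearchResult:
    """Random-addition Wagner trees + SPR then TBR steepest descent.

    Retains all distinct trees at the best length found (up to
    ``max_trees``), expanding plateaus of equal-length rearrangements.
    With ``keep_suboptimal_within > 0``, every distinct tree encountered
    within that many steps of the optimum is kept in ``suboptimal`` (the
    retention pool used for Bremer support).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    scorer = _Scorer(matrix)
    n = matrix.n_taxa
    best_len = math.inf
    pool: dict = {}
    sub_pool: dict = {}

    def consider_sub(adj: Adj, score: int):
        if not keep_suboptimal_within or score > best_len + keep_suboptimal_within:
            return
        key = _adj_splits(adj, n)
        old = sub_pool.get(key)
        if old is None or score < old[0]:
            if old is not None or len(sub_pool) < 5000:
                sub_pool[key] = (score, _copy(adj))

    for _ in range(n_replicates):
        adj = _random_addition_wagner(matrix, scorer, rng)
        score = scorer.score(adj)
        consider_sub(adj, score)
        improved = True
        while improved:
            improved = False
            for gen in (_spr_neighbors, _tbr_neighbors):
                best_move = None
                for cand in gen(adj, n):
                    s = scorer.score(cand)
                    consider_sub(cand, s)
                    if best_move is None or s < best_move[0]:
                        best_move = (s, cand)
                if best_move is not None and best_move[0] < score:
                    score, adj = best_move[0], best_move[1]
                    improved = True
                    break  # restart from SPR after any improvement
        if score < best_len:
            best_len = score
            pool = {}
        if score == best_len:
            key = _adj_splits(adj, n)
            if key not in pool:
                pool[key] = adj

    _plateau_expand(pool, best_len, scorer, n, max_trees)
    if keep_suboptimal_within:
        sub_pool = {k: v for k, v in sub_pool.items()
                    if v[0] <= best_len + keep_suboptimal_within}
    trees = [_adj_to_tree(a, matrix.taxa) for a in pool.values()]
    trees.sort(key=lambda t: t.to_newick())
    suboptimal = sorted(
        ((s, _adj_to_tree(a, matrix.taxa)) for s, a in sub_pool.values()),
        key=lambda p: (p[0], p[1].to_newick()),
    )
    return SearchResult(trees=trees, best_length=int(best_len),
                        n_replicates=n_replicates, suboptimal=suboptimal)


def enumerate_topologies(n_leaves: int):
    """Yield every unrooted binary topology on leaves 0..n-1 as an
    adjacency map ((2n-5)!! of them)."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    base: Adj = {0: [n_leaves], 1: [n_leaves], 2: [n_leaves],
                 n_leaves: [0, 1, 2]}

    def expand(adj: Adj, leaf: int, next_id: int):
        if leaf == n_leaves:
            yield adj
            return
        for (x, y) in _adj_edges(adj):
            cand = _copy(adj)
            cand[x].remove(y)
            cand[y].remove(x)
            cand[next_id] = [x, y, leaf]
            cand[x].append(next_id)
            cand[y].append(next_id)
            cand[leaf] = [next_id]
            yield from expand(cand, leaf + 1, next_id + 1)

    yield from expand(base, 3, n_leaves + 1)


def exhaustive_search(matrix: CharacterMatrix) -> SearchResult:
    """Score every topology; exact MPT set for small taxon counts."""
    scorer = _Scorer(matrix)
    best_len = math.inf
    best: list[Adj] = []
    for adj in enumerate_topologies(matrix.n_taxa):
        s = scorer.score(adj)
        if s < best_len:
            best_len, best = s, [adj]
        elif s == best_len:
            best.append(adj)
    trees = [_adj_to_tree(a, matrix.taxa) for a in best]
    trees.sort(key=lambda t: t.to_newick())
    return SearchResult(trees=trees, best_length=int(best_len))


def bremer_support(matrix: CharacterMatrix, mpts: list[Tree],
                   max_extra_steps: int = 5, seed: int = 0,
                   n_replicates: int = 10) -> dict:
    """Decay index per strict-consensus clade.

    For <= 9 taxa the search over trees lacking each clade is exhaustive
    (the decay is exact); otherwise suboptimal trees within
    ``max_extra_steps`` of the optimum are retained during a heuristic
    search and clades not broken inside the window report
    ``math.inf`` (printed as "> max_extra_steps").
    """
    if not mpts:
        raise ValueError("empty set of most-parsimonious trees")
    names = sorted(mpts[0].leaf_labels())
    consensus = strict_consensus(mpts)
    clades = sorted(consensus.bipartitions(), key=lambda s: (len(s), sorted(s)))
    best_len = tree_length(mpts[0], matrix)
    name_index = {t: i for i, t in enumerate(matrix.taxa)}
    n = matrix.n_taxa

    def to_index_split(split: frozenset[str]) -> frozenset[int]:
        side = frozenset(name_index[t] for t in split)
        if 0 in side:  # canonicalize like _adj_splits (exclude leaf id 0)
            side = frozenset(range(n)) - side
        return side

    results: dict[frozenset[str], float] = {}
    if matrix.n_taxa <= 9:
        scorer = _Scorer(matrix)
        best_without = {c: math.inf for c in clades}
        for adj in enumerate_topologies(n):
            splits = _adj_splits(adj, n)
            s = None
            for clade in clades:
                if to_index_split(clade) not in splits:
                    if s is None:
                        s = scorer.score(adj)
                    if s < best_without[clade]:
                        best_without[clade] = s
        for clade in clades:
            results[clade] = best_without[clade] - best_len
    else:
        res = heuristic_search(matrix, n_replicates=n_replicates, seed=seed,
                               keep_suboptimal_within=max_extra_steps)
        pool = [(res.best_length, t) for t in res.trees] + res.suboptimal
        for clade in clades:
            idx_split = to_index_split(clade)
            lengths = [
                s for s, t in pool
                if idx_split not in _adj_splits(_tree_to_adj(t, matrix.taxa), n)
            ]
            results[clade] = (min(lengths) - best_len) if lengths else math.inf
    return results
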