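"""Parsimony scoring of trees against morphological character matrices.

Lengths are computed by generalized (Sankoff) dynamic programming over
integer states, vectorized across characters: unordered characters use
the Fitch step cost (0 if states equal, else 1), ordered (additive)
characters the Farris interval cost |i - j|.  The recursion handles
polytomies directly (each child attaches to the polytomy node, adding no
resolution penalty beyond its own cheapest assignment), missing cells as
"any state at zero cost", and polymorphic cells as "cheapest member
state".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .matrix import CharacterMatrix
from .trees import Node, Tree

__all__ = [
    "tree_length",
    "step_bounds",
    "ensemble_ci_ri",
    "map_synapomorphies",
    "CharacterStepSummary",
]

_INF = 1.0e9


@dataclass
class CharacterStepSummary:
    """Per-character observed steps s, minimum m and maximum g steps."""

    s: np.ndarray | None
    m: np.ndarray
    g: np.ndarray


def _leaf_costs(matrix: CharacterMatrix) -> tuple[np.ndarray, int]:
    """(n_taxa, n_char, S) cost array: 0 for allowed states, inf else."""
    n_states = np.array(
        [max((max(c) for c in matrix.column(j) if c is not None), default=0) + 1
         for j in range(matrix.n_char)]
    )
    S = int(n_states.max())
    costs = np.full((matrix.n_taxa, matrix.n_char, S), _INF)
    for i, row in enumerate(matrix.cells):
        for j, cell in enumerate(row):
            if cell is None:
                costs[i, j, :] = 0.0
            else:
                for s in cell:
                    costs[i, j, s] = 0.0
    # padding states above a character's own range are inf at observed
    # leaves and 0 at missing leaves; either way they never lower the
    # minimum (both step costs are metrics), so no masking is needed
    return costs, S


def _child_contribution(cost: np.ndarray, ordered_mask: np.ndarray) -> np.ndarray:
    """min over child state t of cost[t] + w(s, t), per character.

    cost is (n_char, S).  Unordered: min(cost[s], min_t cost[t] + 1).
    Ordered: two-pass chamfer distance transform along the state axis.
    """
    S = cost.shape[1]
    unord = np.minimum(cost, cost.min(axis=1, keepdims=True) + 1.0)
    ordv = cost.copy()
    for s in range(1, S):
        np.minimum(ordv[:, s], ordv[:, s - 1] + 1.0, out=ordv[:, s])
    for s in range(S - 2, -1, -1):
        np.minimum(ordv[:, s], ordv[:, s + 1] + 1.0, out=ordv[:, s])
    return np.where(ordered_mask[:, None], ordv, unord)


def _node_costs(tree: Tree, matrix: CharacterMatrix) -> tuple[dict, np.ndarray, int]:
    """Bottom-up Sankoff pass; returns per-node cost arrays."""
    leaf_costs, S = _leaf_costs(matrix)
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    ordered_mask = np.asarray(matrix.ordered_flags, dtype=bool)
    costs: dict[int, np.ndarray] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            if node.label not in taxon_index:
                raise ValueError(f"leaf {node.label!r} absent from the matrix")
            costs[id(node)] = leaf_costs[taxon_index[node.label]]
        else:
            total = np.zeros((matrix.n_char, S))
            for child in node.children:
                total += _child_contribution(costs[id(child)], ordered_mask)
            costs[id(node)] = total
    return costs, ordered_mask, S


def tree_length(tree: Tree, matrix: CharacterMatrix,
                per_character: bool = False):
    """Parsimony length of a tree; optionally the per-character steps."""
    costs, _, _ = _node_costs(tree, matrix)
    per_char = costs[id(tree.root)].min(axis=1)
    total = int(round(per_char.sum()))
    if per_character:
        return total, per_char.astype(int)
    return total


def _min_steps_unordered(cells: list) -> int:
    """Smallest number of distinct states that can cover every observed
    cell (polymorphic cells pick their cheapest member), minus one."""
    sets = [c for c in cells if c is not None]
    if not sets:
        return 0
    states = sorted(frozenset().union(*sets))
    for k in range(1, len(states) + 1):
        for combo in combinations(states, k):
            chosen = set(combo)
            if all(chosen & c for c in sets):
                return k - 1
    return len(states) - 1  # pragma: no cover


def _min_steps_ordered(cells: list) -> int:
    """Width of the shortest integer interval meeting every cell."""
    sets = [c for c in cells if c is not None]
    if not sets:
        return 0
    states = sorted(frozenset().union(*sets))
    best = states[-1] - states[0]
    for a in states:
        for b in states:
            if b < a:
                continue
            if all(any(a <= s <= b for s in c) for c in sets):
                best = min(best, b - a)
    return best


def _max_steps(cells: list, ordered: bool) -> int:
    """Steps on the worst tree (the star/bush value g)."""
    sets = [c for c in cells if c is not None]
    if not sets:
        return 0
    states = sorted(frozenset().union(*sets))
    if not ordered:
        freq = {s: sum(1 for c in sets if s in c) for s in states}
        return len(sets) - max(freq.values())
    return min(
        sum(min(abs(s - med) for s in c) for c in sets)
        for med in range(states[0], states[-1] + 1)
    )


def step_bounds(matrix: CharacterMatrix) -> CharacterStepSummary:
    """Per-character minimum (m) and maximum (g) conceivable steps."""
    m = np.zeros(matrix.n_char, dtype=int)
    g = np.zeros(matrix.n_char, dtype=int)
    for j in range(matrix.n_char):
        col = matrix.column(j)
        if matrix.ordered_flags[j]:
            m[j] = _min_steps_ordered(col)
        else:
            m[j] = _min_steps_unordered(col)
        g[j] = _max_steps(col, matrix.ordered_flags[j])
    return CharacterStepSummary(s=None, m=m, g=g)


def ensemble_ci_ri(tree: Tree, matrix: CharacterMatrix) -> tuple[float, float]:
    """Ensemble consistency index CI = sum(m)/sum(s) and retention index
    RI = (sum(g) - sum(s)) / (sum(g) - sum(m)).

    Characters with g == m (parsimony-uninformative) are excluded from
    the RI sums; if the tree implies zero total steps, CI is 1 by
    convention.
    """
    _, s = tree_length(tree, matrix, per_character=True)
    bounds = step_bounds(matrix)
    m, g = bounds.m, bounds.g
    total_s = s.sum()
    ci = 1.0 if total_s == 0 else float(m.sum() / total_s)
    informative = g > m
    denom = (g[informative] - m[informative]).sum()
    ri = 1.0 if denom == 0 else float(
        (g[informative] - s[informative]).sum() / denom
    )
    return ci, ri


def map_synapomorphies(tree: Tree, matrix: CharacterMatrix,
                       optimization: str = "acctran") -> list[dict]:
    """One most-parsimonious ancestral reconstruction and its implied
    state changes per branch.

    Requires a rooted tree (polarity).  Ties between equally cheap child
    states are broken by the optimization rule: ``acctran`` prefers the
    state that differs from the parent (changes placed as early as
    possible), ``deltran`` the state equal to it (changes delayed);
    remaining ties go to the smallest state.  Branches where a tie
    existed are flagged ambiguous.
    """
    if not tree.rooted:
        raise ValueError("synapomorphy mapping requires a rooted tree")
    if optimization not in ("acctran", "deltran"):
        raise ValueError(f"unknown optimization {optimization!r}")
    costs, ordered_mask, S = _node_costs(tree, matrix)
    n_char = matrix.n_char

    labels = (matrix.character_labels
              or [f"char_{j}" for j in range(n_char)])
    root_cost = costs[id(tree.root)]
    states: dict[int, np.ndarray] = {
        id(tree.root): root_cost.argmin(axis=1)
    }
    changes: list[dict] = []
    # branch names: leaf label, or the sorted leaf set below the node
    def branch_name(n: Node) -> str:
        if n.is_leaf:
            return n.label
        return "{" + ",".join(sorted(l.label for l in n.leaves())) + "}"

    for node in tree.root.preorder():
        if node is tree.root:
            continue
        parent_state = states[id(node.parent)]
        c = costs[id(node)]
        idx = np.arange(S)
        w_ord = np.abs(idx[None, :] - parent_state[:, None]).astype(float)
        w_unord = (idx[None, :] != parent_state[:, None]).astype(float)
        w = np.where(ordered_mask[:, None], w_ord, w_unord)
        total = c + w
        best = total.min(axis=1)
        is_min = np.isclose(total, best[:, None])
        ambiguous = is_min.sum(axis=1) > 1
        if optimization == "acctran":
            pref = is_min & (idx[None, :] != parent_state[:, None])
        else:
            pref = is_min & (idx[None, :] == parent_state[:, None])
        has_pref = pref.any(axis=1)
        pick = np.where(has_pref, pref.argmax(axis=1), is_min.argmax(axis=1))
        states[id(node)] = pick
        for j in np.nonzero(pick != parent_state)[0]:
            changes.append({
                "branch": branch_name(node),
                "character": labels[j],
                "char_index": int(j),
                "from_state": int(parent_state[j]),
                "to_state": int(pick[j]),
                "steps": int(abs(int(pick[j]) - int(parent_state[j])))
                if matrix.ordered_flags[j] else 1,
                "ambiguous": bool(ambiguous[j]),
            })
    return changes
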