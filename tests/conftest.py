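"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's dynamic-programming scorer:
tree length is minimized by exhaustive enumeration over all internal
state assignments, and topology sets are enumerated by stepwise leaf
insertion implemented from scratch here.
"""

from itertools import product

import numpy as np
import pytest

from paleobite.parsimony import CharacterMatrix, Tree


def brute_force_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Minimum steps over every assignment of states to internal nodes.

    Missing leaves cost nothing; polymorphic leaves take their cheapest
    member state; unordered steps cost 1, ordered |i - j|.
    """
    internal = [n for n in tree.root.postorder() if not n.is_leaf]
    total = 0
    for j in range(matrix.n_char):
        ordered = matrix.ordered_flags[j]
        observed = [s for c in matrix.column(j) if c is not None for s in c]
        S = max(observed) + 1
        cells = {t: c for t, c in zip(matrix.taxa, (r[j] for r in matrix.cells))}

        def w(a, b):
            return abs(a - b) if ordered else int(a != b)

        best = None
        for assign in product(range(S), repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            cost = 0
            for node in tree.root.postorder():
                if node is tree.root:
                    continue
                ps = states[id(node.parent)]
                if node.is_leaf:
                    cell = cells[node.label]
                    if cell is not None:
                        cost += min(w(ps, s) for s in cell)
                else:
                    cost += w(ps, states[id(node)])
            best = cost if best is None else min(best, cost)
        total += best
    return total


def all_topologies(labels):
    """Every unrooted binary topology on the given labels, as Trees.

    Independent of the package's enumerator: trees are built as nested
    tuples by stepwise insertion, then converted through Newick.
    """
    def insertions(shape, leaf):
        # shape is a label or a tuple pair; yield all shapes with leaf
        # attached on each edge (including the edge above `shape`)
        yield (shape, leaf)
        if isinstance(shape, tuple):
            a, b = shape
            for sub in insertions(a, leaf):
                yield (sub, b)
            for sub in insertions(b, leaf):
                yield (a, sub)

    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    shapes = [((labels[0], labels[1]), labels[2])]
    for leaf in labels[3:]:
        shapes = [s for old in shapes for s in insertions(old, leaf)]
    # rooted-shape duplicates collapse once encoded as unrooted splits
    seen, out = set(), []
    for shape in shapes:
        def fmt(s):
            return f"({fmt(s[0])},{fmt(s[1])})" if isinstance(s, tuple) else s
        tree = Tree.from_newick(fmt(shape) + ";", rooted=False)
        key = tree.topology_key()
        if key not in seen:
            seen.add(key)
            out.append(tree)
    return out


def random_matrix(rng: np.random.Generator, n_taxa: int, n_char: int,
                  max_states: int = 3, missing_p: float = 0.15,
                  poly_p: float = 0.1, ordered_p: float = 0.4
                  ) -> CharacterMatrix:
    """A random small matrix with missing data, polymorphism, and a mix
    of ordered and unordered characters; every column is kept scoreable."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_char):
            u = rng.random()
            if u < missing_p:
                row.append(None)
            elif u < missing_p + poly_p:
                pair = rng.choice(max_states, size=2, replace=False)
                row.append(frozenset(int(s) for s in pair))
            else:
                row.append(frozenset({int(rng.integers(max_states))}))
        cells.append(row)
    for j in range(n_char):
        if all(r[j] is None for r in cells):
            cells[int(rng.integers(n_taxa))][j] = frozenset({0})
    ordered = [bool(rng.random() < ordered_p) for _ in range(n_char)]
    return CharacterMatrix(taxa, cells, ordered)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
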