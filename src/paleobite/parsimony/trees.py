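"""Phylogenetic tree container with Newick I/O and bipartition utilities.

Trees may be rooted or unrooted and may contain polytomies.  An unrooted
tree is stored rooted at an arbitrary internal node (degree >= 3) purely
for traversal; rooting state is an explicit flag, not an artefact of
storage.  Taxon labels containing spaces or apostrophes are preserved by
single-quoting on output.
"""

from __future__ import annotations

from typing import Iterable, Iterator

__all__ = ["Node", "Tree", "strict_consensus"]


class Node:
    __slots__ = ("children", "parent", "label", "length")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.label = label
        self.length = length

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.postorder() if n.is_leaf)


def _needs_quotes(label: str) -> bool:
    return any(ch in label for ch in " '():,;[]") or label == ""


def _format_label(label: str) -> str:
    if _needs_quotes(label):
        return "'" + label.replace("'", "''") + "'"
    return label


class Tree:
    """A leaf-labelled tree; polytomies allowed; rooted or unrooted."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        labels = [n.label for n in root.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, s: str, rooted: bool | None = None) -> "Tree":
        s = s.strip()
        if s.startswith("[&R]"):
            forced, s = True, s[4:].strip()
        elif s.startswith("[&U]"):
            forced, s = False, s[4:].strip()
        else:
            forced = None
        if not s.endswith(";"):
            raise ValueError("newick string must end with ';'")
        root, pos = cls._parse_clade(s, 0)
        if s[pos:].strip() != ";":
            raise ValueError(f"trailing characters after newick tree: {s[pos:]!r}")
        if rooted is None:
            rooted = forced if forced is not None else (len(root.children) == 2)
        return cls(root, rooted=rooted)

    @staticmethod
    def _parse_clade(s: str, i: int) -> tuple[Node, int]:
        node = Node()
        while i < len(s) and s[i].isspace():
            i += 1
        if i < len(s) and s[i] == "(":
            i += 1
            while True:
                child, i = Tree._parse_clade(s, i)
                node.add(child)
                while i < len(s) and s[i].isspace():
                    i += 1
                if i >= len(s):
                    raise ValueError("unterminated clade")
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                raise ValueError(f"unexpected character {s[i]!r} at {i}")
        # label (possibly quoted)
        while i < len(s) and s[i].isspace():
            i += 1
        if i < len(s) and s[i] == "'":
            j, chunks = i + 1, []
            while True:
                k = s.index("'", j)
                if k + 1 < len(s) and s[k + 1] == "'":
                    chunks.append(s[j:k + 1])
                    j = k + 2
                else:
                    chunks.append(s[j:k])
                    i = k + 1
                    break
            node.label = "".join(chunks)
        else:
            j = i
            while j < len(s) and s[j] not in ",():;[":
                j += 1
            lbl = s[i:j].strip()
            if lbl:
                node.label = lbl
            i = j
        while i < len(s) and s[i].isspace():
            i += 1
        if i < len(s) and s[i] == ":":
            j = i + 1
            while j < len(s) and (s[j].isdigit() or s[j] in ".-+eE"):
                j += 1
            node.length = float(s[i + 1:j])
            i = j
        return node, i

    # -- output -------------------------------------------------------
    def to_newick(self, lengths: bool = False, rooting_token: bool = False) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                out = _format_label(n.label or "")
            else:
                out = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.label:
                    out += _format_label(n.label)
            if lengths and n.length is not None:
                out += f":{n.length:g}"
            return out

        prefix = ("[&R]" if self.rooted else "[&U]") if rooting_token else ""
        return prefix + fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.to_newick()!r}, rooted={self.rooted})"

    # -- structure ----------------------------------------------------
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add(clone(c))
            return m

        return Tree(clone(self.root), rooted=self.rooted)

    def is_binary(self) -> bool:
        """Fully resolved: every internal node trifurcating in the
        unrooted sense (bifurcating below a rooted root)."""
        for n in self.root.postorder():
            if n.is_leaf:
                continue
            if n is self.root:
                want = 2 if self.rooted else 3
                if len(n.children) != want and len(self.leaf_labels()) > 2:
                    return False
            elif len(n.children) != 2:
                return False
        return True

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the side of the split
        that excludes the reference (lexicographically smallest) leaf —
        a rooting-invariant canonical form."""
        labels = set(self.leaf_labels())
        ref = min(labels)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.root.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            side = below[id(n)]
            if ref in side:
                side = frozenset(labels - side)
            if 2 <= len(side) <= len(labels) - 2:
                splits.add(side)
        return splits

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Hashable identity of the unrooted topology."""
        return frozenset(self.bipartitions())


def strict_consensus(trees: Iterable[Tree]) -> Tree:
    """Strict consensus: exactly the bipartitions present in every tree.

    All trees must share one leaf set; the result is unrooted with a
    polytomy wherever input trees disagree.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    labels = set(trees[0].leaf_labels())
    for t in trees[1:]:
        if set(t.leaf_labels()) != labels:
            raise ValueError("all trees must share the same leaf set")
    common = set.intersection(*(set(t.bipartitions()) for t in trees))
    return _tree_from_splits(sorted(labels), common)


def _tree_from_splits(labels: list[str], splits: set[frozenset[str]]) -> Tree:
    # splits are mutually compatible (they co-occur in at least one tree);
    # build top-down by nesting larger splits outside smaller ones
    root = Node()
    leaf_nodes = {lbl: root.add(Node(lbl)) for lbl in labels}
    for side in sorted(splits, key=len, reverse=True):
        members = [leaf_nodes[l] for l in side]
        parents = {m.parent for m in members}
        if len(parents) != 1:  # pragma: no cover - incompatible splits
            raise ValueError("incompatible splits in consensus construction")
        parent = parents.pop()
        group = Node()
        for m in members:
            parent.children.remove(m)
            group.add(m)
        parent.add(group)
    return Tree(root, rooted=False)
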