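"""Trees from dissimilarity matrices: UPGMA, neighbor joining,
Robinson–Foulds distance, Newick round-trip, and dendrogram analysis
(discriminating-node height, clustering accuracy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import KqdistError, NewickParseError

__all__ = [
    "TreeNode",
    "Tree",
    "upgma",
    "neighbor_joining",
    "robinson_foulds",
    "discriminating_node_height",
    "clustering_accuracy",
    "parse_newick",
    "write_newick",
]


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0          # branch length to parent
    children: list = field(default_factory=list)
    height: float = 0.0          # UPGMA: distance from node to its leaves
    merge_value: float | None = None  # UPGMA: linkage dissimilarity at merge

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> frozenset:
        return frozenset(l.label for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    root: TreeNode

    @property
    def leaves(self):
        return self.root.leaves()

    @property
    def leaf_labels(self) -> frozenset:
        labels = [l.label for l in self.root.leaves()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise KqdistError(f"duplicate leaf labels: {dupes}")
        return frozenset(labels)

    def newick(self) -> str:
        return write_newick(self)

    def bipartitions(self) -> set:
        """Non-trivial unrooted bipartitions, as frozensets of
        frozenset-pairs {side, complement}."""
        all_labels = self.leaf_labels
        n = len(all_labels)
        splits = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            side = node.leaf_labels()
            if 2 <= len(side) <= n - 2:
                splits.add(frozenset((side, all_labels - side)))
        return splits


def _as_matrix(matrix):
    """Accept a DissimilarityMatrix or (labels, ndarray)."""
    if hasattr(matrix, "labels") and hasattr(matrix, "values"):
        return list(matrix.labels), np.asarray(matrix.values, dtype=float)
    labels, values = matrix
    return list(labels), np.asarray(values, dtype=float)


def _validate_matrix(labels, d):
    if np.isnan(d).any():
        raise KqdistError("matrix contains NaN entries")
    if d.shape != (len(labels), len(labels)):
        raise KqdistError("matrix shape does not match labels")
    if np.max(np.abs(d - d.T)) > 1e-8:
        raise KqdistError("matrix is not symmetric")
    if (d < -1e-12).any():
        raise KqdistError("matrix has negative entries")


def upgma(matrix) -> Tree:
    """Arithmetic-mean agglomerative clustering; ultrametric rooted tree.

    Ties are broken by the lowest (row, column) index pair, so output is
    deterministic.
    """
    labels, d = _as_matrix(matrix)
    _validate_matrix(labels, d)
    n = len(labels)
    if n < 2:
        raise KqdistError("need at least 2 samples")
    d = d.copy()
    nodes = [TreeNode(label=lbl, height=0.0) for lbl in labels]
    sizes = [1] * n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if best is None or d[i, j] < best[0]:
                    best = (d[i, j], ai, aj)
        dij, ai, aj = best
        i, j = active[ai], active[aj]
        h = dij / 2.0
        left, right = nodes[i], nodes[j]
        left.length = max(h - left.height, 0.0)
        right.length = max(h - right.height, 0.0)
        parent = TreeNode(children=[left, right], height=h, merge_value=dij)
        # merged cluster reuses slot i; average distances weighted by size
        for m in active:
            if m in (i, j):
                continue
            dm = (sizes[i] * d[i, m] + sizes[j] * d[j, m]) / (
                sizes[i] + sizes[j])
            d[i, m] = d[m, i] = dm
        nodes[i] = parent
        sizes[i] += sizes[j]
        active.pop(aj)
    return Tree(root=nodes[active[0]])


def neighbor_joining(matrix) -> Tree:
    """Saitou–Nei NJ; negative branch lengths are clamped to 0 with the
    deficit transferred to the sibling edge. Rooted arbitrarily at the
    final (trifurcating) join.
    """
    labels, d = _as_matrix(matrix)
    _validate_matrix(labels, d)
    n = len(labels)
    if n < 2:
        raise KqdistError("need at least 2 samples")
    nodes = [TreeNode(label=lbl) for lbl in labels]
    if n == 2:
        for nd in nodes:
            nd.length = d[0, 1] / 2.0
        return Tree(root=TreeNode(children=nodes))
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0]:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        if vi < 0:
            vj += -vi
            vi = 0.0
        if vj < 0:
            vi += -vj
            vj = 0.0
        nodes[i].length = vi
        nodes[j].length = vj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        for mth in active:
            if mth in (i, j):
                continue
            dm = 0.5 * (d[i, mth] + d[j, mth] - d[i, j])
            d[i, mth] = d[mth, i] = max(dm, 0.0)
        nodes[i] = parent
        active.pop(aj)
    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, v in zip((a, b, c), (va, vb, vc)):
        nodes[idx].length = max(v, 0.0)
    return Tree(root=TreeNode(children=[nodes[a], nodes[b], nodes[c]]))


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference count of non-trivial unrooted bipartitions."""
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise KqdistError(
            f"leaf sets differ: only in first {only1}, only in second {only2}")
    return len(t1.bipartitions() ^ t2.bipartitions())


def _validate_partition(tree: Tree, partition: dict):
    leaves = tree.leaf_labels
    keys = set(partition)
    if keys != leaves:
        missing = sorted(leaves - keys)
        extra = sorted(keys - leaves)
        raise KqdistError(
            f"partition does not cover the tree leaves "
            f"(missing {missing}, extra {extra})")


def discriminating_node_height(tree: Tree, partition: dict):
    """Merge dissimilarity at which the two classes join, or None.

    ``partition`` maps leaf label -> class label (exactly 2 classes). If
    some node's subtree holds exactly one class, the classes join at its
    parent; the parent's linkage value is returned. Requires a tree with
    merge heights (UPGMA).
    """
    _validate_partition(tree, partition)
    classes = {}
    for leaf, cls in partition.items():
        classes.setdefault(cls, set()).add(leaf)
    if len(classes) != 2:
        raise KqdistError(
            f"discriminating-node height is a two-class statistic; "
            f"got {len(classes)} classes")
    class_sets = [frozenset(s) for s in classes.values()]
    parent_of = {}
    for node in tree.root.walk():
        for c in node.children:
            parent_of[id(c)] = node
    for node in tree.root.walk():
        if node is tree.root:
            continue
        if node.leaf_labels() in class_sets:
            parent = parent_of[id(node)]
            if parent.merge_value is None:
                raise KqdistError(
                    "tree has no merge heights (not built by UPGMA)")
            return float(parent.merge_value)
    return None


def clustering_accuracy(tree: Tree, partition: dict) -> float:
    """Cut the dendrogram into c clusters (c = number of classes) and
    return the fraction of leaves correctly assigned under the best
    cluster-to-class matching."""
    _validate_partition(tree, partition)
    class_labels = sorted(set(partition.values()))
    c = len(class_labels)
    clusters = [tree.root]
    while len(clusters) < c:
        best_i, best_v = None, -math.inf
        for i, node in enumerate(clusters):
            if node.is_leaf:
                continue
            v = node.merge_value if node.merge_value is not None else node.height
            if v > best_v:
                best_i, best_v = i, v
        if best_i is None:
            break  # fewer leaves than classes
        node = clusters.pop(best_i)
        clusters.extend(node.children)
    n_leaves = len(tree.leaves)
    cont = np.zeros((len(clusters), c), dtype=int)
    for ci, node in enumerate(clusters):
        for leaf in node.leaves():
            cont[ci, class_labels.index(partition[leaf.label])] += 1
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum()) / n_leaves


# ---------------------------------------------------------------------------
# Newick

def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_node(node: TreeNode, with_lengths: bool) -> str:
    if node.is_leaf:
        s = _quote_label(node.label or "")
    else:
        s = "(" + ",".join(_write_node(c, with_lengths)
                           for c in node.children) + ")"
        if node.label:
            s += _quote_label(node.label)
    if with_lengths:
        s += f":{node.length:.10g}"
    return s


def write_newick(tree: Tree, with_lengths: bool = True) -> str:
    inner = "(" + ",".join(_write_node(c, with_lengths)
                           for c in tree.root.children) + ")"
    if tree.root.label:
        inner += _quote_label(tree.root.label)
    return inner + ";"


class _NewickReader:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self):
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def error(self, msg):
        raise NewickParseError(msg, self.pos)

    def skip_ws(self):
        while self.peek() != "" and self.peek() in " \t\n\r":
            self.pos += 1

    def read_label(self):
        self.skip_ws()
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                ch = self.peek()
                if ch == "":
                    self.error("unterminated quoted label")
                if ch == "'":
                    if self.text[self.pos:self.pos + 2] == "''":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    break
                out.append(ch)
                self.pos += 1
            return "".join(out)
        out = []
        while self.peek() != "" and self.peek() not in "(),:;[] \t\n\r":
            out.append(self.peek())
            self.pos += 1
        return "".join(out)

    def read_length(self):
        self.skip_ws()
        if self.peek() != ":":
            return 0.0
        self.pos += 1
        start = self.pos
        while self.peek() != "" and self.peek() in "0123456789+-.eE":
            self.pos += 1
        try:
            return float(self.text[start:self.pos])
        except ValueError:
            self.pos = start
            self.error("malformed branch length")

    def read_node(self) -> TreeNode:
        self.skip_ws()
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.children.append(self.read_node())
                self.skip_ws()
                if self.peek() == ",":
                    self.pos += 1
                    continue
                if self.peek() == ")":
                    self.pos += 1
                    break
                self.error("expected ',' or ')'")
            label = self.read_label()
            if label:
                node.label = label
        else:
            label = self.read_label()
            if not label:
                self.error("expected a leaf label")
            node.label = label
        node.length = self.read_length()
        return node


def parse_newick(text: str) -> Tree:
    reader = _NewickReader(text.strip())
    root = reader.read_node()
    reader.skip_ws()
    if reader.peek() != ";":
        reader.error("expected ';' at end of tree")
    reader.pos += 1
    reader.skip_ws()
    if reader.pos != len(reader.text):
        reader.error("trailing characters after ';'")
    tree = Tree(root=root)
    _ = tree.leaf_labels  # raises on duplicates
    _set_heights(root)
    return tree


def _set_heights(node: TreeNode) -> float:
    """Recover UPGMA-style heights from branch lengths (max leaf depth)."""
    if node.is_leaf:
        node.height = 0.0
        return 0.0
    h = max(_set_heights(c) + c.length for c in node.children)
    node.height = h
    if node.merge_value is None:
        node.merge_value = 2.0 * h
    return h
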