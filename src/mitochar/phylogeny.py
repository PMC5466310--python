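"""Concatenated PCG supermatrix, p / K2P distances, canonical neighbor
joining with deterministic tie-breaking, column bootstrap, and Newick I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import genome_model as gm

DEFAULT_PCG_ORDER = [
    "nad2",
    "cox1",
    "cox2",
    "atp8",
    "atp6",
    "cox3",
    "nad3",
    "nad5",
    "nad4",
    "nad4L",
    "nad6",
    "cytb",
    "nad1",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class Node:
    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Rooted representation; an unrooted tree has a trifurcating root."""

    root: Node

    def leaves(self) -> list[Node]:
        out = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical frozensets of leaf names."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset] = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                parts.add(_canonical_split(below, all_leaves))
            return below

        walk(self.root)
        return parts

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            return Node(node.name, node.length, node.support, [dup(c) for c in node.children])

        return Tree(dup(self.root))


def _canonical_split(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Symmetric bipartition distance between two trees on the same taxa."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise ValueError("trees have different leaf sets")
    return len(a.bipartitions() ^ b.bipartitions())


# ---------------------------------------------------------------------------
# Newick


def _format_node(node: Node, with_support: bool) -> str:
    if node.is_leaf:
        label = node.name or ""
    else:
        inner = ",".join(_format_node(c, with_support) for c in node.children)
        label = f"({inner})"
        if with_support and node.support is not None:
            label += str(int(round(node.support)))
        elif node.name:
            label += node.name
    if node.length is not None:
        label += f":{node.length:.6g}"
    return label


def to_newick(tree: Tree, with_support: bool = True) -> str:
    return _format_node(tree.root, with_support) + ";"


def write_newick(tree: Tree, path, with_support: bool = True) -> None:
    with open(path, "w") as handle:
        handle.write(to_newick(tree, with_support) + "\n")


class NewickParseError(ValueError):
    pass


def parse_newick(text: str) -> Tree:
    """Minimal Newick parser; internal labels that parse as numbers are
    stored as supports, otherwise as names."""
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError(f"missing ';' at position {len(text)}")
    s = text[:-1]
    pos = 0

    def error(msg: str):
        raise NewickParseError(f"{msg} at position {pos}")

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    error("unexpected end of input inside group")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}")
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            label = parse_label()
            if not label:
                error("expected a taxon label")
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                error(f"malformed branch length {s[start:pos]!r}")
        return node

    root = parse_node()
    if pos != len(s):
        error(f"trailing characters {s[pos:]!r}")
    return Tree(root)


def read_newick(path) -> Tree:
    with open(path) as handle:
        return parse_newick(handle.read())


# ---------------------------------------------------------------------------
# supermatrix and distances


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]  # taxon -> concatenated aligned sequence
    partition: dict[str, tuple[int, int]]  # gene -> 0-based half-open range

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal is not zero")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


def build_supermatrix(
    genomes: Iterable[gm.AnnotatedGenome], gene_order: Optional[Sequence[str]] = None
) -> Supermatrix:
    """Concatenate pre-aligned PCG sequences in a fixed gene order.

    Per-gene sequences must already be equal length across taxa (alignment is
    out of scope); a length mismatch raises with instructions.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("no genomes supplied")
    genomes = sorted(genomes, key=lambda g: g.identifier)
    if gene_order is None:
        gene_order = [r.name for r in genomes[0].records_of_class("PCG")]
    per_gene: dict[str, dict[str, str]] = {g: {} for g in gene_order}
    for genome in genomes:
        by_name = {r.name: r for r in genome.records_of_class("PCG")}
        for gene in gene_order:
            if gene not in by_name:
                raise ValueError(f"taxon {genome.identifier} is missing gene {gene}")
            per_gene[gene][genome.identifier] = gm.extract_feature_sequence(
                genome, by_name[gene]
            )
    taxa = [g.identifier for g in genomes]
    partition: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene in gene_order:
        lengths = {len(seq) for seq in per_gene[gene].values()}
        if len(lengths) != 1:
            raise ValueError(
                f"gene {gene} has unequal lengths {sorted(lengths)} across taxa; "
                "align the sequences externally before building the supermatrix"
            )
        width = lengths.pop()
        partition[gene] = (offset, offset + width)
        offset += width
    rows = {
        taxon: "".join(per_gene[gene][taxon] for gene in gene_order) for taxon in taxa
    }
    return Supermatrix(taxa=taxa, rows=rows, partition=partition)


def _encode(matrix: Supermatrix) -> np.ndarray:
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    arr = np.full((len(matrix.taxa), matrix.n_columns), -1, dtype=np.int8)
    for i, taxon in enumerate(matrix.taxa):
        row = matrix.rows[taxon].upper()
        arr[i] = [code.get(ch, -1) for ch in row]
    return arr


def _k2p(p: float, q: float, pair: tuple[str, str]) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"K2P distance undefined for pair {pair} (P={p}, Q={q})")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def pairwise_distance(matrix: Supermatrix, model: str = "K2P") -> DistanceMatrix:
    """p or K2P distances with pairwise deletion of gap/ambiguous columns."""
    if model not in ("p", "K2P"):
        raise ValueError(f"unknown model {model!r}")
    if len(matrix.taxa) < 2:
        raise ValueError("need at least two taxa")
    arr = _encode(matrix)
    n = len(matrix.taxa)
    out = np.zeros((n, n))
    purine = np.isin(arr, (0, 2))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] >= 0) & (arr[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {matrix.taxa[i]} and {matrix.taxa[j]}"
                )
            diff = ok & (arr[i] != arr[j])
            if model == "p":
                d = diff.sum() / m
            else:
                transitions = diff & (purine[i] == purine[j])
                p = int(transitions.sum()) / m
                q = (int(diff.sum()) - int(transitions.sum())) / m
                d = _k2p(p, q, (matrix.taxa[i], matrix.taxa[j]))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(matrix.taxa, out)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Canonical Saitou-Nei NJ.

    Ties on the Q criterion are broken by the lexicographically least pair of
    cluster labels (sorted leaf-name tuples), so output is deterministic.
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister edge of the same join.
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        d = dm.matrix[0, 1]
        a, b = sorted(dm.taxa)
        return Tree(Node(children=[Node(a, d / 2), Node(b, d / 2)]))

    nodes: list[Node] = [Node(name=t) for t in dm.taxa]
    labels: list[tuple[str, ...]] = [(t,) for t in dm.taxa]
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        vj = d[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
            vi = max(vi, 0.0)
        new = Node(children=[nodes[i], nodes[j]])
        nodes[i].length = vi
        nodes[j].length = vj
        # distances from the new node
        new_index = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_index, k] = d[k, new_index] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        labels.append(tuple(sorted(labels[i] + labels[j])))
        active = [k for k in active if k not in (i, j)] + [new_index]

    if len(active) == 3:
        i, j, k = active
        vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, v in ((i, vi), (j, vj), (k, vk)):
            nodes[idx].length = max(v, 0.0)
        order = sorted(active, key=lambda x: labels[x])
        root = Node(children=[nodes[x] for x in order])
    else:  # two clusters remain
        i, j = active
        half = d[i, j] / 2
        nodes[i].length = max(half, 0.0)
        nodes[j].length = max(half, 0.0)
        order = sorted(active, key=lambda x: labels[x])
        root = Node(children=[nodes[x] for x in order])
    return Tree(root)


def root_with_outgroup(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Root on the edge separating the named outgroup clade from the rest."""
    outgroup = frozenset(outgroup)
    universe = frozenset(tree.leaf_names())
    missing = outgroup - universe
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    tree = tree.copy()

    if 1 < len(outgroup) < len(universe) - 1:
        if _canonical_split(outgroup, universe) not in tree.bipartitions():
            raise ValueError("outgroup is not a split in the tree")

    # find the edge (parent, child) whose child-side leaf set equals the
    # outgroup or its complement
    result: list[tuple[Node, Node]] = []

    def find(parent: Node) -> None:
        for child in parent.children:
            below = frozenset(_leafset(child))
            if below == outgroup or universe - below == outgroup:
                result.append((parent, child))
            find(child)

    find(tree.root)
    if not result:
        raise ValueError("outgroup is not a split in the tree")
    parent, child = result[0]
    parent.children.remove(child)
    # re-hang the rest of the tree below a new root
    rest = _reroot_at(tree.root, parent)
    half = (child.length or 0.0) / 2
    child.length = half
    rest.length = half
    return Tree(Node(children=[child, rest]))


def _leafset(node: Node) -> list[str]:
    if node.is_leaf:
        return [node.name]
    out: list[str] = []
    for child in node.children:
        out.extend(_leafset(child))
    return out


def _reroot_at(root: Node, target: Node) -> Node:
    """Reorient the tree so ``target`` becomes the apex of the remaining part."""
    path: list[Node] = []

    def find_path(node: Node) -> bool:
        path.append(node)
        if node is target:
            return True
        for child in node.children:
            if find_path(child):
                return True
        path.pop()
        return False

    if not find_path(root):
        raise RuntimeError("target not in tree")
    # walk the path from target back to root, flipping parent links
    for upper, lower in zip(path[:-1], path[1:]):
        upper.children.remove(lower)
        lower.children.append(upper)
        upper.length, lower.length = lower.length, upper.length
        upper.support, lower.support = lower.support, upper.support
    target.length = None
    return target


def bootstrap_support(
    matrix: Supermatrix, model: str = "K2P", reps: int = 100, seed: int = 0
) -> Tree:
    """NJ tree with bootstrap supports from column resampling.

    Support = percentage of replicates whose NJ tree contains the internal
    bipartition; reproducible for a given seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = neighbor_joining(pairwise_distance(matrix, model))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {split: 0 for split in base.bipartitions()}
    n_cols = matrix.n_columns
    for _ in range(reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        resampled = Supermatrix(
            taxa=matrix.taxa,
            rows={
                t: "".join(matrix.rows[t][i] for i in idx) for t in matrix.taxa
            },
            partition={"resampled": (0, n_cols)},
        )
        rep_tree = neighbor_joining(pairwise_distance(resampled, model))
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1
    out = base.copy()
    universe = frozenset(out.leaf_names())

    def annotate(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if node is not out.root and 1 < len(below) < len(universe) - 1:
            split = _canonical_split(below, universe)
            node.support = 100.0 * counts.get(split, 0) / reps
        return below

    annotate(out.root)
    return out
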