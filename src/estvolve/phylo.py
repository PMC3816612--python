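"""Neighbor-joining phylogenetics on SNP genotype matrices.

Pairwise p-distances over SNP alleles (indel alleles are a fifth state;
triangle inequality is not guaranteed and not asserted), Saitou-Nei
neighbor joining with deterministic tie-breaking and zero-clamped branch
lengths, bipartition bootstrap over SNP columns, and a self-round-tripping
Newick writer/reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .snp import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


def p_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Proportion of SNP sites with differing alleles, per accession pair.

    Requires a complete matrix (no missing entries); a mismatch involving a
    gap allele counts as a difference like any other.
    """
    if matrix.n_sites == 0:
        raise ValueError("genotype matrix has no sites")
    if not matrix.is_complete:
        raise ValueError("genotype matrix has missing entries")
    rows = np.array(
        [[ord(c) for c in matrix.row(a)] for a in matrix.accessions]
    )
    n = len(matrix.accessions)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(rows[i] != rows[j])
    return DistanceMatrix(list(matrix.accessions), d)


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating (or leaf-paired) root."""

    root: Node

    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each identified by the side not containing
        the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def visit(node: Node):
            below = frozenset(l.name for l in node.leaves())
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                out.add(side)
            for c in node.children:
                visit(c)

        for c in self.root.children:
            visit(c)
        return out

    def internal_nodes(self) -> list[Node]:
        out = []

        def visit(node: Node):
            if not node.is_leaf:
                out.append(node)
            for c in node.children:
                visit(c)

        for c in self.root.children:
            visit(c)
        return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j, with ties
    broken toward the lexicographically smallest pair of cluster labels
    (a cluster is labelled by its smallest leaf).  Negative branch lengths
    are clamped to zero with the remainder transferred to the sister
    branch.  The final three clusters join at a trifurcating root via the
    three-point formulas.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(name=l) for l in dm.labels]
    tags: list[str] = list(dm.labels)  # smallest leaf label per cluster
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((tags[i], tags[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj, d[i, j])
        parent = Node(children=[_with_length(nodes[i], li), _with_length(nodes[j], lj)])
        # grow the matrix by one row/col for the new cluster
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = sorted(active, key=lambda x: tags[x])
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = Node(
        children=[
            _with_length(nodes[i], max(li, 0.0)),
            _with_length(nodes[j], max(lj, 0.0)),
            _with_length(nodes[k], max(lk, 0.0)),
        ]
    )
    return PhyloTree(root)


def _with_length(node: Node, length: float) -> Node:
    node.length = length
    return node


def _clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
    if li < 0:
        return 0.0, total
    if lj < 0:
        return total, 0.0
    return li, lj


def bootstrap_support(
    matrix: GenotypeMatrix, replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """Point-estimate NJ tree with column-bootstrap supports.

    SNP columns are resampled with replacement ``replicates`` times; the
    support of an internal edge is the integer percentage of replicate
    trees containing its bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(p_distance(matrix))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    n_sites = matrix.n_sites
    for _ in range(replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        sub = GenotypeMatrix(
            accessions=list(matrix.accessions),
            sites=[matrix.sites[i] for i in idx],
            alleles=[matrix.alleles[i] for i in idx],
        )
        rep = neighbor_joining(p_distance(sub))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: Node):
        below = frozenset(l.name for l in node.leaves())
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            node.support = round(100 * counts[side] / replicates)
        for c in node.children:
            annotate(c)

    for c in tree.root.children:
        annotate(c)
    return tree


# ----------------------------------------------------------------- Newick I/O

def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: PhyloTree) -> str:
    """Newick with branch lengths and supports as internal-node labels."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return f"{node.name}:{_fmt_len(node.length)}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else str(node.support)
        return f"({inner}){label}:{_fmt_len(node.length)}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    label = "" if tree.root.support is None else str(tree.root.support)
    return f"({inner}){label};"


def read_newick(text: str) -> PhyloTree:
    """Parse the subset of Newick produced by :func:`write_newick`."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if s[pos] != ")":
                raise ValueError(f"expected ')' at {pos}")
            pos += 1
            label = _take(lambda c: c not in ":,();")
            if label:
                node.support = int(label)
        else:
            node.name = _take(lambda c: c not in ":,();")
        if pos < len(s) and s[pos] == ":":
            pos += 1
            node.length = float(_take(lambda c: c not in ",();"))
        return node

    def _take(pred) -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and pred(s[pos]):
            pos += 1
        return s[start:pos]

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters at {pos}")
    return PhyloTree(root)
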