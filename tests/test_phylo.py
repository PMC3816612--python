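"""Distance matrices, neighbor joining, bootstrap and Newick round-trips."""

import dendropy
import numpy as np
import pytest

from estvolve.phylo import (
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    p_distance,
    read_newick,
    write_newick,
)
from estvolve.snp import GenotypeMatrix, SNPSite
from oracles import random_additive_tree


def matrix_from_rows(rows: dict[str, str]) -> GenotypeMatrix:
    accs = list(rows)
    n = len(next(iter(rows.values())))
    sites = [
        SNPSite("u", i + 1, {a: rows[a][i] for a in accs},
                frozenset(), "unknown")
        for i in range(n)
    ]
    alleles = [[rows[a][i] for a in accs] for i in range(n)]
    return GenotypeMatrix(accs, sites, alleles)


class TestPDistance:
    def test_identical_rows_zero(self):
        gm = matrix_from_rows({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        dm = p_distance(gm)
        assert np.all(dm.d == 0)

    def test_direct_count(self):
        gm = matrix_from_rows({"a": "AAAAAAAAAA", "b": "CCCAAAAAAA"})
        dm = p_distance(gm)
        assert dm.d[0, 1] == pytest.approx(0.3)

    def test_indel_allele_counts_as_difference(self):
        gm = matrix_from_rows({"a": "A-", "b": "AT"})
        assert p_distance(gm).d[0, 1] == pytest.approx(0.5)

    def test_matches_recount_oracle(self, rng):
        accs = [f"a{i}" for i in range(6)]
        rows = {
            a: "".join("ACGT-"[i] for i in rng.integers(0, 5, size=80))
            for a in accs
        }
        dm = p_distance(matrix_from_rows(rows))
        for i, x in enumerate(accs):
            for j, y in enumerate(accs):
                want = sum(c1 != c2 for c1, c2 in zip(rows[x], rows[y])) / 80
                assert dm.d[i, j] == pytest.approx(want)

    def test_bounds(self, rng):
        rows = {
            f"a{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, size=40))
            for i in range(5)
        }
        dm = p_distance(matrix_from_rows(rows))
        assert np.all(dm.d >= 0) and np.all(dm.d <= 1)

    def test_incomplete_matrix_rejected(self):
        gm = matrix_from_rows({"a": "A?", "b": "AT"})
        with pytest.raises(ValueError, match="missing"):
            p_distance(gm)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError, match="no sites"):
            p_distance(GenotypeMatrix(["a", "b"], [], []))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths["a"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["c"] == pytest.approx((0.4 + 0.5 - 0.3) / 2)

    def test_four_taxon_additive_roundtrip(self, rng):
        labels, d, splits = random_additive_tree(rng, 4)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree.bipartitions() == splits
        assert _tree_distances(tree) == pytest.approx(d, abs=1e-9)

    def test_additive_recovery_up_to_twelve_taxa(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 13))
            labels, d, splits = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            assert tree.bipartitions() == splits
            assert _tree_distances(tree) == pytest.approx(d, abs=1e-8)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], d)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_branch_lengths_never_negative(self, rng):
        # noisy (non-additive) matrices can drive NJ estimates negative;
        # clamping must keep every emitted length at zero or above
        for _ in range(20):
            n = 6
            base = random_additive_tree(rng, n)[1]
            noise = rng.uniform(0, 0.2, size=(n, n))
            noisy = base + (noise + noise.T) / 2
            np.fill_diagonal(noisy, 0)
            tree = neighbor_joining(
                DistanceMatrix([f"t{i:02d}" for i in range(n)], noisy)
            )

            def lengths(node):
                yield node.length
                for c in node.children:
                    yield from lengths(c)

            assert all(
                l >= 0 for c in tree.root.children for l in lengths(c)
            )


def _tree_distances(tree) -> np.ndarray:
    """Leaf-leaf path lengths via adjacency walk (independent recount)."""
    adj = {}

    def build(node, parent):
        if parent is not None:
            adj.setdefault(id(node), []).append((id(parent), node.length))
            adj.setdefault(id(parent), []).append((id(node), node.length))
        for c in node.children:
            build(c, node)

    build(tree.root, None)
    leaves = sorted(tree.root.leaves(), key=lambda l: l.name)
    out = np.zeros((len(leaves), len(leaves)))
    for i, src in enumerate(leaves):
        dist = {id(src): 0.0}
        stack = [id(src)]
        while stack:
            x = stack.pop()
            for y, L in adj.get(x, []):
                if y not in dist:
                    dist[y] = dist[x] + L
                    stack.append(y)
        for j, dst in enumerate(leaves):
            out[i, j] = dist[id(dst)]
    return out


class TestBootstrap:
    def _unanimous_matrix(self):
        # every column supports the same 4|4 split
        rows = {}
        for a in ["a1", "a2", "a3", "a4"]:
            rows[a] = "A" * 30
        for b in ["b1", "b2", "b3", "b4"]:
            rows[b] = "C" * 30
        # add distinguishing columns so leaves are not identical
        for i, k in enumerate(rows):
            rows[k] = rows[k][:20] + "ACGTACGT"[i] + rows[k][21:]
        return matrix_from_rows(rows)

    def test_unanimous_split_gets_full_support(self):
        tree = bootstrap_support(self._unanimous_matrix(), replicates=50, seed=3)
        split = frozenset(["b1", "b2", "b3", "b4"])
        supports = {
            frozenset(l.name for l in n.leaves()): n.support
            for n in tree.internal_nodes()
            if n.support is not None
        }
        assert supports.get(split, supports.get(frozenset(["a1", "a2", "a3", "a4"]))) == 100

    def test_single_replicate_supports_are_binary(self):
        tree = bootstrap_support(self._unanimous_matrix(), replicates=1, seed=9)
        sup = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert set(sup) <= {0, 100}

    def test_fixed_seed_reproducible(self):
        gm = self._unanimous_matrix()
        t1 = bootstrap_support(gm, replicates=25, seed=7)
        t2 = bootstrap_support(gm, replicates=25, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._unanimous_matrix(), replicates=0)


class TestNewick:
    def test_three_taxon_output_parses(self):
        d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        text = write_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert len(parsed.leaf_nodes()) == 3

    def test_write_read_write_byte_identical(self, rng):
        labels, d, _ = random_additive_tree(rng, 9)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        text = write_newick(tree)
        assert write_newick(read_newick(text)) == text

    def test_supports_survive_roundtrip(self):
        gm = TestBootstrap()._unanimous_matrix()
        tree = bootstrap_support(gm, replicates=20, seed=5)
        back = read_newick(write_newick(tree))
        orig = sorted(
            n.support for n in tree.internal_nodes() if n.support is not None
        )
        rt = sorted(
            n.support for n in back.internal_nodes() if n.support is not None
        )
        assert orig == rt
        assert back.bipartitions() == tree.bipartitions()

    def test_dendropy_agrees_on_bipartitions(self, rng):
        labels, d, splits = random_additive_tree(rng, 8)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        dt = dendropy.Tree.get(
            data=write_newick(tree), schema="newick", preserve_underscores=True
        )
        dt.encode_bipartitions()
        taxa = frozenset(labels)
        anchor = min(labels)
        dsplits = set()
        for edge in dt.preorder_edge_iter():
            if edge.head_node.parent_node is None:
                continue
            side = frozenset(
                l.taxon.label for l in edge.head_node.leaf_iter()
            )
            if 1 < len(side) < len(labels) - 1:
                dsplits.add(side if anchor not in side else taxa - side)
        assert dsplits == tree.bipartitions() == splits
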