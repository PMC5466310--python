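import math

import numpy as np
import pytest

from mitochar import phylogeny as ph
from mitochar import synthetic_data as sd


def star_matrix():
    taxa = ["a", "b", "c", "d"]
    m = np.full((4, 4), 2.0)
    np.fill_diagonal(m, 0.0)
    return ph.DistanceMatrix(taxa, m)


class TestSupermatrix:
    def test_width_is_sum_of_gene_lengths(self):
        genomes, _ = sd.generate_clade(sd.CladeSpec(tree="((A:0.1,B:0.1):0.1,C:0.1,D:0.1);", seed=1))
        matrix = ph.build_supermatrix(genomes)
        assert matrix.n_columns == sum(sd.DEFAULT_CLADE_GENES.values())
        assert len(matrix.taxa) == 4

    def test_partition_tiles_columns(self):
        genomes, _ = sd.generate_clade(sd.CladeSpec(tree="((A:0.1,B:0.1):0.1,C:0.1,D:0.1);", seed=1))
        matrix = ph.build_supermatrix(genomes)
        spans = sorted(matrix.partition.values())
        assert spans[0][0] == 0 and spans[-1][1] == matrix.n_columns
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c

    def test_single_taxon(self):
        genomes, _ = sd.generate_clade(sd.CladeSpec(tree="((A:0.1,B:0.1):0.1,C:0.1,D:0.1);", seed=1))
        matrix = ph.build_supermatrix(genomes[:1])
        assert matrix.taxa == [genomes[0].identifier]

    def test_taxon_order_invariance(self):
        genomes, _ = sd.generate_clade(sd.CladeSpec(tree="((A:0.1,B:0.1):0.1,C:0.1,D:0.1);", seed=1))
        a = ph.build_supermatrix(genomes)
        b = ph.build_supermatrix(list(reversed(genomes)))
        assert a.rows == b.rows and a.partition == b.partition

    def test_missing_gene_names_taxon(self):
        genomes, _ = sd.generate_clade(sd.CladeSpec(tree="((A:0.1,B:0.1):0.1,C:0.1,D:0.1);", seed=1))
        # drop a gene from a non-reference taxon so the gene order still lists it
        genomes[1].records = genomes[1].records[1:]
        with pytest.raises(ValueError, match="pcg01"):
            ph.build_supermatrix(genomes)


class TestPairwiseDistance:
    def test_identical_rows(self):
        m = ph.Supermatrix(["a", "b"], {"a": "ACGT", "b": "ACGT"}, {"g": (0, 4)})
        assert ph.pairwise_distance(m, "p").get("a", "b") == 0.0
        assert ph.pairwise_distance(m, "K2P").get("a", "b") == 0.0

    def test_closed_form_quarter_transition(self):
        m = ph.Supermatrix(["a", "b"], {"a": "AAAA", "b": "AAAG"}, {"g": (0, 4)})
        assert ph.pairwise_distance(m, "p").get("a", "b") == 0.25
        expected = -0.5 * math.log(1 - 2 * 0.25)  # P=0.25, Q=0
        assert math.isclose(ph.pairwise_distance(m, "K2P").get("a", "b"), expected)

    def test_gap_columns_deleted_pairwise(self):
        m = ph.Supermatrix(["a", "b"], {"a": "A-GT", "b": "ACGA"}, {"g": (0, 4)})
        assert ph.pairwise_distance(m, "p").get("a", "b") == pytest.approx(1 / 3)

    def test_saturated_pair_raises(self):
        m = ph.Supermatrix(["a", "b"], {"a": "AAAA", "b": "GGGG"}, {"g": (0, 4)})
        with pytest.raises(ValueError, match="K2P"):
            ph.pairwise_distance(m, "K2P")

    def test_no_comparable_columns(self):
        m = ph.Supermatrix(["a", "b"], {"a": "--AA", "b": "CC--"}, {"g": (0, 4)})
        with pytest.raises(ValueError, match="comparable"):
            ph.pairwise_distance(m, "p")

    def test_monotone_in_divergence(self):
        means = []
        for scale in (0.02, 0.1, 0.4):
            tree = f"((A:{scale},B:{scale}):{scale},C:{scale},D:{scale});"
            genomes, _ = sd.generate_clade(sd.CladeSpec(tree=tree, seed=9))
            dm = ph.pairwise_distance(ph.build_supermatrix(genomes), "p")
            means.append(dm.matrix.sum() / 12)
        assert means[0] < means[1] < means[2]


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        truth = ph.parse_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.4);")
        dm = sd.tree_distance_matrix(truth)
        nj = ph.neighbor_joining(dm)
        assert ph.robinson_foulds(truth, nj) == 0
        recovered = sd.tree_distance_matrix(nj)
        assert np.allclose(dm.matrix, recovered.matrix)

    def test_twenty_random_additive_matrices(self):
        rng = np.random.default_rng(20)
        for trial in range(20):
            n = int(rng.integers(4, 11))
            tree = sd.random_tree([f"t{i}" for i in range(n)], rng)
            nj = ph.neighbor_joining(sd.tree_distance_matrix(tree))
            assert ph.robinson_foulds(tree, nj) == 0, trial

    def test_three_taxa_closed_form(self):
        dm = ph.DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        )
        tree = ph.neighbor_joining(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_star_matrix_deterministic_tie_break(self):
        t1 = ph.to_newick(ph.neighbor_joining(star_matrix()))
        t2 = ph.to_newick(ph.neighbor_joining(star_matrix()))
        assert t1 == t2

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            n = 6
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = ph.neighbor_joining(ph.DistanceMatrix([f"t{i}" for i in range(n)], m))

            def check(node):
                if node.length is not None:
                    assert node.length >= 0
                for c in node.children:
                    check(c)

            check(tree.root)


class TestRooting:
    def test_outgroup_rooting(self):
        tree = ph.parse_newick("((a:1,b:1):1,(o1:1,o2:1):1,c:2);")
        rooted = ph.root_with_outgroup(tree, ["o1", "o2"])
        sides = [sorted(ph._leafset(c)) for c in rooted.root.children]
        assert sorted(sides) == [["a", "b", "c"], ["o1", "o2"]]

    def test_non_split_outgroup_rejected(self):
        tree = ph.parse_newick("((a:1,b:1):1,(c:1,d:1):1,e:2);")
        with pytest.raises(ValueError, match="split"):
            ph.root_with_outgroup(tree, ["a", "c"])

    def test_missing_taxon_rejected(self):
        tree = ph.parse_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="zz"):
            ph.root_with_outgroup(tree, ["zz"])


@pytest.fixture(scope="module")
def clade_matrix():
    tree = "(((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1):0.1,O1:0.2,O2:0.2);"
    genomes, _ = sd.generate_clade(sd.CladeSpec(tree=tree, seed=4))
    return ph.build_supermatrix(genomes)


class TestBootstrap:
    def test_reps_one_supports_binary(self, clade_matrix):
        tree = ph.bootstrap_support(clade_matrix, reps=1, seed=1)
        supports = [
            n.support
            for n in _internal_nodes(tree)
            if n.support is not None
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_separated_clades_high_support(self, clade_matrix):
        tree = ph.bootstrap_support(clade_matrix, reps=100, seed=2)
        splits = {}

        def walk(node, universe):
            for c in node.children:
                walk(c, universe)
            if node.children and node.support is not None:
                splits[frozenset(ph._leafset(node))] = node.support

        walk(tree.root, set(tree.leaf_names()))
        ab = next(s for k, s in splits.items() if k in ({"A", "B"}, {"C", "D", "O1", "O2"}))
        cd = next(s for k, s in splits.items() if k in ({"C", "D"}, {"A", "B", "O1", "O2"}))
        assert ab >= 95 and cd >= 95

    def test_same_seed_identical(self, clade_matrix):
        a = ph.to_newick(ph.bootstrap_support(clade_matrix, reps=30, seed=7))
        b = ph.to_newick(ph.bootstrap_support(clade_matrix, reps=30, seed=7))
        assert a == b

    def test_taxon_permutation_invariant_supports(self, clade_matrix):
        shuffled = ph.Supermatrix(
            taxa=list(reversed(clade_matrix.taxa)),
            rows=dict(clade_matrix.rows),
            partition=dict(clade_matrix.partition),
        )
        a = ph.bootstrap_support(clade_matrix, reps=30, seed=5)
        b = ph.bootstrap_support(shuffled, reps=30, seed=5)

        def support_map(tree):
            out = {}

            def walk(node):
                for c in node.children:
                    walk(c)
                if node.children and node.support is not None:
                    out[frozenset(ph._leafset(node))] = node.support

            walk(tree.root)
            return out

        am, bm = support_map(a), support_map(b)
        universe = frozenset(a.leaf_names())
        canon = lambda m: {ph._canonical_split(k, universe): v for k, v in m.items()}
        assert canon(am) == canon(bm)


def _internal_nodes(tree):
    out = []

    def walk(node):
        if node.children:
            out.append(node)
        for c in node.children:
            walk(c)

    walk(tree.root)
    return out


class TestNewick:
    def test_three_taxon_roundtrip(self):
        s = "(a:1,b:2,c:3);"
        tree = ph.parse_newick(s)
        assert ph.to_newick(tree) == "(a:1,b:2,c:3);"

    def test_support_labels_roundtrip(self):
        s = "((a:1,b:1)95:0.5,c:1,d:1);"
        tree = ph.parse_newick(s)
        inner = tree.root.children[0]
        assert inner.support == 95.0
        assert ph.parse_newick(ph.to_newick(tree)).root.children[0].support == 95.0

    def test_unrooted_five_taxa_trifurcating_root(self):
        rng = np.random.default_rng(8)
        tree = ph.neighbor_joining(
            sd.tree_distance_matrix(sd.random_tree(list("abcde"), rng))
        )
        assert len(tree.root.children) == 3
        again = ph.parse_newick(ph.to_newick(tree))
        assert len(again.root.children) == 3
        assert ph.robinson_foulds(tree, again) == 0

    def test_file_roundtrip(self, tmp_path):
        tree = ph.parse_newick("((a:1,b:1)80:1,c:1,d:1);")
        path = tmp_path / "t.nwk"
        ph.write_newick(tree, path)
        again = ph.read_newick(path)
        assert ph.to_newick(again) == ph.to_newick(tree)

    def test_parse_error_reports_position(self):
        with pytest.raises(ph.NewickParseError, match="position"):
            ph.parse_newick("((a,b);")

    def test_missing_semicolon(self):
        with pytest.raises(ph.NewickParseError):
            ph.parse_newick("(a,b)")
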