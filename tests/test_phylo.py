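import itertools

import dendropy
import numpy as np
import pytest

from coibarcode import Alignment, SequenceRecord, distance_matrix
from coibarcode.dist import DistanceMatrix
from coibarcode.phylo import (
    BootstrapConfig,
    attach_support,
    bipartitions,
    bootstrap_bipartition_counts,
    bootstrap_support,
    is_monophyletic,
    leaf_labels,
    nj_tree,
    read_newick,
    root_with_outgroup,
    tree_length,
    write_newick,
)


def dm_from(labels, square):
    return DistanceMatrix(labels=list(labels), values=np.array(square, float))


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for a, b in itertools.combinations(taxa, 2):
        out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


class TestNJ:
    def test_three_taxa_closed_form(self):
        # three-point formulas: l_a = (d_ab + d_ac - d_bc)/2, etc.
        dm = dm_from("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_tree(dm)
        d = patristic(tree)
        assert d[("A", "B")] == pytest.approx(3)
        assert d[("A", "C")] == pytest.approx(4)
        assert d[("B", "C")] == pytest.approx(5)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): the AB|CD split and exact lengths
        dm = dm_from(
            "ABCD",
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        tree = nj_tree(dm)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        d = patristic(tree)
        for pair, expected in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert d[pair] == pytest.approx(expected)
        assert tree_length(tree) == pytest.approx(11.0)

    def test_label_permutation_gives_isomorphic_tree(self):
        from conftest import random_alignment

        rng = np.random.default_rng(4)
        aln = random_alignment(rng, n=7, L=80, missing=0.0)
        dm = distance_matrix(aln)
        perm = rng.permutation(7)
        dm2 = DistanceMatrix(
            labels=[dm.labels[i] for i in perm],
            values=dm.values[np.ix_(perm, perm)],
        )
        assert bipartitions(nj_tree(dm)) == bipartitions(nj_tree(dm2))

    def test_undefined_entries_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        with pytest.raises(ValueError, match="saturated"):
            nj_tree(dm_from("ABC", vals))

    def test_exhaustive_least_squares_oracle_five_taxa(self):
        """NJ recovers the generating topology of random additive 5-taxon
        matrices; the oracle fits all 15 unrooted topologies by least
        squares and picks the one with zero residual."""
        labels = list("ABCDE")

        def topology_paths(cherry1, cherry2):
            # unrooted: cherry1-(u)-(v)-cherry2 with the fifth leaf on u-v
            (a, b), (c, d) = cherry1, cherry2
            e = next(x for x in labels if x not in (a, b, c, d))
            # edges: a,b,c,d,e pendant + internal u-m and m-v (m holds e)
            edges = [a, b, c, d, e, "um", "mv"]
            paths = {
                (a, b): [a, b], (c, d): [c, d],
                (a, c): [a, "um", "mv", c], (a, d): [a, "um", "mv", d],
                (b, c): [b, "um", "mv", c], (b, d): [b, "um", "mv", d],
                (a, e): [a, "um", e], (b, e): [b, "um", e],
                (c, e): [c, "mv", e], (d, e): [d, "mv", e],
            }
            return edges, paths

        def all_topologies():
            seen = set()
            for c1 in itertools.combinations(labels, 2):
                rest = [x for x in labels if x not in c1]
                for c2 in itertools.combinations(rest, 2):
                    key = frozenset((frozenset(c1), frozenset(c2)))
                    if key in seen:
                        continue
                    seen.add(key)
                    yield c1, c2

        assert len(list(all_topologies())) == 15

        rng = np.random.default_rng(12)
        pairs = list(itertools.combinations(labels, 2))
        for trial in range(10):
            # generate a random additive matrix from a random 5-taxon tree
            c1, c2 = list(all_topologies())[rng.integers(15)]
            edges, paths = topology_paths(c1, c2)
            lengths = dict(zip(edges, rng.uniform(0.5, 3.0, len(edges))))
            D = np.zeros((5, 5))
            for (x, y), path in paths.items():
                i, j = labels.index(x), labels.index(y)
                D[i, j] = D[j, i] = sum(lengths[e] for e in path)

            # oracle: least-squares over all 15 topologies
            best, best_rss = None, np.inf
            for t1, t2 in all_topologies():
                edg, pth = topology_paths(t1, t2)
                A = np.zeros((len(pairs), len(edg)))
                y = np.zeros(len(pairs))
                for r, (x, z) in enumerate(pairs):
                    key = (x, z) if (x, z) in pth else (z, x)
                    for e in pth[key]:
                        A[r, edg.index(e)] = 1.0
                    y[r] = D[labels.index(x), labels.index(z)]
                fit, rss, *_ = np.linalg.lstsq(A, y, rcond=None)
                resid = float(((A @ fit - y) ** 2).sum())
                if resid < best_rss:
                    best_rss, best = resid, (t1, t2)
            oracle_splits = {frozenset(best[0]), frozenset(best[1])}
            oracle_splits = {
                s if "A" not in s else frozenset(labels) - s for s in oracle_splits
            }

            tree = nj_tree(dm_from(labels, D))
            assert bipartitions(tree) == oracle_splits, f"trial {trial}"


class TestRooting:
    def four_taxon_tree(self):
        dm = dm_from(
            "ABCD",
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        return nj_tree(dm)

    def test_root_on_outgroup_pendant_edge(self):
        tree = root_with_outgroup(self.four_taxon_tree(), "D")
        children = tree.seed_node.child_nodes()
        assert len(children) == 2
        sides = [frozenset(lf.taxon.label for lf in c.leaf_iter()) for c in children]
        assert frozenset({"D"}) in sides
        # ingroup topology unchanged: A,B still cluster
        assert is_monophyletic(tree, {"A", "B"})

    def test_rooting_preserves_bipartitions(self):
        unrooted = self.four_taxon_tree()
        before = bipartitions(unrooted)
        assert bipartitions(root_with_outgroup(unrooted, "D")) == before

    def test_missing_outgroup_is_error(self):
        with pytest.raises(ValueError, match="not a leaf"):
            root_with_outgroup(self.four_taxon_tree(), "Z")


class TestMonophyly:
    def make_tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_clustered_species_is_monophyletic(self):
        t = self.make_tree("((A1,A2),(B1,B2));")
        assert is_monophyletic(t, {"A1", "A2"})
        assert is_monophyletic(t, {"B1", "B2"})

    def test_interleaved_species_is_not(self):
        t = self.make_tree("((A1,B1),(A2,B2));")
        assert not is_monophyletic(t, {"A1", "A2"})

    def test_singleton_convention(self):
        t = self.make_tree("((A1,B1),(A2,B2));")
        assert is_monophyletic(t, {"A1"})

    def test_unknown_leaf_is_error(self):
        t = self.make_tree("((A1,A2),(B1,B2));")
        with pytest.raises(ValueError, match="not in tree"):
            is_monophyletic(t, {"A1", "ZZ"})


class TestBootstrap:
    def alignment_two_clusters(self):
        rng = np.random.default_rng(8)
        base1 = rng.choice(list("ACGT"), 200)
        base2 = base1.copy()
        flip = rng.random(200) < 0.15  # deep split between the two clusters
        base2[flip] = rng.choice(list("ACGT"), int(flip.sum()))
        seqs = []
        for i in range(6):
            s = (base1 if i < 3 else base2).copy()
            flip = rng.random(200) < 0.01
            s[flip] = rng.choice(list("ACGT"), int(flip.sum()))
            seqs.append(SequenceRecord(id=f"x{i}", seq="".join(s), species="Sp x"))
        return Alignment(seqs)

    def test_separated_clusters_high_support(self):
        aln = self.alignment_two_clusters()
        tree = bootstrap_support(aln, BootstrapConfig(replicates=50, seed=1))
        target = frozenset({"x3", "x4", "x5"})
        supports = {}
        leaves = frozenset(leaf_labels(tree))
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node or node.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if min(leaves) in side:
                side = leaves - side
            supports[side] = int(node.label)
        assert supports[target] >= 95

    def test_single_replicate_supports_binary(self):
        aln = self.alignment_two_clusters()
        tree = bootstrap_support(aln, BootstrapConfig(replicates=1, seed=3))
        vals = [
            int(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert vals and all(v in (0, 100) for v in vals)

    def test_constant_columns_give_full_support(self):
        # every column identical -> every replicate rebuilds the same tree,
        # so every observed bipartition appears in 100% of replicates
        rng = np.random.default_rng(2)
        col = rng.choice(list("ACGT"), (8, 1))
        mat = np.repeat(col, 50, axis=1)
        aln = Alignment(
            [SequenceRecord(id=f"s{i}", seq="".join(mat[i]), species="Sp x") for i in range(8)]
        )
        counts, completed = bootstrap_bipartition_counts(
            aln, BootstrapConfig(replicates=10, seed=0), method="p"
        )
        assert completed == 10
        assert all(c == completed for c in counts.values())

    def test_seed_reproducibility(self):
        aln = self.alignment_two_clusters()
        c1, n1 = bootstrap_bipartition_counts(aln, BootstrapConfig(replicates=20, seed=7))
        c2, n2 = bootstrap_bipartition_counts(aln, BootstrapConfig(replicates=20, seed=7))
        assert c1 == c2 and n1 == n2

    def test_supports_within_range(self):
        aln = self.alignment_two_clusters()
        tree = bootstrap_support(aln, BootstrapConfig(replicates=20, seed=5))
        for n in tree.preorder_node_iter():
            if not n.is_leaf() and n.label is not None:
                assert 0 <= int(n.label) <= 100


class TestNewickIO:
    def test_roundtrip_with_supports(self, tmp_path):
        dm = dm_from(
            "ABCD",
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        tree = nj_tree(dm)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert leaf_labels(back) == {"A", "B", "C", "D"}
        assert bipartitions(back) == bipartitions(tree)
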