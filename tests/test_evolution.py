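import dendropy
import numpy as np
import pytest

from nactk.evolution import (
    bootstrap_support,
    distance_matrix,
    estimate_pattern,
    midpoint_root,
    min_duplication_rooting,
    nj_tree,
    pair_counts,
    reconcile,
    _internal_splits,
)
from nactk.sequence_io import SequenceRecord
from nactk.synthetic_data import EvolutionSpec, evolve_alignment, make_gene_family


def tree_from(newick, rooted=True):
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = rooted
    return t


class TestPairCounts:
    def test_identical_sequences_all_diagonal(self):
        pc = pair_counts("ACGT", "ACGT")
        assert pc.sites_compared == 4
        assert np.trace(pc.matrix) == 4

    def test_pairwise_deletion_drops_gap_columns(self):
        assert pair_counts("A-GT", "ACGT").sites_compared == 3
        assert pair_counts("ANGT", "ACGT").sites_compared == 3

    def test_transition_pairs_counted(self):
        pc = pair_counts("AG", "GA")
        assert pc.matrix[0, 2] == 1 and pc.matrix[2, 0] == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pair_counts("ACG", "AC")


class TestEstimatePattern:
    def test_identical_sequences_undefined(self):
        pattern = estimate_pattern(["ACGTACGT", "ACGTACGT"])
        assert pattern.undefined
        assert np.all(pattern.rates[~np.eye(4, dtype=bool)] == 0)

    def test_pure_purine_transitions(self):
        # differ only by A<->G at one site: no pyrimidine transitions,
        # no transversions
        base = "AG" * 10 + "CT" * 10
        mutated = "GG" + base[2:]
        pattern = estimate_pattern([base, mutated])
        assert pattern.undefined  # no transversions -> infinite ratio flag
        assert pattern.k1 == float("inf")
        off = pattern.rates[~np.eye(4, dtype=bool)]
        ag = {(0, 2), (2, 0)}
        for i in range(4):
            for j in range(4):
                if i != j and (i, j) not in ag:
                    assert pattern.rates[i, j] == 0

    def test_rate_percentages_sum_to_100(self):
        spec = EvolutionSpec(tree="(a:0.08,b:0.08);", length=5000, seed=2)
        leaves, _ = evolve_alignment(spec)
        pattern = estimate_pattern(leaves)
        assert pattern.rates.sum() == pytest.approx(100.0, abs=1e-6)
        assert not pattern.undefined and pattern.k1 > pattern.k2 > 0

    def test_recovers_simulated_ratios(self):
        spec = EvolutionSpec(tree="(a:0.05,b:0.05);", k1=4.0, k2=2.0,
                             length=50_000, seed=9)
        leaves, _ = evolve_alignment(spec)
        pattern = estimate_pattern(leaves)
        assert pattern.k1 == pytest.approx(4.0, rel=0.10)
        assert pattern.k2 == pytest.approx(2.0, rel=0.10)


class TestDistances:
    def test_identical_pair_zero(self):
        d = distance_matrix(["ACGT", "ACGT", "ACGT"])
        assert np.all(d == 0)

    def test_p_distance_example(self):
        d = distance_matrix(["AAAA", "AAAT", "AAAA"], model="p")
        assert d[0, 1] == pytest.approx(0.25)

    def test_tn93_at_least_p(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            spec = EvolutionSpec(
                tree="((a:0.05,b:0.05):0.02,(c:0.04,d:0.06):0.02);",
                length=3000, seed=int(rng.integers(1000)),
            )
            leaves, _ = evolve_alignment(spec)
            p = distance_matrix(leaves, model="p")
            tn = distance_matrix(leaves, model="tn93")
            assert np.all(tn + 1e-12 >= p)


class TestNeighborJoining:
    ADDITIVE = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )

    def test_additive_matrix_recovery(self):
        tree = nj_tree(self.ADDITIVE, ["A", "B", "C", "D"])
        splits = _internal_splits(tree)
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert lengths["D"] == pytest.approx(4.0)

    def test_three_taxa_three_point_solution(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(d, ["a", "b", "c"])
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_label_permutation_equivariance(self):
        labels = ["A", "B", "C", "D"]
        perm = [2, 0, 3, 1]
        d2 = self.ADDITIVE[np.ix_(perm, perm)]
        t1 = nj_tree(self.ADDITIVE, labels)
        t2 = nj_tree(d2, [labels[i] for i in perm])
        assert _internal_splits(t1) == _internal_splits(t2)

    def test_asymmetric_matrix_rejected(self):
        bad = self.ADDITIVE.copy()
        bad[0, 1] = 99
        with pytest.raises(ValueError):
            nj_tree(bad, ["A", "B", "C", "D"])

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            true_splits, dist, labels = random_additive_matrix(rng, n)
            recovered = nj_tree(dist, labels)
            assert _internal_splits(recovered) == true_splits

    def test_agreement_with_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbour joining."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(19)
        _, dist, labels = random_additive_matrix(rng, 8)
        ours = nj_tree(dist, labels)
        theirs = skbio_nj(DistanceMatrix(dist, labels))
        their_tree = dendropy.Tree.get(
            data=str(theirs), schema="newick", preserve_underscores=True
        )
        assert _internal_splits(ours) == _internal_splits(their_tree)


def random_additive_matrix(rng, n):
    """Random binary tree (as its non-trivial split set) with positive
    branch lengths, plus the exact path-length (additive) distance matrix.
    Built by random agglomeration with random limb lengths — independent of
    the NJ implementation under test."""
    labels = [f"t{i}" for i in range(n)]
    dist = np.zeros((n, n))
    items = list(range(n))
    next_id = n
    path = {i: {i: 0.0} for i in range(n)}  # node -> leaf -> path length
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        a, b = items[i], items[j]
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        merged = {leaf: d + la for leaf, d in path[a].items()}
        merged.update({leaf: d + lb for leaf, d in path[b].items()})
        for x, dx in path[a].items():
            for y, dy in path[b].items():
                dist[x, y] = dist[y, x] = dx + la + dy + lb
        path[next_id] = merged
        items = [v for v in items if v not in (a, b)] + [next_id]
        next_id += 1
    all_leaves = frozenset(labels)
    ref = min(labels)
    splits = set()
    for key, leaf_paths in path.items():
        if key < n:
            continue
        side = frozenset(labels[k] for k in leaf_paths)
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < n - 1:
            splits.add(side)
    return splits, dist, labels


class TestBootstrap:
    def test_two_clades_full_support(self):
        spec = EvolutionSpec(
            tree="((a:0.01,b:0.01):0.3,(c:0.01,d:0.01):0.3);",
            length=2000, seed=7,
        )
        leaves, _ = evolve_alignment(spec)
        _, support = bootstrap_support(leaves, n_reps=100, seed=7)
        assert support and all(v == pytest.approx(1.0) for v in support.values())

    def test_single_replicate_support_binary(self):
        spec = EvolutionSpec(
            tree="((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05);",
            length=500, seed=3,
        )
        leaves, _ = evolve_alignment(spec)
        _, support = bootstrap_support(leaves, n_reps=1, seed=1)
        assert all(v in (0.0, 1.0) for v in support.values())

    def test_same_seed_same_support(self):
        spec = EvolutionSpec(
            tree="((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02);",
            length=800, seed=5,
        )
        leaves, _ = evolve_alignment(spec)
        _, s1 = bootstrap_support(leaves, n_reps=25, seed=42)
        _, s2 = bootstrap_support(leaves, n_reps=25, seed=42)
        assert s1 == s2


class TestReconcile:
    SPECIES_AB = "(A,B);"

    def test_congruent_single_copy_family(self):
        gene = tree_from("(A|g1,B|g1);")
        res = reconcile(gene, tree_from(self.SPECIES_AB))
        assert (res.duplications, res.losses, res.paralog_gene_count) == (0, 0, 0)

    def test_root_duplication(self):
        gene = tree_from("((A|g1,B|g1),(A|g2,B|g2));")
        res = reconcile(gene, tree_from(self.SPECIES_AB))
        assert res.duplications == 1 and res.losses == 0
        assert res.paralog_gene_count == 4

    def test_duplication_with_loss(self):
        # duplicated at the root, one B copy lost
        gene = tree_from("((A|g1,B|g1),A|g2);")
        res = reconcile(gene, tree_from(self.SPECIES_AB))
        assert res.duplications == 1 and res.losses == 1

    def test_non_binary_species_tree_rejected(self):
        gene = tree_from("(A|g1,B|g1);")
        with pytest.raises(ValueError, match="binary"):
            reconcile(gene, tree_from("(A,B,C);"))

    def test_unmapped_leaf_rejected(self):
        gene = tree_from("(A|g1,Z|g1);")
        with pytest.raises(ValueError, match="absent"):
            reconcile(gene, tree_from(self.SPECIES_AB))

    def test_planted_duplications_recovered(self):
        species = tree_from("((A,B),(C,D));")
        for seed in range(40):
            d = seed % 6
            gene, leaf_map, truth = make_gene_family(
                species, n_duplications=d, loss_prob=0.0, seed=seed
            )
            res = reconcile(gene, species, leaf_map)
            assert res.duplications == truth["duplications"] == d
            assert res.losses == 0

    def test_zero_duplications_iff_congruent(self):
        species = tree_from("((A,B),(C,D));")
        gene, leaf_map, _ = make_gene_family(species, 0, 0.0, seed=1)
        assert reconcile(gene, species, leaf_map).duplications == 0
        gene2, leaf_map2, _ = make_gene_family(species, 2, 0.0, seed=1)
        assert reconcile(gene2, species, leaf_map2).duplications > 0

    def test_midpoint_rooting_never_beats_exhaustive_search(self):
        species = tree_from("((A,B),(C,D));")
        for seed in range(10):
            gene, leaf_map, _ = make_gene_family(species, 2, 0.0, seed=seed)
            for e in gene.preorder_edge_iter():
                e.length = 1.0
            unrooted = gene.clone(depth=1)
            unrooted.is_rooted = False
            best, _ = min_duplication_rooting(unrooted, species, leaf_map)
            mid = midpoint_root(unrooted)
            res_mid = reconcile(mid, species, leaf_map)
            assert res_mid.duplications >= best.duplications
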