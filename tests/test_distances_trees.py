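"""Chord / allele-sharing distances, NJ, least-squares search, consensus."""

import numpy as np
import pytest

import lapinpop as lp
from lapinpop.distances import CHORD_MAX, read_phylip_distances, write_phylip_distances
from lapinpop.trees import Tree, ls_branch_lengths

from conftest import random_dataset


def _dataset_from_genotypes(genotypes, units=None):
    """genotypes: list of per-individual lists of (a, b) pairs."""
    n_loci = len(genotypes[0])
    loci = [lp.Locus(f"L{j}") for j in range(n_loci)]
    inds = [
        lp.Individual(f"i{k}", "domestic", (units or ["u"] * len(genotypes))[k])
        for k in range(len(genotypes))
    ]
    return lp.GenotypeDataset(loci, inds, np.array(genotypes))


class TestChordDistance:
    def test_identical_frequencies_give_zero(self):
        ds = _dataset_from_genotypes([[(1, 2), (3, 3)], [(1, 2), (3, 3)]])
        dm = lp.chord_distance_matrix(ds)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_hit_formula_limit(self):
        ds = _dataset_from_genotypes([[(1, 1)], [(2, 2)]])
        dm = lp.chord_distance_matrix(ds)
        assert dm.values[0, 1] == pytest.approx(CHORD_MAX)

    def test_matches_direct_formula_recomputation(self):
        """Spreadsheet-style recomputation of the pinned per-locus form."""
        ds = random_dataset(41, n_units=2, n_per_unit=6, missing_rate=0.0)
        tab = lp.allele_frequencies(ds, "unit")
        dm = lp.chord_distance_matrix(tab)
        d2 = []
        for loc in ds.locus_names:
            fa = tab.frequencies("unit0", loc)
            fb = tab.frequencies("unit1", loc)
            s = sum(
                np.sqrt(fa.get(a, 0.0) * fb.get(a, 0.0))
                for a in set(fa) | set(fb)
            )
            d2.append((2 / np.pi) ** 2 * 2 * (1 - s))
        assert dm.get("unit0", "unit1") == pytest.approx(np.sqrt(np.mean(d2)))

    def test_invariant_under_locus_order(self):
        ds = random_dataset(42, missing_rate=0.0)
        dm1 = lp.chord_distance_matrix(ds)
        perm = list(reversed(range(ds.n_loci)))
        shuffled = lp.GenotypeDataset(
            [ds.loci[j] for j in perm], ds.individuals, ds.calls[:, perm, :]
        )
        dm2 = lp.chord_distance_matrix(shuffled)
        assert np.allclose(dm1.values, dm2.values)


class TestAlleleSharingDistance:
    def test_identical_genotypes_give_zero(self):
        ds = _dataset_from_genotypes([[(1, 2), (3, 4)], [(1, 2), (3, 4)]])
        assert lp.allele_sharing_distance_matrix(ds).values[0, 1] == 0.0

    def test_no_shared_alleles_give_one(self):
        ds = _dataset_from_genotypes([[(1, 2), (3, 4)], [(5, 6), (7, 8)]])
        assert lp.allele_sharing_distance_matrix(ds).values[0, 1] == 1.0

    def test_half_shared_single_locus(self):
        # AB vs AA: one of two alleles matched -> 0.5
        ds = _dataset_from_genotypes([[(1, 2)], [(1, 1)]])
        assert lp.allele_sharing_distance_matrix(ds).values[0, 1] == pytest.approx(0.5)

    def test_het_pair_shares_both(self):
        ds = _dataset_from_genotypes([[(1, 2)], [(2, 1)]])
        assert lp.allele_sharing_distance_matrix(ds).values[0, 1] == 0.0


class TestPhylipIO:
    @pytest.mark.parametrize("lower", [False, True])
    def test_round_trip(self, tmp_path, lower):
        rng = np.random.default_rng(1)
        v = rng.random((4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        dm = lp.DistanceMatrix(list("abcd"), v)
        path = tmp_path / "d.phy"
        write_phylip_distances(dm, path, lower_triangle=lower)
        back = read_phylip_distances(path)
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values, atol=1e-6)


# ---------------------------------------------------------------------
# random additive trees as the NJ oracle


def random_binary_tree(n_leaves, rng):
    """Sequential random leaf addition with random branch lengths."""
    adjacency = {0: {3: 0.0}, 1: {3: 0.0}, 2: {3: 0.0},
                 3: {0: 0.0, 1: 0.0, 2: 0.0}}
    leaf_labels = {i: f"t{i}" for i in range(3)}
    nxt = 4
    for leaf in range(3, n_leaves):
        edges = [(u, v) for u in adjacency for v in adjacency[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        mid, new_leaf = nxt, nxt + 1
        nxt += 2
        del adjacency[u][v], adjacency[v][u]
        adjacency[mid] = {u: 0.0, v: 0.0, new_leaf: 0.0}
        adjacency[u][mid] = adjacency[v][mid] = 0.0
        adjacency[new_leaf] = {mid: 0.0}
        leaf_labels[new_leaf] = f"t{leaf}"
    t = Tree(adjacency, leaf_labels)
    for a, b in t.edges():
        length = float(rng.uniform(0.1, 1.0))
        t.adjacency[a][b] = t.adjacency[b][a] = length
    return t


class TestNeighborJoining:
    @pytest.mark.parametrize("n", [4, 6, 9, 12])
    def test_recovers_additive_matrices(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            true = random_binary_tree(n, rng)
            dm = true.path_lengths()
            est = lp.neighbor_joining(dm)
            assert est.splits() == true.splits()
            back = est.path_lengths()
            order = [back.labels.index(lb) for lb in dm.labels]
            assert np.allclose(
                back.values[np.ix_(order, order)], dm.values, atol=1e-9
            )

    def test_three_taxa_three_point_solution(self):
        v = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        t = lp.neighbor_joining(lp.DistanceMatrix(list("abc"), v))
        back = t.path_lengths()
        order = [back.labels.index(x) for x in "abc"]
        assert np.allclose(back.values[np.ix_(order, order)], v, atol=1e-12)

    def test_absent_entries_rejected(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = np.nan
        with pytest.raises(ValueError, match="absent"):
            lp.neighbor_joining(lp.DistanceMatrix(list("abc"), v))

    def test_branch_lengths_nonnegative_on_noisy_input(self):
        rng = np.random.default_rng(77)
        true = random_binary_tree(8, rng)
        dm = true.path_lengths()
        noisy = dm.values + rng.normal(0, 0.05, dm.values.shape)
        noisy = np.clip((noisy + noisy.T) / 2, 0.01, None)
        np.fill_diagonal(noisy, 0)
        t = lp.neighbor_joining(lp.DistanceMatrix(dm.labels, noisy))
        assert all(
            l >= 0 for nbrs in t.adjacency.values() for l in nbrs.values()
        )


def enumerate_topologies(labels):
    """All unrooted binary topologies by sequential insertion (15 at n=5,
    105 at n=6)."""
    base = Tree(
        {0: {3: 0.0}, 1: {3: 0.0}, 2: {3: 0.0}, 3: {0: 0.0, 1: 0.0, 2: 0.0}},
        {i: labels[i] for i in range(3)},
    )
    trees = [base]
    for leaf in range(3, len(labels)):
        nxt_trees = []
        for t in trees:
            for u, v in t.edges():
                t2 = t.copy()
                mid = max(t2.adjacency) + 1
                new_leaf = mid + 1
                del t2.adjacency[u][v], t2.adjacency[v][u]
                t2.adjacency[mid] = {u: 0.0, v: 0.0, new_leaf: 0.0}
                t2.adjacency[u][mid] = t2.adjacency[v][mid] = 0.0
                t2.adjacency[new_leaf] = {mid: 0.0}
                t2.leaf_labels[new_leaf] = labels[leaf]
                nxt_trees.append(t2)
        trees = nxt_trees
    return trees


class TestLeastSquaresTree:
    def test_additive_input_recovered_with_zero_objective(self):
        rng = np.random.default_rng(5)
        true = random_binary_tree(7, rng)
        dm = true.path_lengths()
        est = lp.least_squares_tree(dm)
        assert est.splits() == true.splits()
        assert est.ls_objective == pytest.approx(0.0, abs=1e-10)

    def test_objective_not_above_nj_fit(self):
        ds = random_dataset(55, n_units=5, n_per_unit=5, missing_rate=0.0)
        dm = lp.chord_distance_matrix(lp.allele_frequencies(ds, "unit"))
        nj_fit, nj_obj = ls_branch_lengths(lp.neighbor_joining(dm), dm)
        est = lp.least_squares_tree(dm)
        assert est.ls_objective <= nj_obj + 1e-12

    def test_matches_exhaustive_search_at_n6(self):
        """NNI hill-climb finds the global weighted-LS optimum over all
        105 six-taxon topologies in >= 90% of noisy trials."""
        rng = np.random.default_rng(99)
        labels = [f"t{i}" for i in range(6)]
        wins = 0
        trials = 25
        for _ in range(trials):
            true = random_binary_tree(6, rng)
            noisy = true.path_lengths().values + rng.normal(0, 0.08, (6, 6))
            noisy = np.clip((noisy + noisy.T) / 2, 0.01, None)
            np.fill_diagonal(noisy, 0)
            dm = lp.DistanceMatrix([true.leaf_labels[v] for v in true.leaves],
                                   noisy)
            est = lp.least_squares_tree(dm)
            best = min(
                ls_branch_lengths(t, dm)[1] for t in enumerate_topologies(dm.labels)
            )
            wins += est.ls_objective <= best + 1e-9
        assert wins >= 0.9 * trials


class TestConsensus:
    def test_degenerate_consensus_reproduces_input(self, rabbit_sim):
        ds, _ = rabbit_sim
        sub = ds.subset(units=ds.units()[:8])
        t = lp.bootstrap_consensus(sub, n_replicates=5, seed=0, resample=False)
        single = lp.neighbor_joining(
            lp.chord_distance_matrix(lp.allele_frequencies(sub, "unit"))
        )
        assert t.splits() == single.splits()
        assert set(t.edge_support.values()) == {5}

    def test_two_clade_recovery_under_strong_drift(self):
        """Two deeply diverged stage families should form >= 95%-supported
        clades in the locus bootstrap."""
        stages = [
            lp.FounderEvent("anc", None, 1000),
            lp.FounderEvent("cladeA", "anc", 4, 20, 20),
            lp.FounderEvent("cladeB", "anc", 4, 20, 20),
        ]
        for fam in "AB":
            for i in range(3):
                stages.append(
                    lp.FounderEvent(f"{fam}{i}", f"clade{fam}", 30, 2, 100)
                )
        sc = lp.BottleneckScenario(
            n_loci=40, allele_states_per_locus=(6, 12),
            ancestral_dirichlet_alpha=1.0, stages=stages,
            sample_plan={
                f"{fam}{i}": (f"{fam}{i}", "domestic", 15)
                for fam in "AB" for i in range(3)
            },
            seed=8,
        )
        ds, _ = lp.simulate_scenario(sc)
        t = lp.bootstrap_consensus(ds, n_replicates=100, seed=2)
        clade_a = frozenset({"A0", "A1", "A2"})
        clade_b = frozenset({"B0", "B1", "B2"})
        split_support = {}
        full = frozenset(t.leaf_labels.values())
        ref = sorted(t.leaf_labels.values())[0]
        for (u, v), c in [(tuple(sorted(e)), c) for e, c in t.edge_support.items()]:
            side = frozenset(
                t.leaf_labels[x] for x in t._leafset_beyond(u, v)
            )
            for s in (side, full - side):
                split_support[s] = c
        found = {s for s in (clade_a, clade_b) if s in split_support}
        assert found == {clade_a, clade_b}
        assert all(split_support[s] >= 95 for s in found)

    def test_support_counts_bounded_by_replicates(self, rabbit_sim):
        ds, _ = rabbit_sim
        sub = ds.subset(units=ds.units()[:6])
        t = lp.bootstrap_consensus(sub, n_replicates=30, seed=4)
        assert all(0 < c <= 30 for c in t.edge_support.values())

    def test_newick_round_trips_through_dendropy(self, rabbit_sim):
        import dendropy

        ds, _ = rabbit_sim
        sub = ds.subset(units=ds.units()[:6])
        t = lp.neighbor_joining(
            lp.chord_distance_matrix(lp.allele_frequencies(sub, "unit"))
        )
        parsed = dendropy.Tree.get(
            data=t.to_newick(), schema="newick", preserve_underscores=True
        )
        assert {x.taxon.label for x in parsed.leaf_node_iter()} == set(
            t.leaf_labels.values()
        )
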