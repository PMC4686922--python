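"""Weir-Cockerham theta, three-level AMOVA and the HW chi-square screen."""

import numpy as np
import pytest

import lapinpop as lp

from conftest import random_dataset, two_unit_panmictic


def _fixed_difference_dataset(n=20, n_loci=5):
    loci = [lp.Locus(f"L{j}") for j in range(n_loci)]
    inds = [lp.Individual(f"a{i}", "domestic", "A") for i in range(n)] + [
        lp.Individual(f"b{i}", "domestic", "B") for i in range(n)
    ]
    calls = np.empty((2 * n, n_loci, 2), dtype=np.int64)
    calls[:n] = 100
    calls[n:] = 102
    return lp.GenotypeDataset(loci, inds, calls)


class TestTheta:
    def test_panmictic_units_near_zero(self):
        ds = two_unit_panmictic(1)
        assert abs(lp.weir_cockerham_theta(ds)) < 0.02

    def test_fixed_differences_give_one(self):
        ds = _fixed_difference_dataset()
        assert lp.weir_cockerham_theta(ds) == pytest.approx(1.0)

    def test_invariant_under_allele_relabeling(self, rabbit_sim):
        ds, _ = rabbit_sim
        dom = ds.subset(groups=["domestic"])
        t1 = lp.weir_cockerham_theta(dom)
        relabeled = lp.GenotypeDataset(
            dom.loci, dom.individuals,
            np.where(dom.calls > 0, 1000 - dom.calls, 0),
        )
        assert lp.weir_cockerham_theta(relabeled) == pytest.approx(t1)

    def test_stable_under_duplicating_individuals(self):
        ds = random_dataset(3, n_units=2, n_per_unit=50, n_loci=12,
                            missing_rate=0.0)
        t1 = lp.weir_cockerham_theta(ds)
        doubled = lp.GenotypeDataset(
            ds.loci,
            ds.individuals
            + [lp.Individual(f"{i.id}_dup", i.group, i.unit) for i in ds.individuals],
            np.concatenate([ds.calls, ds.calls]),
        )
        assert abs(lp.weir_cockerham_theta(doubled) - t1) < 0.01

    def test_pairwise_matrix_structure(self):
        ds = random_dataset(9, n_units=3, n_per_unit=8, missing_rate=0.0)
        res = lp.pairwise_fst(ds, n_permutations=49, seed=1)
        assert np.allclose(res.theta, res.theta.T)
        assert np.allclose(np.diag(res.theta), 0.0)
        assert ((res.p_values >= 1 / 50) | np.eye(3, dtype=bool)).all()
        assert (res.p_values <= 1.0).all()

    def test_permutation_detects_fixed_structure(self):
        ds = _fixed_difference_dataset(n=10, n_loci=3)
        res = lp.pairwise_fst(ds, n_permutations=99, seed=0)
        assert res.pair("A", "B") == pytest.approx(1.0)
        assert res.p_values[0, 1] <= 0.05
        assert res.global_p <= 0.05


class TestAmova:
    def test_hand_computed_toy(self):
        """4 individuals, 1 locus, 2 units: AA,AB | BB,BB.

        Sums of squares from the number-of-different-alleles identity:
        SS_total = 1.875, within-units = 0.75, within-individuals = 0.5,
        hence SS = (1.125, 0.25, 0.5) and components
        Va = 0.25, Vb = 0, Vc = 0.125.
        """
        loci = [lp.Locus("L1")]
        inds = [
            lp.Individual("i1", "domestic", "U1"),
            lp.Individual("i2", "domestic", "U1"),
            lp.Individual("i3", "domestic", "U2"),
            lp.Individual("i4", "domestic", "U2"),
        ]
        calls = np.array([[[1, 1]], [[1, 2]], [[2, 2]], [[2, 2]]])
        res = lp.amova_three_level(lp.GenotypeDataset(loci, inds, calls))
        ss = res.sum_of_squares
        assert ss["among_units"] == pytest.approx(1.125)
        assert ss["among_individuals_within_units"] == pytest.approx(0.25)
        assert ss["within_individuals"] == pytest.approx(0.5)
        v = res.variance_components
        assert v["among_units"] == pytest.approx(0.25)
        assert v["among_individuals_within_units"] == pytest.approx(0.0)
        assert v["within_individuals"] == pytest.approx(0.125)
        assert res.df == {
            "among_units": 1,
            "among_individuals_within_units": 2,
            "within_individuals": 4,
        }

    def test_percent_sums_to_100(self, rabbit_sim):
        ds, _ = rabbit_sim
        res = lp.amova_three_level(ds.subset(groups=["domestic"]))
        assert sum(res.percent_variation.values()) == pytest.approx(100, abs=0.1)

    def test_cloned_unit_has_no_among_component(self):
        ds = random_dataset(17, n_units=1, n_per_unit=20, missing_rate=0.0)
        cloned = lp.GenotypeDataset(
            ds.loci,
            [lp.Individual(i.id, i.group, "u_a") for i in ds.individuals[:10]]
            + [lp.Individual(i.id, i.group, "u_b") for i in ds.individuals[10:]],
            ds.calls,
        )
        res = lp.amova_three_level(cloned)
        total = sum(res.variance_components.values())
        assert abs(res.variance_components["among_units"]) <= 0.005 * abs(total) + 0.02

    def test_agreement_with_theta_estimator(self, rabbit_sim):
        """Va/(Va+Vb+Vc) and Weir-Cockerham theta are the same quantity
        computed through two independent code paths."""
        ds, _ = rabbit_sim
        dom = ds.subset(groups=["domestic"])
        res = lp.amova_three_level(dom)
        phi = res.variance_components["among_units"] / sum(
            res.variance_components.values()
        )
        assert phi == pytest.approx(lp.weir_cockerham_theta(dom), abs=0.01)

    def test_permutation_p_for_real_structure(self):
        ds, _ = __import__("conftest").drifted_units(3, n_units=3, n=10, n_loci=10)
        res = lp.amova_three_level(ds, n_permutations=49, seed=1)
        assert res.p_values["among_units"] <= 0.05


class TestHWScreen:
    def test_exact_hw_proportions_give_zero_chi2(self):
        loci = [lp.Locus("L1")]
        inds = [lp.Individual(f"i{k}", "domestic", "u") for k in range(4)]
        calls = np.array([[[1, 1]], [[1, 2]], [[1, 2]], [[2, 2]]])
        res = lp.hw_chisq_screen(lp.GenotypeDataset(loci, inds, calls))
        row = res.table.iloc[0]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_total_homozygote_excess(self):
        """100 individuals, all homozygous, p = q = 0.5: chi2 = 100 on 1 df."""
        loci = [lp.Locus("L1")]
        inds = [lp.Individual(f"i{k}", "domestic", "u") for k in range(100)]
        calls = np.array([[[1, 1]]] * 50 + [[[2, 2]]] * 50)
        res = lp.hw_chisq_screen(lp.GenotypeDataset(loci, inds, calls))
        row = res.table.iloc[0]
        assert row["chi2"] == pytest.approx(100.0)
        assert row["df"] == 1
        assert row["significant_after_bonferroni"]

    def test_monomorphic_cells_excluded(self):
        loci = [lp.Locus("L1"), lp.Locus("L2")]
        inds = [lp.Individual(f"i{k}", "domestic", "u") for k in range(4)]
        calls = np.array(
            [[[1, 1], [5, 5]], [[1, 2], [5, 5]], [[1, 2], [5, 5]], [[2, 2], [5, 5]]]
        )
        res = lp.hw_chisq_screen(lp.GenotypeDataset(loci, inds, calls))
        assert set(res.table["locus"]) == {"L1"}

    def test_percent_deviating_bounded(self, rabbit_sim):
        ds, _ = rabbit_sim
        res = lp.hw_chisq_screen(ds.subset(groups=["domestic"]))
        assert ((res.percent_deviating >= 0) & (res.percent_deviating <= 100)).all()
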