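"""He, FIS and rarefied (private) allelic richness against exhaustive oracles."""

import itertools

import numpy as np
import pytest

import lapinpop as lp
from lapinpop.diversity import expected_heterozygosity

from conftest import random_dataset


# ---------------------------------------------------------------------
# exhaustive oracles: average over every possible g-copy subsample


def _enum_ar(counts: dict, g: int) -> float:
    copies = [a for a, c in counts.items() for _ in range(c)]
    subs = list(itertools.combinations(range(len(copies)), g))
    total = sum(len({copies[i] for i in s}) for s in subs)
    return total / len(subs)


def _enum_presence(counts: dict, g: int) -> dict:
    """P(allele in a random g-copy subsample), per allele, by enumeration."""
    copies = [a for a, c in counts.items() for _ in range(c)]
    subs = list(itertools.combinations(range(len(copies)), g))
    out = {}
    for a in counts:
        out[a] = sum(a in {copies[i] for i in s} for s in subs) / len(subs)
    return out


def _enum_par(by_unit: dict, focal: str, g: int) -> float:
    pres = {u: _enum_presence(c, g) for u, c in by_unit.items()}
    total = 0.0
    for a in by_unit[focal]:
        term = pres[focal][a]
        for u in by_unit:
            if u != focal:
                term *= 1.0 - pres[u].get(a, 0.0)
        total += term
    return total


class TestExpectedHeterozygosity:
    def test_monomorphic_is_zero(self):
        assert expected_heterozygosity({1: 1.0}) == 0.0

    def test_two_equal_alleles(self):
        assert expected_heterozygosity({1: 0.5, 2: 0.5}) == pytest.approx(0.5)

    def test_unbiased_correction(self):
        assert expected_heterozygosity(
            [0.5, 0.5], n_copies=4, unbiased=True
        ) == pytest.approx(0.5 * 4 / 3)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expected_heterozygosity({})

    def test_invariant_under_relabeling(self):
        f = {100: 0.2, 104: 0.5, 110: 0.3}
        g = {7: 0.5, 1: 0.3, 3: 0.2}
        assert expected_heterozygosity(f) == pytest.approx(
            expected_heterozygosity(g)
        )


class TestAllelicRichness:
    def test_full_sample_equals_observed_count(self):
        counts = {1: 3, 2: 5, 3: 1}
        assert lp.allelic_richness(counts, g=9) == pytest.approx(3.0)

    def test_two_by_two_at_g2(self):
        # enumeration: 2 * (1 - C(2,2)/C(4,2)) = 5/3
        assert lp.allelic_richness({1: 2, 2: 2}, g=2) == pytest.approx(5 / 3)

    def test_g_exceeding_copies_rejected(self):
        with pytest.raises(ValueError, match="drop this unit"):
            lp.allelic_richness({1: 2}, g=3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        counts = {int(a): int(c) for a, c in
                  zip(range(k), rng.integers(1, 5, size=k))}
        n = sum(counts.values())
        if n > 12:
            counts[0] -= n - 12
            counts = {a: c for a, c in counts.items() if c > 0}
            n = sum(counts.values())
        for g in range(1, n + 1):
            assert lp.allelic_richness(counts, g) == pytest.approx(
                _enum_ar(counts, g), abs=1e-10
            )

    def test_monotone_in_g(self):
        counts = {1: 4, 2: 3, 3: 2, 4: 1}
        vals = [lp.allelic_richness(counts, g) for g in range(1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestPrivateAllelicRichness:
    def test_single_unit_equals_ar(self):
        counts = {"u": {1: 3, 2: 5}}
        assert lp.private_allelic_richness(counts, "u", 4) == pytest.approx(
            lp.allelic_richness(counts["u"], 4)
        )

    def test_shared_fixed_allele_contributes_nothing(self):
        by_unit = {"a": {1: 6}, "b": {1: 6}}
        assert lp.private_allelic_richness(by_unit, "a", 4) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        by_unit = {}
        for u in ("a", "b", "c"):
            k = rng.integers(2, 4)
            alleles = rng.choice(6, size=k, replace=False)
            by_unit[u] = {int(a): int(c) for a, c in
                          zip(alleles, rng.integers(1, 4, size=k))}
        for u in by_unit:
            while sum(by_unit[u].values()) < 4:
                a = next(iter(by_unit[u]))
                by_unit[u][a] += 1
        g = 4
        got = lp.private_allelic_richness(by_unit, "b", g)
        assert got == pytest.approx(_enum_par(by_unit, "b", g), abs=1e-10)

    def test_par_never_exceeds_ar(self):
        rng = np.random.default_rng(5)
        by_unit = {
            u: {int(a): int(c) for a, c in
                zip(rng.choice(8, 4, replace=False), rng.integers(2, 6, 4))}
            for u in "abcd"
        }
        for u in by_unit:
            par = lp.private_allelic_richness(by_unit, u, 6)
            ar = lp.allelic_richness(by_unit[u], 6)
            assert 0.0 <= par <= ar + 1e-12


class TestFis:
    def test_all_heterozygotes_gives_minus_one(self):
        loci = [lp.Locus("L1")]
        inds = [lp.Individual(f"i{k}", "domestic", "u") for k in range(4)]
        calls = np.tile(np.array([[[100, 102]]]), (4, 1, 1))
        ds = lp.GenotypeDataset(loci, inds, calls)
        assert lp.fis(ds, "u") == pytest.approx(-1.0)

    def test_hw_proportions_give_zero(self):
        # genotype counts 1 AA : 2 AB : 1 BB -> Ho = He = 0.5
        loci = [lp.Locus("L1")]
        inds = [lp.Individual(f"i{k}", "domestic", "u") for k in range(4)]
        calls = np.array([[[100, 100]], [[100, 102]], [[100, 102]], [[102, 102]]])
        ds = lp.GenotypeDataset(loci, inds, calls)
        assert lp.fis(ds, "u") == pytest.approx(0.0)

    def test_matches_direct_counting(self):
        ds = random_dataset(21, n_units=2, n_per_unit=8)
        for unit, idx in ds.partition("unit").items():
            per_locus = []
            for j in range(ds.n_loci):
                sub = ds.calls[idx, j]
                sub = sub[(sub != 0).all(axis=1)]
                if not len(sub):
                    continue
                ho = np.mean(sub[:, 0] != sub[:, 1])
                _, cnt = np.unique(sub.ravel(), return_counts=True)
                he = 1 - ((cnt / cnt.sum()) ** 2).sum()
                if he > 0:
                    per_locus.append(1 - ho / he)
            assert lp.fis(ds, unit) == pytest.approx(np.mean(per_locus))

    def test_all_monomorphic_is_nan(self):
        loci = [lp.Locus("L1")]
        inds = [lp.Individual("a", "domestic", "u")]
        ds = lp.GenotypeDataset(loci, inds, np.array([[[100, 100]]]))
        assert np.isnan(lp.fis(ds, "u"))


class TestSummary:
    def test_single_unit_group_row_equals_unit_row(self):
        ds = random_dataset(31, n_units=1, n_per_unit=8, missing_rate=0.0)
        by_unit = lp.summarize_diversity(ds, "unit", g=8).table
        by_group = lp.summarize_diversity(ds, "group", g=8).table
        for col in ("n", "Na", "He", "Ho", "FIS", "Ar"):
            assert by_unit.iloc[0][col] == pytest.approx(
                by_group.iloc[0][col], nan_ok=True
            )

    def test_small_unit_rarefied_columns_absent(self):
        ds = random_dataset(32, n_units=2, n_per_unit=3, missing_rate=0.0)
        table = lp.summarize_diversity(ds, "unit", g=8).table
        assert table["Ar"].isna().all()  # 3 individuals = 6 copies < g = 8
        assert table["He"].notna().all()

    def test_rarefied_values_bounded_by_na(self, rabbit_sim):
        ds, _ = rabbit_sim
        summ = lp.summarize_diversity(ds, "unit", g=8)
        ok = summ.table.dropna(subset=["Ar"])
        assert ((ok["Ar"] >= 1 - 1e-9) & (ok["Ar"] <= ok["Na"] + 1e-9)).all()
        assert (summ.table["PAr"].dropna() >= -1e-12).all()
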