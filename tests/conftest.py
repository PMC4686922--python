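import numpy as np
import pytest

import lapinpop as lp


@pytest.fixture(scope="session")
def rabbit_sim():
    """One realisation of the default study-shaped scenario (shared)."""
    return lp.simulate_scenario(lp.default_rabbit_scenario(1))


@pytest.fixture
def tiny_dataset():
    """3 individuals x 2 loci, two units, no missing data."""
    loci = [lp.Locus("L1"), lp.Locus("L2")]
    inds = [
        lp.Individual("i1", "wild_iberia", "loc1"),
        lp.Individual("i2", "wild_iberia", "loc1"),
        lp.Individual("i3", "domestic", "breedA"),
    ]
    calls = np.array(
        [
            [[100, 100], [200, 202]],
            [[100, 102], [200, 200]],
            [[102, 102], [202, 202]],
        ]
    )
    return lp.GenotypeDataset(loci, inds, calls)


def random_dataset(seed, n_units=3, n_per_unit=6, n_loci=4, missing_rate=0.1):
    """Small random dataset with missing calls, for round-trip/oracle tests."""
    rng = np.random.default_rng(seed)
    loci = [lp.Locus(f"L{j}") for j in range(n_loci)]
    groups = ["wild_iberia", "wild_france", "domestic"]
    inds, rows = [], []
    for u in range(n_units):
        for i in range(n_per_unit):
            inds.append(
                lp.Individual(f"u{u}_i{i}", groups[u % 3], f"unit{u}",
                              subunit="s1" if (u == 0 and i % 2) else None)
            )
            geno = rng.integers(100, 112, size=(n_loci, 2)) * 1
            rows.append(geno)
    calls = np.stack(rows)
    miss = rng.random((len(inds), n_loci)) < missing_rate
    calls[miss] = 0
    return lp.GenotypeDataset(loci, inds, calls)


def two_unit_panmictic(seed, n=50, n_loci=20, k=8):
    """Two units sampled from one panmictic pool (theta should be ~0)."""
    rng = np.random.default_rng(seed)
    stages = [lp.FounderEvent("pool", None, founder_size=10**6)]
    sc = lp.BottleneckScenario(
        n_loci=n_loci,
        allele_states_per_locus=(k, k),
        ancestral_dirichlet_alpha=1.0,
        stages=stages,
        sample_plan={
            "a": ("pool", "domestic", n),
            "b": ("pool", "domestic", n),
        },
        seed=int(rng.integers(2**31)),
    )
    ds, _ = lp.simulate_scenario(sc)
    return ds


def drifted_units(seed, n_units=3, founder=4, gens=15, n=20, n_loci=30):
    """Strongly drifted sibling units (deep independent bottlenecks)."""
    stages = [lp.FounderEvent("anc", None, 1000)] + [
        lp.FounderEvent(f"s{i}", "anc", founder, gens, 20)
        for i in range(n_units)
    ]
    sc = lp.BottleneckScenario(
        n_loci=n_loci,
        allele_states_per_locus=(5, 10),
        ancestral_dirichlet_alpha=1.0,
        stages=stages,
        sample_plan={f"u{i}": (f"s{i}", "domestic", n) for i in range(n_units)},
        seed=seed,
    )
    return lp.simulate_scenario(sc)
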