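"""Chromosome-resampling estimator of proportional diversity loss.

The statistic behind each comparison is

    loss = 1 - He(derived draw) / He(source draw)

where each replicate draws exactly one gene copy ("chromosome") per
sampling unit on each side — sampling units are whole populations or
breeds for the colonization and domestication comparisons, and single
individuals for the breed-formation comparison — pools the drawn copies
per locus, computes unbiased expected heterozygosity
``N/(N-1) * (1 - sum p^2)`` per locus, and averages across loci before
taking the ratio.  Resampling equalises the weight of unequal-sized
units and dampens the effect of relatedness and inbreeding within them.

Replicates are independent; the point estimate is the replicate mean and
the confidence interval the 2.5/97.5 percentile band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeDataset

__all__ = [
    "SideSpec",
    "ResamplingScheme",
    "LossEstimate",
    "colonization_scheme",
    "domestication_scheme",
    "breed_formation_scheme",
    "resample_once",
    "estimate_loss",
    "per_breed_losses",
]


@dataclass(frozen=True)
class SideSpec:
    """One side of a comparison: which units, and the draw granularity.

    ``mode='per_unit'`` draws one gene copy uniformly from all
    non-missing copies of each listed unit; ``mode='per_individual'``
    draws one copy from each individual belonging to the listed units
    (individuals untyped at a locus are skipped for that locus).
    """

    mode: str
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("per_unit", "per_individual"):
            raise ValueError(f"unknown side mode {self.mode!r}")
        if not self.units:
            raise ValueError("side has no units")


@dataclass(frozen=True)
class ResamplingScheme:
    name: str
    derived: SideSpec
    source: SideSpec


@dataclass
class LossEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_replicates: int
    per_replicate: np.ndarray = field(repr=False)
    n_discarded: int = 0


# ---------------------------------------------------------------------
# built-in schemes, expressed against the group/unit hierarchy


def _units_of_group(dataset: GenotypeDataset, group: str) -> tuple[str, ...]:
    units = tuple(
        dict.fromkeys(i.unit for i in dataset.individuals if i.group == group)
    )
    if not units:
        raise ValueError(f"dataset has no units in group {group!r}")
    return units


def colonization_scheme(dataset: GenotypeDataset) -> ResamplingScheme:
    """One copy per French locality vs one copy per Iberian locality."""
    return ResamplingScheme(
        "colonization",
        derived=SideSpec("per_unit", _units_of_group(dataset, "wild_france")),
        source=SideSpec("per_unit", _units_of_group(dataset, "wild_iberia")),
    )


def domestication_scheme(dataset: GenotypeDataset) -> ResamplingScheme:
    """One copy per breed vs one copy per French locality."""
    return ResamplingScheme(
        "domestication",
        derived=SideSpec("per_unit", _units_of_group(dataset, "domestic")),
        source=SideSpec("per_unit", _units_of_group(dataset, "wild_france")),
    )


def breed_formation_scheme(dataset: GenotypeDataset, breed: str) -> ResamplingScheme:
    """One copy per individual of the breed vs one per domestic individual."""
    domestic = _units_of_group(dataset, "domestic")
    if breed not in domestic:
        raise KeyError(f"{breed!r} is not a domestic unit")
    return ResamplingScheme(
        f"breed_formation:{breed}",
        derived=SideSpec("per_individual", (breed,)),
        source=SideSpec("per_individual", domestic),
    )


# ---------------------------------------------------------------------
# the resampler


def _side_pools(
    dataset: GenotypeDataset, side: SideSpec
) -> list[list[np.ndarray]]:
    """Per locus, the list of gene-copy pools (one pool per sampling unit)."""
    unit_of = {}
    for i, ind in enumerate(dataset.individuals):
        unit_of.setdefault(ind.unit, []).append(i)
    for u in side.units:
        if u not in unit_of:
            raise KeyError(f"unknown unit {u!r}")
    pools: list[list[np.ndarray]] = []
    for j in range(dataset.n_loci):
        locus_pools = []
        if side.mode == "per_unit":
            for u in side.units:
                calls = dataset.calls[unit_of[u], j, :]
                copies = calls[(calls != MISSING).all(axis=1)].ravel()
                locus_pools.append(copies)
        else:
            for u in side.units:
                for i in unit_of[u]:
                    a, b = dataset.calls[i, j]
                    if a != MISSING and b != MISSING:
                        locus_pools.append(np.array([a, b]))
        pools.append(locus_pools)
    return pools


def _draw_he(
    pools: list[list[np.ndarray]],
    rng: np.random.Generator,
    n_reps: int,
    strict: bool,
) -> np.ndarray:
    """Unbiased He per (locus, replicate); NaN where a locus is undrawable.

    ``strict`` marks the per-unit behaviour: a unit with an empty pool
    invalidates the locus.  In per-individual mode untyped individuals
    were already skipped when the pools were built.
    """
    n_loci = len(pools)
    he = np.full((n_loci, n_reps), np.nan)
    for j, locus_pools in enumerate(pools):
        locus_pools = [p for p in locus_pools if len(p) or strict]
        if any(len(p) == 0 for p in locus_pools) or len(locus_pools) < 2:
            continue
        n_units = len(locus_pools)
        draws = np.empty((n_reps, n_units), dtype=np.int64)
        for k, pool in enumerate(locus_pools):
            draws[:, k] = pool[rng.integers(0, len(pool), size=n_reps)]
        # factorise alleles, then per-replicate counts via one bincount
        _, codes = np.unique(draws, return_inverse=True)
        codes = codes.reshape(draws.shape)
        n_states = codes.max() + 1
        flat = codes + n_states * np.arange(n_reps)[:, None]
        counts = np.bincount(flat.ravel(), minlength=n_reps * n_states)
        counts = counts.reshape(n_reps, n_states)
        sum_sq = (counts.astype(float) ** 2).sum(axis=1)
        he[j] = (n_units / (n_units - 1)) * (1.0 - sum_sq / n_units**2)
    return he


def resample_once(
    dataset: GenotypeDataset, scheme: ResamplingScheme, rng: np.random.Generator
) -> tuple[float, float]:
    """One replicate: (He_derived, He_source), each a mean across loci."""
    he_d = _draw_he(_side_pools(dataset, scheme.derived), rng, 1,
                    scheme.derived.mode == "per_unit")
    he_s = _draw_he(_side_pools(dataset, scheme.source), rng, 1,
                    scheme.source.mode == "per_unit")
    ok = np.isfinite(he_d[:, 0]) & np.isfinite(he_s[:, 0])
    if not ok.any():
        raise ValueError("no locus drawable on both sides")
    return float(he_d[ok, 0].mean()), float(he_s[ok, 0].mean())


def estimate_loss(
    dataset: GenotypeDataset,
    scheme: ResamplingScheme,
    n_replicates: int = 1000,
    seed: int = 0,
) -> LossEstimate:
    """Replicate the draw ``n_replicates`` times and summarise the loss.

    Loci where either side is undrawable are dropped from both sides
    (keeping numerator and denominator comparable).  Replicates with
    zero source-side He are discarded and counted.
    """
    rng = np.random.default_rng(seed)
    he_d = _draw_he(_side_pools(dataset, scheme.derived), rng, n_replicates,
                    scheme.derived.mode == "per_unit")
    he_s = _draw_he(_side_pools(dataset, scheme.source), rng, n_replicates,
                    scheme.source.mode == "per_unit")
    ok_loci = np.isfinite(he_d).all(axis=1) & np.isfinite(he_s).all(axis=1)
    if not ok_loci.any():
        raise ValueError("no locus drawable on both sides")
    mean_d = he_d[ok_loci].mean(axis=0)
    mean_s = he_s[ok_loci].mean(axis=0)
    keep = mean_s > 0
    losses = 1.0 - mean_d[keep] / mean_s[keep]
    if losses.size == 0:
        raise ValueError("all replicates had zero source-side He")
    lo, hi = np.percentile(losses, [2.5, 97.5])
    return LossEstimate(
        point=float(losses.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=n_replicates,
        per_replicate=losses,
        n_discarded=int((~keep).sum()),
    )


def per_breed_losses(
    dataset: GenotypeDataset, n_replicates: int = 1000, seed: int = 0
) -> dict[str, LossEstimate]:
    """Breed-formation loss for every domestic unit vs the pooled domestic
    sample, each with its own seeded replicate stream."""
    breeds = _units_of_group(dataset, "domestic")
    seeds = np.random.SeedSequence(seed).spawn(len(breeds))
    return {
        breed: estimate_loss(
            dataset,
            breed_formation_scheme(dataset, breed),
            n_replicates=n_replicates,
            seed=int(s.generate_state(1)[0] % (2**31)),
        )
        for breed, s in zip(breeds, seeds)
    }
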