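"""Core data model for multilocus codominant microsatellite genotypes.

A :class:`GenotypeDataset` holds diploid allele calls (integer fragment
sizes) for a set of individuals typed at a set of loci, together with a
two-level sampling hierarchy: every individual belongs to one of three
*groups* (wild Iberia, wild France, domestic) and to one *unit* within
that group (a wild sampling locality or a domestic breed), optionally
refined by a *subunit* (strain or colour morph).

Allele calls are stored as an ``(n_individuals, n_loci, 2)`` integer
array; 0 is the missing sentinel.  A genotype is either two valid allele
codes or fully missing — half-calls are normalised to missing during
validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GROUPS",
    "Locus",
    "Individual",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "allele_frequencies",
    "ValidationError",
]

#: The three top-level sampling groups, in wild-to-domestic order.
GROUPS = ("wild_iberia", "wild_france", "domestic")

MISSING = 0


class ValidationError(ValueError):
    """A dataset violates one of its structural invariants."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    Parameters
    ----------
    name:
        Unique locus identifier.
    chromosome_class:
        ``"autosomal"`` or ``"x_linked"``.  Only used when hemizygous
        male coding is requested; by default all individuals are treated
        as diploid at all loci.
    motif_length:
        Repeat-motif length in base pairs (informational; dinucleotide
        loci have ``motif_length=2``).
    """

    name: str
    chromosome_class: str = "autosomal"
    motif_length: int = 2

    def __post_init__(self) -> None:
        if self.chromosome_class not in ("autosomal", "x_linked"):
            raise ValidationError(
                f"locus {self.name!r}: unknown chromosome_class "
                f"{self.chromosome_class!r}"
            )
        if self.motif_length < 1:
            raise ValidationError(f"locus {self.name!r}: motif_length must be >= 1")


@dataclass(frozen=True)
class Individual:
    """A sampled diploid individual with its hierarchy labels."""

    id: str
    group: str
    unit: str
    subunit: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"individual {self.id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.sex is not None and self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"individual {self.id!r}: bad sex {self.sex!r}")


class GenotypeDataset:
    """Validated container of diploid multilocus genotypes.

    Parameters
    ----------
    loci:
        Ordered loci; names must be unique.
    individuals:
        Ordered individuals; ids must be unique and each unit label must
        belong to exactly one group.
    calls:
        Integer array of shape ``(n_individuals, n_loci, 2)``; 0 encodes
        a missing allele.  Genotypes with exactly one missing allele are
        normalised to fully missing (a warning reports the count).
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        individuals: Sequence[Individual],
        calls: np.ndarray,
    ) -> None:
        self.loci = list(loci)
        self.individuals = list(individuals)
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        self.calls = calls
        self.load_report: dict = {}
        self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate locus names")
        if not self.loci:
            raise ValidationError("dataset must contain at least one locus")
        if not self.individuals:
            raise ValidationError("dataset must contain at least one individual")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate individual ids: {dup}")
        unit_group: dict[str, str] = {}
        for ind in self.individuals:
            prev = unit_group.setdefault(ind.unit, ind.group)
            if prev != ind.group:
                raise ValidationError(
                    f"unit {ind.unit!r} appears in groups {prev!r} and {ind.group!r}"
                )
        if np.any(self.calls < 0):
            raise ValidationError("allele codes must be non-negative integers")
        # normalise half-calls to fully missing
        half = (self.calls == MISSING).sum(axis=2) == 1
        n_half = int(half.sum())
        if n_half:
            warnings.warn(
                f"{n_half} half-missing genotype(s) normalised to fully missing",
                stacklevel=3,
            )
            self.calls[half] = MISSING
        self.load_report.setdefault("half_calls_normalised", n_half)
        typed = (self.calls != MISSING).all(axis=2)
        empty = ~typed.any(axis=0)
        if np.any(empty):
            bad = [self.loci[j].name for j in np.flatnonzero(empty)]
            raise ValidationError(f"loci with no non-missing calls: {bad}")

    # -- basic accessors ----------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)`` mask of non-missing genotypes."""
        return (self.calls != MISSING).all(axis=2)

    def missing_per_locus(self) -> dict[str, int]:
        miss = (~self.typed_mask()).sum(axis=0)
        return {loc.name: int(m) for loc, m in zip(self.loci, miss)}

    # -- hierarchy ----------------------------------------------------

    def label_of(self, ind: Individual, level: str) -> str:
        if level == "pooled":
            return "pooled"
        if level == "group":
            return ind.group
        if level == "unit":
            return ind.unit
        if level == "subunit":
            return ind.subunit if ind.subunit is not None else ind.unit
        raise ValueError(f"unknown level {level!r}")

    def partition(self, level: str) -> dict[str, np.ndarray]:
        """Map each label at *level* to the indices of its individuals.

        Labels preserve first-appearance order.
        """
        out: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individuals):
            out.setdefault(self.label_of(ind, level), []).append(i)
        return {k: np.asarray(v, dtype=np.intp) for k, v in out.items()}

    def units(self, level: str = "unit") -> list[str]:
        return list(self.partition(level))

    def subset(self, indices: Iterable[int] | None = None, *,
               units: Iterable[str] | None = None,
               groups: Iterable[str] | None = None) -> "GenotypeDataset":
        """Return a new dataset restricted to the given individuals."""
        if indices is None:
            keep_units = set(units) if units is not None else None
            keep_groups = set(groups) if groups is not None else None
            indices = [
                i for i, ind in enumerate(self.individuals)
                if (keep_units is None or ind.unit in keep_units)
                and (keep_groups is None or ind.group in keep_groups)
            ]
        idx = np.asarray(list(indices), dtype=np.intp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return GenotypeDataset(
                self.loci, [self.individuals[i] for i in idx], self.calls[idx].copy()
            )

    def drop_loci(self, names: Iterable[str]) -> "GenotypeDataset":
        drop = set(names)
        keep = [j for j, loc in enumerate(self.loci) if loc.name not in drop]
        return GenotypeDataset(
            [self.loci[j] for j in keep],
            self.individuals,
            self.calls[:, keep, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeDataset: {self.n_individuals} individuals x "
            f"{self.n_loci} loci, {len(self.units())} units>"
        )


@dataclass
class AlleleFrequencyTable:
    """Per-(unit, locus) allele frequencies and gene-copy counts.

    ``counts[label][locus]`` maps allele code -> gene-copy count; the
    frequency of allele *a* is its count divided by :meth:`gene_copies`.
    A (label, locus) cell with zero non-missing gene copies is flagged
    absent (missing from the mapping) rather than zero-filled.
    """

    level: str
    labels: list[str]
    locus_names: list[str]
    counts: dict[str, dict[str, dict[int, int]]] = field(repr=False)

    def gene_copies(self, label: str, locus: str) -> int:
        return sum(self.counts[label].get(locus, {}).values())

    def has_data(self, label: str, locus: str) -> bool:
        return locus in self.counts[label]

    def frequencies(self, label: str, locus: str) -> dict[int, float]:
        cell = self.counts[label].get(locus)
        if not cell:
            raise KeyError(f"no data for ({label!r}, {locus!r})")
        n = sum(cell.values())
        return {a: c / n for a, c in cell.items()}

    def allele_counts(self, label: str, locus: str) -> dict[int, int]:
        return dict(self.counts[label].get(locus, {}))

    def alleles(self, locus: str) -> list[int]:
        """All allele codes observed at *locus* across labels, sorted."""
        seen: set[int] = set()
        for label in self.labels:
            seen.update(self.counts[label].get(locus, {}))
        return sorted(seen)


def allele_frequencies(
    dataset: GenotypeDataset,
    level: str = "unit",
    *,
    hemizygous_males: bool = False,
) -> AlleleFrequencyTable:
    """Tally allele frequencies per (label, locus) from non-missing calls.

    With ``hemizygous_males=True``, males contribute a single gene copy at
    X-linked loci (their two recorded calls must agree; the first is
    counted).  The default treats every individual as diploid everywhere.
    """
    parts = dataset.partition(level)
    x_linked = np.array(
        [loc.chromosome_class == "x_linked" for loc in dataset.loci]
    )
    counts: dict[str, dict[str, dict[int, int]]] = {}
    for label, idx in parts.items():
        per_locus: dict[str, dict[int, int]] = {}
        for j, loc in enumerate(dataset.loci):
            tally: dict[int, int] = {}
            for i in idx:
                a, b = dataset.calls[i, j]
                if a == MISSING or b == MISSING:
                    continue
                ind = dataset.individuals[i]
                if hemizygous_males and x_linked[j] and ind.sex == "male":
                    tally[a] = tally.get(a, 0) + 1
                else:
                    tally[a] = tally.get(a, 0) + 1
                    tally[b] = tally.get(b, 0) + 1
            if tally:
                per_locus[loc.name] = tally
        counts[label] = per_locus
    return AlleleFrequencyTable(
        level=level,
        labels=list(parts),
        locus_names=dataset.locus_names,
        counts=counts,
    )
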