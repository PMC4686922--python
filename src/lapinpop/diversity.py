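"""Genetic-diversity summaries: He, Ho, FIS, and rarefied allelic richness.

Conventions
-----------
* Expected heterozygosity uses the plain frequency form ``1 - sum(p^2)``
  by default (the GenAlEx convention for summary tables); the unbiased
  small-sample form ``N/(N-1) * (1 - sum(p^2))`` is available via
  ``unbiased=True`` and is the form used inside the diversity-loss
  resampler, where pooled draws are tiny.
* Allelic richness Ar(g) and private allelic richness PAr(g) follow the
  hypergeometric rarefaction of Kalinowski: the expected number of
  distinct (respectively, private) alleles in a random draw of *g* gene
  copies.  The default rarefaction size is g = 8 gene copies.
* Per-locus statistics are averaged with equal locus weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import (
    MISSING,
    GenotypeDataset,
    allele_frequencies,
)

__all__ = [
    "expected_heterozygosity",
    "allelic_richness",
    "private_allelic_richness",
    "fis",
    "DiversitySummary",
    "summarize_diversity",
]


def expected_heterozygosity(
    freqs, *, n_copies: int | None = None, unbiased: bool = False
) -> float:
    """He = 1 - sum(p_i^2) from an allele-frequency vector or mapping.

    With ``unbiased=True`` the estimate is multiplied by ``N/(N-1)``
    where ``N`` is the gene-copy count (``n_copies``, required then).
    """
    p = np.asarray(
        list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float
    )
    if p.size == 0:
        raise ValueError("empty frequency vector: He undefined")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    he = 1.0 - float((p**2).sum())
    if unbiased:
        if n_copies is None:
            raise ValueError("unbiased He requires n_copies")
        if n_copies < 2:
            raise ValueError("unbiased He requires at least 2 gene copies")
        he *= n_copies / (n_copies - 1)
    return he


def _log_absent(n_rest: np.ndarray, n_total: int, g: int) -> np.ndarray:
    """log of C(n_rest, g) / C(n_total, g): chance a draw of g misses an allele."""
    n_rest = np.asarray(n_rest, dtype=float)
    out = np.full(n_rest.shape, -np.inf)
    ok = n_rest >= g
    out[ok] = (
        gammaln(n_rest[ok] + 1)
        - gammaln(n_rest[ok] - g + 1)
        - gammaln(n_total + 1)
        + gammaln(n_total - g + 1)
    )
    return out


def allelic_richness(allele_counts: dict[int, int], g: int) -> float:
    """Rarefied allelic richness: expected distinct alleles in g gene copies."""
    if g < 1:
        raise ValueError("g must be >= 1")
    counts = np.asarray(list(allele_counts.values()), dtype=np.int64)
    n = int(counts.sum())
    if g > n:
        raise ValueError(
            f"rarefaction size g={g} exceeds the {n} available gene copies; "
            "drop this unit from rarefied statistics"
        )
    p_absent = np.exp(_log_absent(n - counts, n, g))
    return float((1.0 - p_absent).sum())


def private_allelic_richness(
    allele_counts_by_unit: dict[str, dict[int, int]], focal: str, g: int
) -> float:
    """Rarefied private allelic richness of *focal* against all other units.

    For each allele, the probability it appears in a g-copy draw from the
    focal unit times the probability it is absent from independent g-copy
    draws of every other unit.  With a single-unit comparison set this
    degenerates to Ar(g) (every allele is trivially private).
    """
    if focal not in allele_counts_by_unit:
        raise KeyError(f"focal unit {focal!r} not in comparison set")
    others = [u for u in allele_counts_by_unit if u != focal]
    focal_counts = allele_counts_by_unit[focal]
    n_f = sum(focal_counts.values())
    if g > n_f:
        raise ValueError(f"g={g} exceeds focal gene copies ({n_f})")
    totals = {u: sum(c.values()) for u, c in allele_counts_by_unit.items()}
    for u in others:
        if g > totals[u]:
            raise ValueError(f"g={g} exceeds gene copies of unit {u!r}")
    total = 0.0
    for allele, cnt in focal_counts.items():
        log_in_focal = _log_absent(np.array([n_f - cnt]), n_f, g)[0]
        p_in = 1.0 - np.exp(log_in_focal)
        log_absent_others = 0.0
        for u in others:
            c = allele_counts_by_unit[u].get(allele, 0)
            log_absent_others += _log_absent(
                np.array([totals[u] - c]), totals[u], g
            )[0]
        total += p_in * np.exp(log_absent_others)
    return float(total)


def _per_locus_ho_he(
    dataset: GenotypeDataset, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed/expected heterozygosity and gene-copy counts per locus."""
    calls = dataset.calls[idx]
    typed = (calls != MISSING).all(axis=2)
    n_loci = dataset.n_loci
    ho = np.full(n_loci, np.nan)
    he = np.full(n_loci, np.nan)
    ncop = np.zeros(n_loci, dtype=int)
    for j in range(n_loci):
        sub = calls[typed[:, j], j, :]
        if len(sub) == 0:
            continue
        ncop[j] = 2 * len(sub)
        ho[j] = float(np.mean(sub[:, 0] != sub[:, 1]))
        _, counts = np.unique(sub.ravel(), return_counts=True)
        p = counts / counts.sum()
        he[j] = 1.0 - float((p**2).sum())
    return ho, he, ncop


def fis(dataset: GenotypeDataset, unit: str, level: str = "unit") -> float:
    """Mean per-locus fixation index F = 1 - Ho/He for one unit.

    Loci that are monomorphic in the unit (He = 0) are excluded; NaN is
    returned when every locus is monomorphic.
    """
    parts = dataset.partition(level)
    if unit not in parts:
        raise KeyError(f"unknown {level} label {unit!r}")
    ho, he, _ = _per_locus_ho_he(dataset, parts[unit])
    ok = np.isfinite(he) & (he > 0)
    if not ok.any():
        return float("nan")
    return float(np.mean(1.0 - ho[ok] / he[ok]))


@dataclass
class DiversitySummary:
    """Per-label diversity table plus per-locus breakdowns.

    ``table`` has one row per label with columns
    ``n, Na, Ar, PAr, He, Ho, FIS``; rarefied columns are NaN where a
    label lacks enough gene copies.  ``mean`` / ``se`` summarise the
    labels in ``mean_labels`` (domestic units when present, else all).
    """

    level: str
    g: int
    table: pd.DataFrame
    per_locus_he: pd.DataFrame
    per_locus_ar: pd.DataFrame
    mean_labels: list[str]

    @property
    def mean(self) -> pd.Series:
        return self.table.loc[self.mean_labels].mean(numeric_only=True)

    @property
    def se(self) -> pd.Series:
        sub = self.table.loc[self.mean_labels]
        return sub.std(numeric_only=True, ddof=1) / np.sqrt(len(sub))


def summarize_diversity(
    dataset: GenotypeDataset, level: str = "unit", g: int = 8
) -> DiversitySummary:
    """Table-style diversity summary at a hierarchy level.

    For each label: sample size n, mean observed alleles per locus (Na),
    rarefied allelic richness Ar(g) and private allelic richness PAr(g)
    (means over loci with at least g gene copies in every label), He, Ho
    and FIS.  The mean/SE summary is taken over domestic labels when the
    dataset contains any (the breed-table convention), else over all.
    """
    parts = dataset.partition(level)
    freq = allele_frequencies(dataset, level)
    labels = list(parts)
    locus_names = dataset.locus_names

    rows = []
    he_rows, ar_rows = {}, {}
    for label, idx in parts.items():
        ho_l, he_l, ncop = _per_locus_ho_he(dataset, idx)
        has = np.isfinite(he_l)
        na_l = np.full(len(locus_names), np.nan)
        ar_l = np.full(len(locus_names), np.nan)
        par_l = np.full(len(locus_names), np.nan)
        for j, loc in enumerate(locus_names):
            if not freq.has_data(label, loc):
                continue
            cnts = freq.allele_counts(label, loc)
            na_l[j] = len(cnts)
            if ncop[j] >= g:
                ar_l[j] = allelic_richness(cnts, g)
                by_unit = {
                    u: freq.allele_counts(u, loc)
                    for u in labels
                    if freq.gene_copies(u, loc) >= g
                }
                if label in by_unit:
                    par_l[j] = private_allelic_richness(by_unit, label, g)
        ok_f = has & (he_l > 0)
        rows.append(
            {
                "label": label,
                "n": len(idx),
                "Na": np.nanmean(na_l) if has.any() else np.nan,
                "Ar": np.nanmean(ar_l) if np.isfinite(ar_l).any() else np.nan,
                "PAr": np.nanmean(par_l) if np.isfinite(par_l).any() else np.nan,
                "He": np.nanmean(he_l) if has.any() else np.nan,
                "Ho": np.nanmean(ho_l) if has.any() else np.nan,
                "FIS": (
                    float(np.mean(1 - ho_l[ok_f] / he_l[ok_f]))
                    if ok_f.any()
                    else np.nan
                ),
            }
        )
        he_rows[label] = he_l
        ar_rows[label] = ar_l
    table = pd.DataFrame(rows).set_index("label")
    group_of = {
        dataset.label_of(ind, level): ind.group for ind in dataset.individuals
    }
    domestic = [lb for lb in labels if group_of[lb] == "domestic"]
    return DiversitySummary(
        level=level,
        g=g,
        table=table,
        per_locus_he=pd.DataFrame(he_rows, index=locus_names).T,
        per_locus_ar=pd.DataFrame(ar_rows, index=locus_names).T,
        mean_labels=domestic if domestic else labels,
    )
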