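"""Chord and allele-sharing genetic distances, with PHYLIP matrix I/O.

The chord distance (Cavalli-Sforza & Edwards) is pinned to the
(2/pi)-normalised single-locus form

    d_l = (2/pi) * sqrt(2 * (1 - sum_i sqrt(p_i * q_i)))

combined across loci as the root-mean-square sqrt(mean_l d_l^2), so a
single locus with disjoint allele sets contributes (2/pi)*sqrt(2)
~ 0.9003.  Published software variants disagree on the normalisation;
this module documents and tests exactly this form.

Individuals are treated as two-gene-copy populations (allele
frequencies 0, 0.5 or 1) when chord distances between individuals are
requested.

The allele-sharing distance between two diploid genotypes counts the
multiset intersection of their allele pairs (AB vs AC shares 1, AB vs
AB shares 2, AA vs AB shares 1):  DAS = 1 - mean_l(shared_l / 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotypes import MISSING, AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "DistanceMatrix",
    "chord_distance_matrix",
    "allele_sharing_distance_matrix",
    "read_phylip_distances",
    "write_phylip_distances",
]

CHORD_MAX = (2.0 / np.pi) * np.sqrt(2.0)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric_name: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def has_absent(self) -> bool:
        return bool(np.isnan(self.values).any())


# ---------------------------------------------------------------------


def _sqrt_freq_blocks(
    labels: list[str],
    per_locus_freqs: list[dict[str, dict[int, float]]],
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-locus sqrt-frequency matrices and a (n_entities, n_loci) data mask."""
    n = len(labels)
    blocks = []
    mask = np.zeros((n, len(per_locus_freqs)), dtype=bool)
    for j, freqs in enumerate(per_locus_freqs):
        alleles = sorted({a for f in freqs.values() for a in f})
        a_index = {a: k for k, a in enumerate(alleles)}
        s = np.zeros((n, len(alleles)))
        for i, lb in enumerate(labels):
            f = freqs.get(lb)
            if f:
                mask[i, j] = True
                for a, p in f.items():
                    s[i, a_index[a]] = np.sqrt(p)
        blocks.append(s)
    return blocks, mask


def _chord_from_blocks(
    labels: list[str], blocks: list[np.ndarray], mask: np.ndarray
) -> DistanceMatrix:
    n = len(labels)
    d2_sum = np.zeros((n, n))
    shared = np.zeros((n, n))
    for j, s in enumerate(blocks):
        m = mask[:, j].astype(float)
        cos = s @ s.T
        d2 = (4.0 / np.pi**2) * 2.0 * np.clip(1.0 - cos, 0.0, None)
        pair_ok = np.outer(m, m)
        d2_sum += d2 * pair_ok
        shared += pair_ok
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.sqrt(d2_sum / shared)
    values[shared == 0] = np.nan
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values, "chord")


def chord_distance_matrix(
    source: AlleleFrequencyTable | GenotypeDataset,
) -> DistanceMatrix:
    """Chord distances among units (frequency table) or individuals (dataset).

    Entity pairs sharing no typed locus get a NaN ("absent") entry.
    """
    if isinstance(source, AlleleFrequencyTable):
        labels = list(source.labels)
        per_locus = []
        for loc in source.locus_names:
            per_locus.append(
                {
                    lb: source.frequencies(lb, loc)
                    for lb in labels
                    if source.has_data(lb, loc)
                }
            )
    else:
        labels = [ind.id for ind in source.individuals]
        per_locus = []
        for j in range(source.n_loci):
            freqs: dict[str, dict[int, float]] = {}
            for i, lb in enumerate(labels):
                a, b = source.calls[i, j]
                if a == MISSING or b == MISSING:
                    continue
                freqs[lb] = {int(a): 1.0} if a == b else {int(a): 0.5, int(b): 0.5}
            per_locus.append(freqs)
    blocks, mask = _sqrt_freq_blocks(labels, per_locus)
    return _chord_from_blocks(labels, blocks, mask)


def allele_sharing_distance_matrix(dataset: GenotypeDataset) -> DistanceMatrix:
    """Allele-sharing distance DAS between all pairs of individuals."""
    labels = [ind.id for ind in dataset.individuals]
    n = dataset.n_individuals
    dist_sum = np.zeros((n, n))
    shared_loci = np.zeros((n, n))
    for j in range(dataset.n_loci):
        calls = dataset.calls[:, j, :]
        typed = (calls != MISSING).all(axis=1)
        alleles = np.unique(calls[typed].ravel())
        a_index = {a: k for k, a in enumerate(alleles)}
        cnt = np.zeros((n, len(alleles)))
        for i in np.flatnonzero(typed):
            cnt[i, a_index[calls[i, 0]]] += 1
            cnt[i, a_index[calls[i, 1]]] += 1
        # multiset intersection = 2 - L1/2; per-locus distance = L1/4
        l1 = np.abs(cnt[:, None, :] - cnt[None, :, :]).sum(axis=2)
        ok = np.outer(typed, typed)
        dist_sum += (l1 / 4.0) * ok
        shared_loci += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        values = dist_sum / shared_loci
    values[shared_loci == 0] = np.nan
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values, "allele_sharing")


# ---------------------------------------------------------------------
# PHYLIP interchange


def write_phylip_distances(
    dm: DistanceMatrix, path: str | Path, lower_triangle: bool = False
) -> None:
    lines = [f"    {len(dm.labels)}"]
    for i, lb in enumerate(dm.labels):
        row = dm.values[i, :i] if lower_triangle else dm.values[i]
        lines.append(f"{lb:<12s}" + "  ".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip_distances(path: str | Path) -> DistanceMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if all(len(r) == n for r in rows):
        values = np.asarray(rows)
    else:  # lower triangle
        values = np.zeros((n, n))
        for i, r in enumerate(rows):
            if len(r) != i:
                raise ValueError(f"{path}: row {i + 1} has {len(r)} entries")
            values[i, :i] = r
            values[:i, i] = r
    return DistanceMatrix(labels, values, "custom")
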