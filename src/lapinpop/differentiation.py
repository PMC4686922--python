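"""Population differentiation: Weir–Cockerham FST, AMOVA, HW screening.

FST uses the Weir & Cockerham (1984) variance-components estimator
θ, with loci and alleles combined as a ratio of sums Σa / Σ(a+b+c).
Negative estimates are reported as computed, not truncated.

AMOVA partitions allelic variance at three nested levels — among units,
among individuals within units, and within individuals — using the
number-of-different-alleles distance between gene copies (the FST-like
metric).  Components are computed per locus (individuals untyped at a
locus are dropped locus-wise) and summed over loci.

Hardy–Weinberg deviation is screened per (unit, locus) with a chi-square
goodness-of-fit over all genotype categories, df = k(k-1)/2 for k
observed alleles, Bonferroni-corrected within each unit across its
tested loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .genotypes import MISSING, GenotypeDataset

__all__ = [
    "FstMatrix",
    "AmovaResult",
    "HWScreenResult",
    "weir_cockerham_theta",
    "pairwise_fst",
    "amova_three_level",
    "hw_chisq_screen",
]


# ---------------------------------------------------------------------
# Weir & Cockerham theta


def _wc_sums(calls: np.ndarray, unit_idx: list[np.ndarray]) -> tuple[float, float]:
    """Σa and Σ(a+b+c) over loci and alleles for the given unit partition.

    ``calls`` is the (n, L, 2) call array; ``unit_idx`` the per-unit
    individual indices.  Loci informative in fewer than two units are
    skipped.
    """
    n_loci = calls.shape[1]
    sum_a = 0.0
    sum_abc = 0.0
    for j in range(n_loci):
        pops = []
        for idx in unit_idx:
            sub = calls[idx, j, :]
            sub = sub[(sub != MISSING).all(axis=1)]
            if len(sub) >= 1:
                pops.append(sub)
        r = len(pops)
        if r < 2:
            continue
        n_i = np.array([len(p) for p in pops], dtype=float)
        alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
        if len(alleles) < 2:
            continue
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        # per-allele frequencies and heterozygote frequencies per pop
        p_mat = np.zeros((r, len(alleles)))
        h_mat = np.zeros((r, len(alleles)))
        for i, sub in enumerate(pops):
            for k, al in enumerate(alleles):
                p_mat[i, k] = np.mean(sub == al)
                h_mat[i, k] = np.mean(
                    (sub[:, 0] == al) ^ (sub[:, 1] == al)
                )
        pbar = (n_i[:, None] * p_mat).sum(axis=0) / (r * nbar)
        s2 = ((n_i[:, None] * (p_mat - pbar) ** 2).sum(axis=0)) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * h_mat).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / n_c * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        sum_a += a.sum()
        sum_abc += (a + b + c).sum()
    return sum_a, sum_abc


def weir_cockerham_theta(
    dataset: GenotypeDataset, units: list[str] | None = None, level: str = "unit"
) -> float:
    """Multi-locus, multi-allelic θ over the given units (all by default)."""
    parts = dataset.partition(level)
    if units is not None:
        parts = {u: parts[u] for u in units}
    if len(parts) < 2:
        raise ValueError("theta requires at least two units")
    sa, sabc = _wc_sums(dataset.calls, list(parts.values()))
    if sabc == 0.0:
        return float("nan")
    return sa / sabc


@dataclass
class FstMatrix:
    labels: list[str]
    theta: np.ndarray
    p_values: np.ndarray | None
    global_theta: float
    global_p: float | None
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.labels, columns=self.labels)

    def pair(self, a: str, b: str) -> float:
        return float(self.theta[self.labels.index(a), self.labels.index(b)])


def pairwise_fst(
    dataset: GenotypeDataset,
    level: str = "unit",
    n_permutations: int = 0,
    seed: int = 0,
) -> FstMatrix:
    """Pairwise and global θ with optional permutation p-values.

    Permutation p-values shuffle individuals between the pair (or among
    all units for the global test); ``p = (#perm >= obs + 1)/(P + 1)``.
    """
    rng = np.random.default_rng(seed)
    parts = dataset.partition(level)
    labels = list(parts)
    r = len(labels)
    if r < 2:
        raise ValueError("pairwise FST requires at least two units")
    theta = np.zeros((r, r))
    pvals = np.ones((r, r)) if n_permutations else None
    for i, k in combinations(range(r), 2):
        idx_pair = [parts[labels[i]], parts[labels[k]]]
        sa, sabc = _wc_sums(dataset.calls, idx_pair)
        t = sa / sabc if sabc else float("nan")
        theta[i, k] = theta[k, i] = t
        if n_permutations:
            pool = np.concatenate(idx_pair)
            n1 = len(idx_pair[0])
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pool)
                psa, psabc = _wc_sums(dataset.calls, [perm[:n1], perm[n1:]])
                if psabc and psa / psabc >= t:
                    hits += 1
            pvals[i, k] = pvals[k, i] = (hits + 1) / (n_permutations + 1)
    g_sa, g_sabc = _wc_sums(dataset.calls, list(parts.values()))
    global_theta = g_sa / g_sabc if g_sabc else float("nan")
    global_p = None
    if n_permutations:
        pool = np.concatenate(list(parts.values()))
        sizes = [len(v) for v in parts.values()]
        cuts = np.cumsum(sizes)[:-1]
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pool)
            groups = np.split(perm, cuts)
            psa, psabc = _wc_sums(dataset.calls, groups)
            if psabc and psa / psabc >= global_theta:
                hits += 1
        global_p = (hits + 1) / (n_permutations + 1)
    return FstMatrix(labels, theta, pvals, global_theta, global_p, n_permutations)


# ---------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """Three-level AMOVA table (genotypic, FST-like allelic distance)."""

    level: str
    df: dict[str, int]
    sum_of_squares: dict[str, float]
    variance_components: dict[str, float]
    percent_variation: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    LEVELS = ("among_units", "among_individuals_within_units", "within_individuals")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lv in self.LEVELS:
            rows.append(
                {
                    "source": lv,
                    "df": self.df[lv],
                    "sum_of_squares": self.sum_of_squares[lv],
                    "variance_component": self.variance_components[lv],
                    "percent_variation": self.percent_variation[lv],
                    "p_value": self.p_values.get(lv, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("source")


def _amova_components(
    calls: np.ndarray, unit_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (SSa, SSb, SSc) and (Va, Vb, Vc) for the unit partition."""
    n_loci = calls.shape[1]
    ss = np.zeros((n_loci, 3))
    var = np.zeros((n_loci, 3))
    for j in range(n_loci):
        pops = []
        for idx in unit_idx:
            sub = calls[idx, j, :]
            sub = sub[(sub != MISSING).all(axis=1)]
            if len(sub):
                pops.append(sub)
        r = len(pops)
        if r < 2:
            continue
        n_i = np.array([len(p) for p in pops], dtype=float)
        n_tot = n_i.sum()
        all_calls = np.concatenate(pops)
        # SS within a set of 2m gene copies with allele freqs p: m(1 - sum p^2)
        _, cnt = np.unique(all_calls.ravel(), return_counts=True)
        p_t = cnt / cnt.sum()
        ss_total = n_tot * (1 - (p_t**2).sum())
        ss_wu = 0.0
        for sub in pops:
            _, c = np.unique(sub.ravel(), return_counts=True)
            p = c / c.sum()
            ss_wu += len(sub) * (1 - (p**2).sum())
        ss_c = 0.5 * sum(int((sub[:, 0] != sub[:, 1]).sum()) for sub in pops)
        ss_a = ss_total - ss_wu
        ss_b = ss_wu - ss_c
        ss[j] = (ss_a, ss_b, ss_c)
        vc = ss_c / n_tot
        vb = (ss_b / (n_tot - r) - vc) / 2 if n_tot > r else 0.0
        n_c = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
        va = (ss_a / (r - 1) - vc - 2 * vb) / (2 * n_c)
        var[j] = (va, vb, vc)
    return ss, var


def amova_three_level(
    dataset: GenotypeDataset,
    level: str = "unit",
    n_permutations: int = 0,
    seed: int = 0,
) -> AmovaResult:
    """Nested AMOVA: among units / among individuals within / within individuals.

    Negative components are reported as computed.  Permutation p-values:
    individuals are shuffled among units for the among-units component;
    gene copies are shuffled among individuals within units for the two
    lower components.
    """
    rng = np.random.default_rng(seed)
    parts = dataset.partition(level)
    if len(parts) < 2:
        raise ValueError("three-level AMOVA requires at least two units")
    unit_idx = list(parts.values())
    ss, var = _amova_components(dataset.calls, unit_idx)
    ss_sum = ss.sum(axis=0)
    v_sum = var.sum(axis=0)
    total_v = v_sum.sum()
    n = dataset.n_individuals
    r = len(parts)
    keys = AmovaResult.LEVELS
    result = AmovaResult(
        level=level,
        df=dict(zip(keys, (r - 1, n - r, n))),
        sum_of_squares=dict(zip(keys, ss_sum)),
        variance_components=dict(zip(keys, v_sum)),
        percent_variation=dict(zip(keys, 100 * v_sum / total_v)),
        n_permutations=n_permutations,
    )
    if n_permutations:
        pool = np.concatenate(unit_idx)
        cuts = np.cumsum([len(v) for v in unit_idx])[:-1]
        hits_a = 0
        for _ in range(n_permutations):
            perm_groups = np.split(rng.permutation(pool), cuts)
            _, pv = _amova_components(dataset.calls, perm_groups)
            if pv.sum(axis=0)[0] >= v_sum[0]:
                hits_a += 1
        result.p_values["among_units"] = (hits_a + 1) / (n_permutations + 1)
        hits_b = hits_c = 0
        for _ in range(n_permutations):
            shuffled = dataset.calls.copy()
            for idx in unit_idx:
                for j in range(dataset.n_loci):
                    sub = shuffled[idx, j, :]
                    typed = (sub != MISSING).all(axis=1)
                    copies = sub[typed].ravel()
                    sub[typed] = rng.permutation(copies).reshape(-1, 2)
                    shuffled[idx, j, :] = sub
            _, pv = _amova_components(shuffled, unit_idx)
            pvs = pv.sum(axis=0)
            if pvs[1] >= v_sum[1]:
                hits_b += 1
            if pvs[2] <= v_sum[2]:  # excess within-individual homogeneity
                hits_c += 1
        result.p_values["among_individuals_within_units"] = (hits_b + 1) / (
            n_permutations + 1
        )
        result.p_values["within_individuals"] = (hits_c + 1) / (n_permutations + 1)
    return result


# ---------------------------------------------------------------------
# Hardy-Weinberg chi-square screen


@dataclass
class HWScreenResult:
    table: pd.DataFrame  # per (unit, locus): chi2, df, p, significant
    percent_deviating: pd.Series  # per unit
    alpha: float
    family: str  # 'within_unit' or 'global'


def hw_chisq_screen(
    dataset: GenotypeDataset,
    level: str = "unit",
    alpha: float = 0.05,
    family: str = "within_unit",
) -> HWScreenResult:
    """Chi-square HW goodness-of-fit per (unit, locus), Bonferroni-corrected.

    All genotype categories are kept (no pooling of rare classes; low
    expected counts make this screen conservative only in the chi-square
    approximation sense).  Monomorphic (unit, locus) cells are skipped
    and excluded from the per-unit denominator.
    """
    parts = dataset.partition(level)
    rows = []
    for label, idx in parts.items():
        for j, loc in enumerate(dataset.loci):
            sub = dataset.calls[idx, j, :]
            sub = sub[(sub != MISSING).all(axis=1)]
            if len(sub) == 0:
                continue
            alleles, cnt = np.unique(sub.ravel(), return_counts=True)
            k = len(alleles)
            if k < 2:
                continue
            p = cnt / cnt.sum()
            n = len(sub)
            a_index = {a: i for i, a in enumerate(alleles)}
            obs = np.zeros((k, k))
            for g1, g2 in sub:
                i1, i2 = sorted((a_index[g1], a_index[g2]))
                obs[i1, i2] += 1
            chi2 = 0.0
            for i1 in range(k):
                for i2 in range(i1, k):
                    e = n * (p[i1] ** 2 if i1 == i2 else 2 * p[i1] * p[i2])
                    chi2 += (obs[i1, i2] - e) ** 2 / e
            df = k * (k - 1) // 2
            rows.append(
                {
                    "unit": label,
                    "locus": loc.name,
                    "chi2": chi2,
                    "df": df,
                    "p_value": float(chi2_dist.sf(chi2, df)),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no polymorphic (unit, locus) cells to test")
    if family == "within_unit":
        m = table.groupby("unit")["locus"].transform("count")
    elif family == "global":
        m = len(table)
    else:
        raise ValueError(f"unknown Bonferroni family {family!r}")
    table["significant_after_bonferroni"] = table["p_value"] < alpha / m
    percent = (
        table.groupby("unit")["significant_after_bonferroni"].mean() * 100
    ).rename("percent_deviating")
    return HWScreenResult(table=table, percent_deviating=percent,
                          alpha=alpha, family=family)
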