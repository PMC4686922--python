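"""Population structure: assignment tests, DAPC, admixture Gibbs sampling,
cluster-number selection and run alignment.

* :func:`paetkau_assign` — frequency-based assignment: each individual
  goes to the candidate unit maximising the Hardy–Weinberg likelihood of
  its multilocus genotype under that unit's allele frequencies, with
  leave-one-out removal of the focal individual from its own unit and a
  small substitute frequency for alleles unobserved in a unit.
* :func:`dapc` — discriminant analysis of principal components:
  allele-count encoding, PCA retaining ~90% cumulative variance, then
  linear discriminants on the retained components.
* :func:`admixture_gibbs` — a Gibbs sampler for the admixture model:
  every gene copy carries a latent cluster of origin Z; cluster allele
  frequencies P and individual membership vectors Q get conjugate
  Dirichlet updates.  Returns the posterior-mean Q matrix and a
  log-likelihood summary used for selecting K.
* :func:`evanno_delta_k` — the second-difference statistic
  ``delta K = mean(|L(K+1) - 2 L(K) + L(K-1)|) / sd(L(K))`` over
  replicate runs.
* :func:`align_runs` — label-switching repair across replicate Q
  matrices (optimal column matching against a reference) plus the mean
  pairwise similarity coefficient C of the aligned runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import MISSING, GenotypeDataset, allele_frequencies

__all__ = [
    "AssignmentResult",
    "QMatrix",
    "KSelectionTable",
    "paetkau_assign",
    "dapc",
    "admixture_gibbs",
    "evanno_delta_k",
    "align_runs",
]


# ---------------------------------------------------------------------
# Paetkau frequency assignment


@dataclass
class AssignmentResult:
    log_likelihoods: pd.DataFrame  # individuals x candidate units (log10)
    assigned: pd.Series
    true_unit: pd.Series
    n_ties: int

    @property
    def correct(self) -> pd.Series:
        return self.assigned == self.true_unit

    @property
    def percent_correct(self) -> float:
        return 100.0 * float(self.correct.mean())

    @property
    def n_correct(self) -> int:
        return int(self.correct.sum())


def paetkau_assign(
    dataset: GenotypeDataset,
    level: str = "unit",
    leave_one_out: bool = True,
    zero_freq: float = 0.005,
) -> AssignmentResult:
    """Assign each individual to the unit maximising its HW genotype likelihood.

    Per locus the genotype probability is ``p^2`` (homozygote) or
    ``2 p q`` (heterozygote) from the unit's allele frequencies; the
    log10 products are summed over the individual's typed loci.  With
    ``leave_one_out`` the focal individual's own alleles are removed
    from its unit's counts before computing that unit's frequencies.
    Alleles absent from a unit are given frequency ``zero_freq``.
    Ties resolve to the lowest label in sorted order.
    """
    parts = dataset.partition(level)
    labels = list(parts)
    freq = allele_frequencies(dataset, level)
    n = dataset.n_individuals
    ll = np.zeros((n, len(labels)))
    own = {i: dataset.label_of(ind, level)
           for i, ind in enumerate(dataset.individuals)}
    for j, loc in enumerate(dataset.locus_names):
        counts = {lb: freq.allele_counts(lb, loc) for lb in labels}
        totals = {lb: sum(c.values()) for lb, c in counts.items()}
        for i in range(n):
            a, b = dataset.calls[i, j]
            if a == MISSING or b == MISSING:
                continue
            for k, lb in enumerate(labels):
                c, tot = counts[lb], totals[lb]
                if leave_one_out and own[i] == lb:
                    ca = c.get(a, 0) - 1
                    cb = c.get(b, 0) - (1 if a != b else 1)
                    if a == b:
                        ca = c.get(a, 0) - 2
                        cb = ca
                    tot_eff = tot - 2
                else:
                    ca, cb = c.get(a, 0), c.get(b, 0)
                    tot_eff = tot
                if tot_eff <= 0:
                    continue
                pa = ca / tot_eff if ca > 0 else zero_freq
                pb = cb / tot_eff if cb > 0 else zero_freq
                prob = pa * pa if a == b else 2 * pa * pb
                ll[i, k] += np.log10(prob)
    typed_any = dataset.typed_mask().any(axis=1)
    order = np.argsort(labels)
    best = np.full(n, -1)
    n_ties = 0
    for i in range(n):
        if not typed_any[i]:
            continue
        top = ll[i].max()
        cand = np.flatnonzero(np.isclose(ll[i], top, atol=1e-12))
        if len(cand) > 1:
            n_ties += 1
            cand = cand[np.argsort([labels[c] for c in cand])]
        best[i] = cand[0]
    ids = [ind.id for ind in dataset.individuals]
    assigned = pd.Series(
        [labels[b] if b >= 0 else None for b in best], index=ids, name="assigned"
    )
    true_unit = pd.Series([own[i] for i in range(n)], index=ids, name="unit")
    mask = assigned.notna()
    return AssignmentResult(
        log_likelihoods=pd.DataFrame(ll, index=ids, columns=labels),
        assigned=assigned[mask],
        true_unit=true_unit[mask],
        n_ties=n_ties,
    )


# ---------------------------------------------------------------------
# DAPC


def _allele_count_matrix(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """0/1/2 allele-count encoding; NaN where untyped.  Columns: (locus, allele)."""
    cols = []
    mats = []
    for j in range(dataset.n_loci):
        calls = dataset.calls[:, j, :]
        typed = (calls != MISSING).all(axis=1)
        alleles = np.unique(calls[typed].ravel())
        m = np.full((dataset.n_individuals, len(alleles)), np.nan)
        m[typed] = (
            (calls[typed, 0][:, None] == alleles).astype(float)
            + (calls[typed, 1][:, None] == alleles)
        )
        mats.append(m)
        cols.extend((dataset.locus_names[j], int(a)) for a in alleles)
    return np.hstack(mats), np.asarray(cols, dtype=object)


@dataclass
class DapcResult:
    memberships: pd.DataFrame  # individuals x units
    assigned: pd.Series
    true_unit: pd.Series
    coordinates: np.ndarray  # first discriminant axes
    n_components: int
    explained_variance: float

    @property
    def percent_correct(self) -> float:
        return 100.0 * float((self.assigned == self.true_unit).mean())


def dapc(
    dataset: GenotypeDataset,
    level: str = "unit",
    cum_var: float = 0.90,
    n_discriminants: int = 5,
) -> DapcResult:
    """Discriminant analysis of principal components over the given level.

    Missing allele counts are imputed to the unit mean before the PCA
    rotation; the smallest component count reaching ``cum_var`` of the
    variance is retained, then an LDA with at most ``n_discriminants``
    axes is fitted on the retained components.
    """
    parts = dataset.partition(level)
    if len(parts) < 2:
        raise ValueError("DAPC requires at least two units")
    x, _ = _allele_count_matrix(dataset)
    y = np.array([dataset.label_of(ind, level) for ind in dataset.individuals])
    for lb, idx in parts.items():
        sub = x[idx]
        mu = np.nanmean(sub, axis=0)
        mu = np.where(np.isfinite(mu), mu, 0.0)
        nanmask = np.isnan(sub)
        sub[nanmask] = np.broadcast_to(mu, sub.shape)[nanmask]
        x[idx] = sub
    pca = PCA()
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, min(cum_var, cum[-1] - 1e-12)) + 1)
    n_comp = min(n_comp, len(cum), dataset.n_individuals - 1)
    scores = scores[:, :n_comp]
    lda = LinearDiscriminantAnalysis(
        n_components=min(n_discriminants, len(parts) - 1, n_comp)
    )
    coords = lda.fit_transform(scores, y)
    proba = lda.predict_proba(scores)
    ids = [ind.id for ind in dataset.individuals]
    return DapcResult(
        memberships=pd.DataFrame(proba, index=ids, columns=lda.classes_),
        assigned=pd.Series(lda.predict(scores), index=ids),
        true_unit=pd.Series(y, index=ids),
        coordinates=coords[:, : min(2, coords.shape[1])],
        n_components=n_comp,
        explained_variance=float(cum[n_comp - 1]),
    )


# ---------------------------------------------------------------------
# admixture-model Gibbs sampler


@dataclass
class QMatrix:
    q: pd.DataFrame  # individuals x K, rows sum to 1
    k: int
    iterations: int
    burn_in: int
    seed: int
    mean_log_likelihood: float
    log_likelihood_trace: np.ndarray = field(repr=False, default=None)

    def values(self) -> np.ndarray:
        return self.q.to_numpy()


def admixture_gibbs(
    dataset: GenotypeDataset,
    K: int,
    iterations: int = 10_000,
    burn_in: int = 5_000,
    seed: int = 0,
    alpha: float = 1.0,
    lambda_p: float = 1.0,
) -> QMatrix:
    """Admixture-model Gibbs sampler (uncorrelated allele frequencies).

    Latent origins Z (one per gene copy), cluster frequencies P and
    admixture vectors Q are updated in turn with conjugate Dirichlet
    draws.  Missing gene copies are excluded from likelihood and counts.
    ``mean_log_likelihood`` is the STRUCTURE-style estimate
    ``mean(lnL) - var(lnL)/2`` over post-burn-in sweeps.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > dataset.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    if not iterations > burn_in >= 0:
        raise ValueError("need iterations > burn_in >= 0")
    rng = np.random.default_rng(seed)
    n, L = dataset.n_individuals, dataset.n_loci
    ids = [ind.id for ind in dataset.individuals]
    if K == 1:
        q = pd.DataFrame(np.ones((n, 1)), index=ids, columns=[0])
        # likelihood under pooled frequencies, for K-selection tables
        ll = _pooled_loglik(dataset)
        return QMatrix(q, 1, iterations, burn_in, seed, ll,
                       np.full(iterations - burn_in, ll))

    # factorise allele codes per locus
    codes = np.full((n, L, 2), -1, dtype=np.int64)
    n_states = np.zeros(L, dtype=np.int64)
    for j in range(L):
        calls = dataset.calls[:, j, :]
        typed = (calls != MISSING).all(axis=1)
        alleles, inv = np.unique(calls[typed].ravel(), return_inverse=True)
        codes[typed, j, :] = inv.reshape(-1, 2)
        n_states[j] = len(alleles)
    a_max = int(n_states.max())
    observed = codes >= 0  # (n, L, 2)

    q = rng.dirichlet(np.full(K, alpha), size=n)
    z = rng.integers(0, K, size=(n, L, 2))
    ind_idx = np.repeat(np.arange(n), L * 2)
    loc_idx = np.tile(np.repeat(np.arange(L), 2), n)
    q_sum = np.zeros((n, K))
    ll_trace = np.empty(iterations - burn_in)
    state_pad = a_max
    for sweep in range(iterations):
        # P | Z: Dirichlet(lambda + counts) per (cluster, locus)
        counts = np.zeros((K, L, state_pad))
        flat_ok = observed.ravel()
        np.add.at(
            counts,
            (z.ravel()[flat_ok], loc_idx[flat_ok], codes.ravel()[flat_ok]),
            1.0,
        )
        gam = rng.gamma(lambda_p + counts)
        for j in range(L):  # zero out padding states
            gam[:, j, n_states[j]:] = 0.0
        p = gam / gam.sum(axis=2, keepdims=True)
        # Z | P, Q per gene copy
        safe_codes = np.where(codes >= 0, codes, 0)
        pz = p[:, np.arange(L)[None, :, None], safe_codes]  # (K, n, L, 2)
        probs = q.T[:, :, None, None] * pz  # (K, n, L, 2)
        tot = probs.sum(axis=0)
        probs /= np.where(tot > 0, tot, 1.0)
        u = rng.random((n, L, 2))
        cum = np.cumsum(probs, axis=0)
        z = (u[None] > cum).sum(axis=0)
        z = np.clip(z, 0, K - 1)
        # Q | Z: Dirichlet(alpha + membership counts)
        m = np.zeros((n, K))
        np.add.at(m, (ind_idx[flat_ok], z.ravel()[flat_ok]), 1.0)
        gq = rng.gamma(alpha + m)
        q = gq / gq.sum(axis=1, keepdims=True)
        if sweep >= burn_in:
            q_sum += q
            with np.errstate(divide="ignore"):
                ll = np.log(np.where(tot > 0, tot, 1.0))
            ll_trace[sweep - burn_in] = ll[observed].sum()
    q_mean = q_sum / (iterations - burn_in)
    mean_ll = float(ll_trace.mean() - ll_trace.var() / 2)
    return QMatrix(
        pd.DataFrame(q_mean, index=ids, columns=range(K)),
        K, iterations, burn_in, seed, mean_ll, ll_trace,
    )


def _pooled_loglik(dataset: GenotypeDataset) -> float:
    """ln-likelihood of all gene copies under pooled allele frequencies."""
    total = 0.0
    for j in range(dataset.n_loci):
        calls = dataset.calls[:, j, :]
        typed = (calls != MISSING).all(axis=1)
        alleles, counts = np.unique(calls[typed].ravel(), return_counts=True)
        p = counts / counts.sum()
        total += float((counts * np.log(p)).sum())
    return total


# ---------------------------------------------------------------------
# K selection (Evanno) and run alignment


@dataclass
class KSelectionTable:
    table: pd.DataFrame  # index K: mean_L, sd_L, delta_k
    best_k: int | None


def evanno_delta_k(replicate_lls: dict[int, list[float]]) -> KSelectionTable:
    """Second-difference statistic over replicate mean log-likelihoods.

    ``delta K`` is undefined at the boundary K values and flagged absent
    (NaN) there; a zero replicate standard deviation yields an infinite
    value, reported as computed.
    """
    ks = sorted(replicate_lls)
    if len(ks) < 3:
        raise ValueError("Evanno's method needs at least 3 consecutive K values")
    for k in ks:
        if len(replicate_lls[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 replicates")
    mean_l = {k: float(np.mean(replicate_lls[k])) for k in ks}
    sd_l = {k: float(np.std(replicate_lls[k], ddof=1)) for k in ks}
    rows = []
    for i, k in enumerate(ks):
        if 0 < i < len(ks) - 1:
            second = abs(mean_l[ks[i + 1]] - 2 * mean_l[k] + mean_l[ks[i - 1]])
            with np.errstate(divide="ignore"):
                dk = second / sd_l[k] if sd_l[k] > 0 else np.inf
        else:
            dk = np.nan
        rows.append({"K": k, "mean_L": mean_l[k], "sd_L": sd_l[k], "delta_k": dk})
    table = pd.DataFrame(rows).set_index("K")
    finite = table["delta_k"].replace(np.inf, np.nan).dropna()
    interior = table["delta_k"].iloc[1:-1]
    best = None
    if interior.notna().any():
        best = int(interior.idxmax()) if np.isfinite(interior.max()) else int(
            interior.index[np.isinf(interior)][0]
        )
    del finite
    return KSelectionTable(table=table, best_k=best)


def align_runs(runs: list[QMatrix]) -> tuple[list[QMatrix], float]:
    """Repair label switching across replicate runs; return similarity C.

    Each run's columns are permuted to best match the first run (optimal
    assignment on the column-correlation score).  C is the mean pairwise
    similarity ``1 - ||Q - Q'||_F / sqrt(2 n)`` of the aligned runs,
    which is 1 for identical runs and lies in [0, 1].
    """
    if not runs:
        raise ValueError("no runs to align")
    k = runs[0].k
    if any(r.k != k for r in runs):
        raise ValueError("all runs must share the same K")
    ref = runs[0].values()
    aligned = [runs[0]]
    for r in runs[1:]:
        q = r.values()
        score = ref.T @ q  # (K, K) agreement
        row, col = linear_sum_assignment(-score)
        perm = np.empty(k, dtype=int)
        perm[row] = col
        q2 = q[:, perm]
        aligned.append(
            QMatrix(
                pd.DataFrame(q2, index=r.q.index, columns=range(k)),
                r.k, r.iterations, r.burn_in, r.seed,
                r.mean_log_likelihood, r.log_likelihood_trace,
            )
        )
    n = ref.shape[0]
    sims = []
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            diff = aligned[i].values() - aligned[j].values()
            sims.append(1.0 - np.linalg.norm(diff) / np.sqrt(2 * n))
    c = float(np.mean(sims)) if sims else 1.0
    return aligned, c
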