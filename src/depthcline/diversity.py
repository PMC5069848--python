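"""Per-group genetic diversity: allele counts, heterozygosities, rarefied
(private) allelic richness, and the Fis permutation test, plus the SGoF and
Bonferroni multiple-test corrections.

Rarefaction uses exact hypergeometric expectations rather than resampling:
the expected number of distinct alleles in a standardized subsample of ``g``
gene copies is a closed-form sum over observed allele counts, so the result
is deterministic and fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .io_formats import GenotypeTable, allele_count_matrices


def n_pairs(n: int) -> int:
    """Number of unordered pairs n(n-1)/2 (locus-pair bookkeeping helper)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def _group_indices(grouping) -> tuple[list[str], list[np.ndarray]]:
    labels = pd.Series(grouping).astype(str)
    names = sorted(labels.unique())
    return names, [np.flatnonzero((labels == g).to_numpy()) for g in names]


def allele_frequencies(
    gt: GenotypeTable, grouping
) -> dict[str, list[dict[int, float]]]:
    """Per-group, per-locus allele frequency dictionaries.

    Missing calls are excluded locus-wise; a locus entirely missing within a
    group yields an empty dict for that group/locus (flagged by emptiness) and
    is excluded from multilocus summaries downstream.
    """
    names, idx = _group_indices(grouping)
    mats = allele_count_matrices(gt)
    out: dict[str, list[dict[int, float]]] = {g: [] for g in names}
    for counts, alleles in mats:
        for g, rows in zip(names, idx):
            sub = counts[rows]
            total = sub.sum()
            if total == 0:
                out[g].append({})
            else:
                freqs = sub.sum(axis=0) / total
                out[g].append(
                    {int(a): float(f) for a, f in zip(alleles, freqs) if f > 0}
                )
    return out


def heterozygosities(gt: GenotypeTable, grouping) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per group and locus.

    Ho is the fraction of heterozygous individuals among those typed; He is
    Nei's gene diversity with the small-sample correction
    ``(2n/(2n-1)) * (1 - sum p^2)``.  Monomorphic loci give Ho = He = 0.
    Rows: (group, locus) plus a multilocus ``mean`` row per group.
    """
    names, idx = _group_indices(grouping)
    mats = allele_count_matrices(gt)
    rows = []
    for g, gi in zip(names, idx):
        hos, hes = [], []
        for (counts, _), locus in zip(mats, gt.locus_names):
            sub = counts[gi]
            typed = sub.sum(axis=1) == 2
            n = int(typed.sum())
            if n == 0:
                rows.append((g, locus, np.nan, np.nan, 0))
                continue
            ho = float((sub[typed] == 1).any(axis=1).mean())
            p = sub[typed].sum(axis=0) / (2 * n)
            he = (2 * n / (2 * n - 1)) * (1 - float((p**2).sum())) if n > 0 else 0.0
            if len(p[p > 0]) <= 1:
                ho, he = ho, 0.0
            rows.append((g, locus, ho, he, n))
            hos.append(ho)
            hes.append(he)
        rows.append((g, "mean", float(np.mean(hos)), float(np.mean(hes)), np.nan))
    return pd.DataFrame(rows, columns=["group", "locus", "Ho", "He", "n_typed"])


def _rarefied_locus(allele_counts: np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in g gene copies drawn without
    replacement from a sample with the given per-allele counts."""
    N = int(allele_counts.sum())
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > N:
        raise ValueError(f"g={g} exceeds available gene copies N={N}")
    # P(allele absent from the subsample) = C(N - Na, g) / C(N, g)
    q = hypergeom.pmf(0, N, allele_counts, g)
    return float((1.0 - q).sum())


def rarefied_richness(gt: GenotypeTable, grouping, g: int) -> pd.DataFrame:
    """Allelic richness standardized to g gene copies, per group and locus.

    ``g`` must not exceed twice the smallest per-group typed sample size at
    any locus; the per-group mean over loci is appended as locus ``mean``.
    """
    names, idx = _group_indices(grouping)
    mats = allele_count_matrices(gt)
    per_group: dict[str, list[float]] = {name: [] for name in names}
    rows = []
    for (counts, _), locus in zip(mats, gt.locus_names):
        for name, gi in zip(names, idx):
            tot = counts[gi].sum(axis=0)
            N = int(tot.sum())
            if N < g:
                raise ValueError(
                    f"g={g} exceeds the {N} gene copies of group {name!r} "
                    f"at locus {locus!r}"
                )
            ar = _rarefied_locus(tot, g)
            per_group[name].append(ar)
            rows.append((name, locus, ar))
    for name in names:
        rows.append((name, "mean", float(np.mean(per_group[name]))))
    return pd.DataFrame(rows, columns=["group", "locus", "Ar"])


def private_rarefied_richness(gt: GenotypeTable, grouping, g: int) -> pd.DataFrame:
    """Rarefied private allelic richness per group and locus.

    For each allele, the probability that it appears in a subsample of g gene
    copies from the focal group while being absent from independent
    g-gene-copy subsamples of every other group (the generalized rarefaction
    scheme popularized by HP-RARE).
    """
    names, idx = _group_indices(grouping)
    mats = allele_count_matrices(gt)
    per_group: dict[str, list[float]] = {name: [] for name in names}
    rows = []
    for (counts, alleles), locus in zip(mats, gt.locus_names):
        totals = np.stack([counts[gi].sum(axis=0) for gi in idx])  # (r, k)
        Ns = totals.sum(axis=1)
        if (Ns < g).any():
            small = names[int(np.argmin(Ns))]
            raise ValueError(
                f"g={g} exceeds the gene copies of group {small!r} at locus "
                f"{locus!r}"
            )
        # q[r, a] = P(allele a absent from group r's subsample of g copies)
        q = np.stack(
            [hypergeom.pmf(0, int(N), tot, g) for N, tot in zip(Ns, totals)]
        )
        for r_i, name in enumerate(names):
            others = np.prod(np.delete(q, r_i, axis=0), axis=0)
            par = float(((1.0 - q[r_i]) * others).sum())
            per_group[name].append(par)
            rows.append((name, locus, par))
    for name in names:
        rows.append((name, "mean", float(np.mean(per_group[name]))))
    return pd.DataFrame(rows, columns=["group", "locus", "PAr"])


def mean_alleles(gt: GenotypeTable, grouping) -> pd.Series:
    """Mean number of distinct alleles per locus, per group."""
    names, idx = _group_indices(grouping)
    mats = allele_count_matrices(gt)
    out = {}
    for name, gi in zip(names, idx):
        counts_per_locus = [
            int((counts[gi].sum(axis=0) > 0).sum()) for counts, _ in mats
        ]
        out[name] = float(np.mean(counts_per_locus))
    return pd.Series(out, name="A")


# ---------------------------------------------------------------------------
# Fis (Weir-Cockerham small f) and its permutation test
# ---------------------------------------------------------------------------

def _fis_components(counts: np.ndarray) -> tuple[float, float]:
    """Single-group Weir-Cockerham variance components at one locus.

    Returns (sum_b + sum_c, sum_c) over alleles, where b is the
    between-individual-within-group and c the within-individual component;
    small f = 1 - sum(c) / sum(b + c) accumulated over alleles and loci.
    """
    typed = counts.sum(axis=1) == 2
    n = int(typed.sum())
    if n < 2:
        return 0.0, 0.0
    sub = counts[typed]
    p = sub.sum(axis=0) / (2 * n)
    if (p > 0).sum() <= 1:
        return 0.0, 0.0
    hbar = (sub == 1).sum(axis=0) / n  # het frequency carrying each allele
    b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
    c = hbar / 2
    return float((b + c).sum()), float(c.sum())


def _fis_from_mats(mats, rows: np.ndarray) -> float:
    bc = c = 0.0
    for counts, _ in mats:
        bc_l, c_l = _fis_components(counts[rows])
        bc += bc_l
        c += c_l
    if bc == 0.0:
        return np.nan
    return 1.0 - c / bc


def fis_test(
    gt: GenotypeTable,
    grouping,
    n_perm: int = 10000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Multilocus Fis per group with a within-group allele-permutation test.

    The null is Hardy-Weinberg within each group: alleles are shuffled among
    individuals within the group at each locus, and the two-sided P-value is
    ``(#{|Fis_perm| >= |Fis_obs|} + 1) / (n_perm + 1)``.  Monomorphic groups
    give Fis = NaN.
    """
    rng = np.random.default_rng(rng)
    names, idx = _group_indices(grouping)
    mats = allele_count_matrices(gt)
    rows = []
    for name, gi in zip(names, idx):
        if len(gi) < 2:
            raise ValueError(f"group {name!r} needs >= 2 individuals")
        fobs = _fis_from_mats(mats, gi)
        if np.isnan(fobs):
            rows.append((name, np.nan, np.nan, False))
            continue
        # Pre-split each locus into its typed allele pool within the group.
        pools = []
        for counts, alleles in mats:
            sub = counts[gi]
            typed = np.flatnonzero(sub.sum(axis=1) == 2)
            pool = np.repeat(
                np.arange(sub.shape[1]), sub[typed].sum(axis=0)
            )
            pools.append((typed, pool, sub.shape[1]))
        hits = 0
        for _ in range(n_perm):
            bc = c = 0.0
            for typed, pool, k in pools:
                if len(typed) < 2 or len(pool) == 0:
                    continue
                perm = rng.permutation(pool).reshape(-1, 2)
                counts_p = np.zeros((len(typed), k), dtype=np.int8)
                np.add.at(counts_p, (np.arange(len(typed)), perm[:, 0]), 1)
                np.add.at(counts_p, (np.arange(len(typed)), perm[:, 1]), 1)
                bc_l, c_l = _fis_components(counts_p)
                bc += bc_l
                c += c_l
            f_p = 1.0 - c / bc if bc != 0 else 0.0
            if abs(f_p) >= abs(fobs) - 1e-15:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        rows.append((name, fobs, p, p <= alpha))
    return pd.DataFrame(rows, columns=["group", "Fis", "P", "significant"])


# ---------------------------------------------------------------------------
# Multiple-test corrections
# ---------------------------------------------------------------------------

def bonferroni_correct(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of tests significant at the Bonferroni level alpha/n."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    _check_p(p)
    return p <= alpha / p.size


def sgof_correct(p_values, alpha: float = 0.05) -> np.ndarray:
    """Sequential goodness-of-fit (SGoF) metatest.

    With ``R`` of ``n`` p-values at or below alpha, the number of discoveries
    is the largest k such that observing ``R - k + 1 .. R`` sub-alpha tests
    still exceeds binomial(n, alpha) expectation at level alpha, applied
    sequentially from R downward; the k smallest p-values are declared
    significant.  Returns a boolean mask aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    _check_p(p)
    n = p.size
    R = int((p <= alpha).sum())
    k = 0
    for j in range(R, 0, -1):
        # one-sided exact binomial: P(X >= j) under Bin(n, alpha)
        if binom.sf(j - 1, n, alpha) <= alpha:
            k += 1
        else:
            break
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        mask[np.argsort(p, kind="stable")[:k]] = True
    return mask


def _check_p(p: np.ndarray) -> None:
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
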