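"""Differentiation and structure: Weir-Cockerham theta with permutation and
locus-bootstrap inference, Jost's Dest with a pooled-pair bootstrap null,
hierarchical AMOVA with factor ranking, Mantel tests, and individual-level
principal coordinates.

Theta follows the classical variance-component estimator: per locus and
allele the among-group (a), among-individual-within-group (b) and
within-individual (c) components are accumulated and theta = sum(a) /
sum(a + b + c).  Negative estimates are reported as computed — truncation
would bias the weak-differentiation regime this pipeline targets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, allele_count_matrices

__all__ = [
    "weir_cockerham_theta",
    "pairwise_fst",
    "fst_bootstrap_ci",
    "ci_to_se",
    "jost_d",
    "pairwise_jost_d",
    "amova",
    "amova_rank",
    "mantel",
    "pcoa_individuals",
    "genotype_distance_matrix",
    "DifferentiationResult",
    "AmovaResult",
    "MantelResult",
    "PcoaResult",
]


def _group_rows(grouping) -> tuple[list[str], np.ndarray]:
    labels = pd.Series(grouping).astype(str)
    names = sorted(labels.unique())
    codes = labels.map({g: i for i, g in enumerate(names)}).to_numpy()
    return names, codes


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _theta_locus_components(
    counts: np.ndarray, codes: np.ndarray, r: int
) -> tuple[float, float]:
    """(sum_a, sum_abc) over alleles for one locus.

    ``counts`` is the (n, k) per-individual allele-copy matrix (all-zero rows
    are missing calls), ``codes`` the 0..r-1 group code per individual.
    """
    typed = counts.sum(axis=1) == 2
    n_i = np.bincount(codes[typed], minlength=r).astype(float)
    live = n_i >= 1
    r_eff = int(live.sum())
    if r_eff < 2:
        return 0.0, 0.0
    n_i = n_i[live]
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0
    n_c = (r_eff * nbar - (n_i**2).sum() / (r_eff * nbar)) / (r_eff - 1)
    if n_c <= 0:
        return 0.0, 0.0
    k = counts.shape[1]
    S = np.zeros((r, k))
    np.add.at(S, codes[typed], counts[typed])
    H = np.zeros((r, k))
    np.add.at(H, codes[typed], (counts[typed] == 1).astype(float))
    S, H = S[live], H[live]
    p_i = S / (2 * n_i[:, None])
    pbar = S.sum(axis=0) / (2 * r_eff * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r_eff - 1) * nbar)
    hbar = H.sum(axis=0) / (r_eff * nbar)
    a = (nbar / n_c) * (
        s2
        - (pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r_eff - 1) / r_eff * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float((a + b + c).sum())


def theta_locus_sums(gt: GenotypeTable, grouping) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (sum_a, sum_abc) arrays, the raw material for multilocus
    theta and its locus bootstrap."""
    names, codes = _group_rows(grouping)
    mats = allele_count_matrices(gt)
    a = np.empty(gt.n_loci)
    abc = np.empty(gt.n_loci)
    for j, (counts, _) in enumerate(mats):
        a[j], abc[j] = _theta_locus_components(counts, codes, len(names))
    return a, abc


def weir_cockerham_theta(gt: GenotypeTable, grouping) -> float:
    """Multilocus Weir-Cockerham theta (Fst estimator) across all groups."""
    a, abc = theta_locus_sums(gt, grouping)
    total = abc.sum()
    if total == 0:
        return np.nan
    return float(a.sum() / total)


@dataclass
class DifferentiationResult:
    """Pairwise differentiation with permutation/bootstrap inference.

    Matrices are symmetric with zero diagonals; ``fst_p``/``d_p`` hold the
    corresponding P-values, and the boolean masks flag pairs that survive
    Bonferroni correction across the pairs tested.
    """

    group_labels: list[str]
    fst: pd.DataFrame
    fst_p: pd.DataFrame | None = None
    d: pd.DataFrame | None = None
    d_p: pd.DataFrame | None = None
    fst_bonferroni: pd.DataFrame | None = None
    d_bonferroni: pd.DataFrame | None = None
    global_theta: float | None = None
    global_theta_ci: tuple[float, float] | None = None
    global_theta_se: float | None = None

    def combined_table(self) -> pd.DataFrame:
        """Fst below the diagonal, Jost D above (the familiar print layout)."""
        labels = self.group_labels
        out = pd.DataFrame(np.nan, index=labels, columns=labels)
        for i, gi in enumerate(labels):
            for j, gj in enumerate(labels):
                if i > j:
                    out.loc[gi, gj] = self.fst.loc[gi, gj]
                elif i < j and self.d is not None:
                    out.loc[gi, gj] = self.d.loc[gi, gj]
        return out


def pairwise_fst(
    gt: GenotypeTable,
    grouping,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> DifferentiationResult:
    """Pairwise multilocus theta with permutation P-values.

    For each pair of groups, individuals are permuted between the two groups
    and theta recomputed; P = (#{theta_perm >= theta_obs} + 1) / (n_perm + 1).
    Pairs for which every locus is monomorphic are reported as NaN.
    """
    rng = np.random.default_rng(rng)
    names, codes = _group_rows(grouping)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    mats = allele_count_matrices(gt)
    fst = pd.DataFrame(0.0, index=names, columns=names)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        rows = np.flatnonzero((codes == i) | (codes == j))
        pair_codes = (codes[rows] == j).astype(int)
        sub = [(counts[rows], al) for counts, al in mats]
        theta_obs = _multilocus_theta(sub, pair_codes)
        if np.isnan(theta_obs):
            fst.loc[names[i], names[j]] = fst.loc[names[j], names[i]] = np.nan
            continue
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pair_codes)
            if _multilocus_theta(sub, perm) >= theta_obs - 1e-15:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        fst.loc[names[i], names[j]] = fst.loc[names[j], names[i]] = theta_obs
        pmat.loc[names[i], names[j]] = pmat.loc[names[j], names[i]] = p
    ps = np.array(
        [pmat.iloc[i, j] for i, j in itertools.combinations(range(len(names)), 2)]
    )
    n_tests = np.isfinite(ps).sum()
    bonf = pd.DataFrame(False, index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        sig = bool(pmat.iloc[i, j] <= 0.05 / max(n_tests, 1))
        bonf.iloc[i, j] = bonf.iloc[j, i] = sig
    return DifferentiationResult(
        group_labels=names, fst=fst, fst_p=pmat, fst_bonferroni=bonf
    )


def _multilocus_theta(mats, codes: np.ndarray) -> float:
    r = int(codes.max()) + 1
    a_sum = abc_sum = 0.0
    for counts, _ in mats:
        a, abc = _theta_locus_components(counts, codes, r)
        a_sum += a
        abc_sum += abc
    return a_sum / abc_sum if abc_sum != 0 else np.nan


def fst_bootstrap_ci(
    gt: GenotypeTable,
    grouping,
    n_boot: int = 1000,
    ci: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, tuple[float, float], float]:
    """Multilocus theta with a percentile CI over locus resampling.

    Returns ``(theta, (lower, upper), se)`` where the SE derives from the CI
    by the normal-width rule ``SE = (upper - lower) / 3.92``.
    """
    if gt.n_loci < 2:
        raise ValueError("locus bootstrap needs >= 2 loci")
    rng = np.random.default_rng(rng)
    a, abc = theta_locus_sums(gt, grouping)
    theta = float(a.sum() / abc.sum())
    idx = rng.integers(0, gt.n_loci, size=(n_boot, gt.n_loci))
    num = a[idx].sum(axis=1)
    den = abc[idx].sum(axis=1)
    boots = np.divide(num, den, out=np.full(n_boot, np.nan), where=den != 0)
    lo, hi = np.nanquantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return theta, (float(lo), float(hi)), ci_to_se(float(lo), float(hi))


def ci_to_se(lower: float, upper: float) -> float:
    """Convert a 95% CI to a standard error: SE = (upper - lower) / 3.92."""
    if upper < lower:
        raise ValueError("upper CI limit below lower limit")
    return (upper - lower) / 3.92


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def _dest_locus(totals: np.ndarray, n_ind: np.ndarray) -> float:
    """Per-locus Dest from per-group allele-copy totals (r, k) and the
    per-group typed individual counts, with the small-sample estimators of
    Hs and Ht (harmonic-mean sample size, n/(n-1)-style corrections)."""
    r = totals.shape[0]
    gene_copies = totals.sum(axis=1)
    if (gene_copies == 0).any():
        return np.nan
    p = totals / gene_copies[:, None]
    hs = 1.0 - float((p**2).sum(axis=1).mean())
    pbar = p.mean(axis=0)
    ht = 1.0 - float((pbar**2).sum())
    nh = r / (1.0 / n_ind).sum()  # harmonic mean individuals per group
    hs_est = (2 * nh / (2 * nh - 1)) * hs
    ht_est = ht + hs_est / (2 * nh * r)
    if ht_est >= 1.0 or hs_est >= 1.0:
        return 1.0
    return ((ht_est - hs_est) / (1.0 - hs_est)) * r / (r - 1)


def _dest_multilocus(d_locus: np.ndarray) -> float:
    """Combine per-locus Dest by the variance-adjusted harmonic mean
    1 / (1/mean + var * (1/mean)^3); falls back to the arithmetic mean when
    that delta-method form is undefined (mean <= 0, or a single locus)."""
    d = d_locus[np.isfinite(d_locus)]
    if d.size == 0:
        return np.nan
    mu = d.mean()
    if d.size == 1 or mu <= 0:
        return float(mu)
    var = d.var(ddof=1)
    return float(1.0 / (1.0 / mu + var / mu**3))


def _locus_totals(mats, rows: np.ndarray, codes: np.ndarray, r: int):
    """Per-locus (totals (r,k), n_ind (r,)) for the given individuals."""
    out = []
    for counts, _ in mats:
        sub = counts[rows]
        typed = sub.sum(axis=1) == 2
        totals = np.zeros((r, sub.shape[1]))
        np.add.at(totals, codes[typed], sub[typed])
        n_ind = np.bincount(codes[typed], minlength=r).astype(float)
        out.append((totals, n_ind))
    return out


def jost_d(
    gt: GenotypeTable,
    grouping,
    n_boot: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Multilocus Dest across the given groups with a bootstrap P-value.

    The null resamples each group's genotypes at each locus from the pooled
    allele distribution under Hardy-Weinberg (preserving sample sizes), the
    semantics of the DEMEtics-style significance test; P is one-sided,
    P = (#{D_boot >= D_obs} + 1) / (n_boot + 1).
    """
    rng = np.random.default_rng(rng)
    names, codes = _group_rows(grouping)
    r = len(names)
    if r < 2:
        raise ValueError("need >= 2 groups")
    mats = allele_count_matrices(gt)
    rows = np.arange(gt.n_individuals)
    per_locus = _locus_totals(mats, rows, codes, r)
    d_obs = _dest_multilocus(
        np.array([_dest_locus(t, n) for t, n in per_locus if (n > 0).all()])
    )
    if np.isnan(d_obs):
        return np.nan, np.nan
    pooled = [
        (t.sum(axis=0) / max(t.sum(), 1), n) for t, n in per_locus
    ]
    hits = 0
    for _ in range(n_boot):
        d_l = []
        for (p_pool, n_ind), (t, _) in zip(pooled, per_locus):
            if (n_ind == 0).any() or p_pool.sum() == 0:
                continue
            k = len(p_pool)
            tot_b = np.stack(
                [rng.multinomial(int(2 * n), p_pool) for n in n_ind]
            ).astype(float)
            d_l.append(_dest_locus(tot_b, n_ind))
        d_b = _dest_multilocus(np.array(d_l))
        if d_b >= d_obs - 1e-15:
            hits += 1
    return float(d_obs), (hits + 1) / (n_boot + 1)


def pairwise_jost_d(
    gt: GenotypeTable,
    grouping,
    n_boot: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> DifferentiationResult:
    """Pairwise Dest matrix with bootstrap P and Bonferroni flags."""
    rng = np.random.default_rng(rng)
    names, codes = _group_rows(grouping)
    labels = pd.Series(grouping).astype(str).to_numpy()
    d = pd.DataFrame(0.0, index=names, columns=names)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    pairs = list(itertools.combinations(names, 2))
    for gi, gj in pairs:
        rows = np.flatnonzero((labels == gi) | (labels == gj))
        sub = gt.subset_individuals(np.isin(np.arange(gt.n_individuals), rows))
        dv, pv = jost_d(sub, labels[rows], n_boot=n_boot, rng=rng)
        d.loc[gi, gj] = d.loc[gj, gi] = dv
        pmat.loc[gi, gj] = pmat.loc[gj, gi] = pv
    bonf = pd.DataFrame(False, index=names, columns=names)
    for gi, gj in pairs:
        sig = bool(pmat.loc[gi, gj] <= 0.05 / len(pairs))
        bonf.loc[gi, gj] = bonf.loc[gj, gi] = sig
    return DifferentiationResult(
        group_labels=names, fst=pd.DataFrame(), d=d, d_p=pmat, d_bonferroni=bonf
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    source: str
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    fct: float
    p_value: float
    n_perm: int
    n_groups: int


def _genotype_matrix(gt: GenotypeTable) -> np.ndarray:
    """Individuals x allele-copy columns, scaled so squared Euclidean row
    distances equal the allele-count (number-of-different-alleles) metric
    at the gene-copy level; missing calls are mean-imputed per locus."""
    blocks = []
    for counts, _ in allele_count_matrices(gt):
        X = counts.astype(float)
        typed = X.sum(axis=1) == 2
        if typed.any() and (~typed).any():
            X[~typed] = X[typed].mean(axis=0)
        blocks.append(X / np.sqrt(2.0))
    return np.hstack(blocks)


def genotype_distance_matrix(gt: GenotypeTable) -> np.ndarray:
    """Squared inter-individual genotypic distance (allele-count metric)."""
    X = _genotype_matrix(gt)
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _amova_from_matrix(
    X: np.ndarray, codes: np.ndarray, k: int
) -> tuple[float, float, float, float, float]:
    """(ss_among, ss_within, var_among, var_within, fct)."""
    N = X.shape[0]
    n_g = np.bincount(codes, minlength=k).astype(float)
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, codes, X)
    total_sq = float((X**2).sum())
    grand = X.sum(axis=0)
    ss_total = total_sq - float((grand**2).sum()) / N
    ss_within = total_sq - float(((sums**2).sum(axis=1) / n_g).sum())
    ss_among = ss_total - ss_within
    var_within = ss_within / (N - k)
    n0 = (N - (n_g**2).sum() / N) / (k - 1)
    var_among = (ss_among / (k - 1) - var_within) / n0
    total_var = var_among + var_within
    fct = var_among / total_var if total_var != 0 else np.nan
    return ss_among, ss_within, var_among, var_within, fct


def amova(
    gt: GenotypeTable,
    grouping,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
    source: str = "grouping",
) -> AmovaResult:
    """One-level AMOVA on the allele-count genotypic distance.

    Variance is partitioned among and within groups; Fct = among / total.
    The P-value permutes whole individuals across groups:
    P = (#{Fct_perm >= Fct_obs} + 1) / (n_perm + 1).  Empty groups (e.g.
    empty factor-crossing cells) are dropped before computing degrees of
    freedom; a source with fewer than two non-empty groups raises.
    """
    rng = np.random.default_rng(rng)
    names, codes = _group_rows(grouping)
    k = len(names)
    if k < 2:
        raise ValueError(f"source {source!r} has fewer than two groups")
    X = _genotype_matrix(gt)
    N = X.shape[0]
    ss_a, ss_w, var_a, var_w, fct = _amova_from_matrix(X, codes, k)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        fct_p = _amova_from_matrix(X, perm, k)[4]
        if fct_p >= fct - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    total = var_a + var_w
    return AmovaResult(
        source=source,
        df_among=k - 1,
        df_within=N - k,
        ss_among=ss_a,
        ss_within=ss_w,
        var_among=var_a,
        var_within=var_w,
        pct_among=100 * var_a / total if total else np.nan,
        pct_within=100 * var_w / total if total else np.nan,
        fct=fct,
        p_value=p,
        n_perm=n_perm,
        n_groups=k,
    )


def amova_rank(
    gt: GenotypeTable,
    frame: pd.DataFrame,
    factors: tuple[str, ...] = ("ecotype", "zone", "stratum"),
    crossings: bool = True,
    n_perm: int = 10000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """AMOVA over each factor (and pairwise crossings), ranked by Fct.

    Sources are ranked with significant Fct first (descending Fct within
    each significance class), the factor-ranking view used to choose the
    grouping for downstream stages.  Crossing labels join the two factor
    levels; empty cells simply never appear as groups.
    """
    rng = np.random.default_rng(rng)
    ids = pd.Index(frame["individual_id"].astype(str))
    order = ids.get_indexer(gt.individual_ids)
    if (order < 0).any():
        raise ValueError("metadata does not cover all genotyped individuals")
    sources: list[tuple[str, pd.Series]] = [
        (f, frame.iloc[order][f].reset_index(drop=True)) for f in factors
    ]
    if crossings:
        for f1, f2 in itertools.combinations(factors, 2):
            lab = (
                frame.iloc[order][f1].astype(str)
                + "|"
                + frame.iloc[order][f2].astype(str)
            )
            sources.append((f"{f1} and {f2}", lab.reset_index(drop=True)))
    rows = []
    for name, labels in sources:
        if labels.nunique() < 2:
            continue  # skipped with warning semantics: unrankable source
        res = amova(gt, labels, n_perm=n_perm, rng=rng, source=name)
        rows.append(res)
    table = pd.DataFrame(
        {
            "source": [r.source for r in rows],
            "Fct": [r.fct for r in rows],
            "df": [r.df_among for r in rows],
            "sum_of_squares": [r.ss_among for r in rows],
            "var_among": [r.var_among for r in rows],
            "pct_variation": [r.pct_among for r in rows],
            "P": [r.p_value for r in rows],
        }
    )
    table["significant"] = table["P"] <= alpha
    return table.sort_values(
        ["significant", "Fct"], ascending=[False, False]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r_m: float
    p_value: float
    n_perm: int
    exact: bool
    labels: list[str] | None = None


def mantel(
    dist_a,
    dist_b,
    n_perm: int = 9999,
    alternative: str = "greater",
    rng: np.random.Generator | int | None = None,
    interpolate_index: int | None = None,
) -> MantelResult:
    """Mantel correlation between two square symmetric distance matrices.

    ``r_m`` is the Pearson correlation over upper-triangle entries; the null
    permutes rows and columns of the second matrix simultaneously.  For
    matrices of side <= 6 the full n! permutation set is enumerated and the
    P-value is exact; otherwise ``n_perm`` random permutations give
    P = (#{>= observed} + 1) / (n_perm + 1).  At least 4 points are required
    (fewer leave the test degenerate, the classical constraint).

    ``interpolate_index`` optionally replaces one putative-outlier point's
    distances in the second matrix with the mean of the other points'
    distances (a neighbor-mean interpolation).  It is off by default and the
    point must be named by the analyst: no objective outlier criterion is
    imposed.
    """
    A = _as_square(dist_a, "dist_a")
    B = _as_square(dist_b, "dist_b")
    labels = None
    if isinstance(dist_a, pd.DataFrame):
        labels = [str(x) for x in dist_a.index]
        if isinstance(dist_b, pd.DataFrame) and list(dist_b.index) != list(
            dist_a.index
        ):
            raise ValueError("matrix labels do not match")
    if interpolate_index is not None:
        B = _interpolate_point(B, int(interpolate_index))
    n = A.shape[0]
    if A.shape != B.shape:
        raise ValueError("matrices differ in size")
    if n < 4:
        raise ValueError("more than three points are required for a Mantel test")
    iu = np.triu_indices(n, k=1)
    x = A[iu]
    r_obs = _pearson(x, B[iu])
    def tail(r_p: float) -> bool:
        if alternative == "greater":
            return r_p >= r_obs - 1e-15
        if alternative == "less":
            return r_p <= r_obs + 1e-15
        return abs(r_p) >= abs(r_obs) - 1e-15
    if n <= 6:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            if tail(_pearson(x, B[np.ix_(p, p)][iu])):
                hits += 1
            total += 1
        return MantelResult(float(r_obs), hits / total, total, True, labels)
    rng = np.random.default_rng(rng)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if tail(_pearson(x, B[np.ix_(p, p)][iu])):
            hits += 1
    return MantelResult(
        float(r_obs), (hits + 1) / (n_perm + 1), n_perm, False, labels
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / den) if den else np.nan


def _interpolate_point(B: np.ndarray, i: int) -> np.ndarray:
    """Replace point i's distances with the neighbor mean: B[i, j] becomes
    the mean of B[k, j] over the other points k (k != i, j)."""
    n = B.shape[0]
    if not 0 <= i < n:
        raise ValueError(f"interpolate_index {i} outside 0..{n - 1}")
    B = B.copy()
    others = [k for k in range(n) if k != i]
    for j in range(n):
        if j == i:
            continue
        neigh = [B[k, j] for k in others if k != j]
        B[i, j] = B[j, i] = float(np.mean(neigh))
    return B


def _as_square(m, name: str) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    return a


def linearized(theta: np.ndarray | pd.DataFrame):
    """Rousset's linearization theta / (1 - theta) for distance-style use."""
    return theta / (1.0 - theta)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    prop_explained: np.ndarray
    degenerate: bool


def pcoa_individuals(gt: GenotypeTable) -> PcoaResult:
    """Principal coordinates of individuals from genotypic distances.

    The squared allele-count distance matrix is Gower double-centered and
    eigendecomposed; coordinates span the positive-eigenvalue axes, the
    percentage of variance is taken over positive eigenvalues only, and
    negative eigenvalues are retained in ``eigenvalues`` for inspection.
    An all-zero distance matrix is flagged as degenerate.
    """
    if gt.n_individuals < 3:
        raise ValueError("PCoA needs >= 3 individuals")
    d2 = genotype_distance_matrix(gt)
    degenerate = bool(np.allclose(d2, 0.0))
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(abs(vals[0]), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.zeros(0)
    return PcoaResult(coords, vals, prop, degenerate)
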