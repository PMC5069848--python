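"""Quantitative-trait divergence and its comparison with neutral Fst.

Two estimators of the phenotypic Fst analogue are provided.  The
variance-component route computes Pst = sigma2_B / (sigma2_B + 2 h2 sigma2_W)
from one-way random-effects components (method of moments; negative
between-group components truncate to zero).  The relationship-matrix route
standardizes group means by pooled within-group dispersion, forms the
codivergence matrix of centred means, corrects the diagonal for the O(1/n)
sampling variance of a group mean, scales by 1/(2 h2), and renormalizes so
the weighted mean of the diagonal equals the global Pst on the Fst scale.
Mahalanobis D2 between groups is r_ii + r_jj - 2 r_ij on that scale.  For
one trait, equal samples and h2 = 1 the two routes agree exactly, which is
enforced as an internal cross-validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PstResult:
    trait: str
    pst: float
    ci_low: float
    ci_high: float
    sigma2_between: float
    sigma2_within: float
    h2: float
    n_boot: int


@dataclass
class RMatrixResult:
    group_labels: list[str]
    r_matrix: pd.DataFrame
    rii: pd.Series
    d2: pd.DataFrame
    d2_se: pd.DataFrame | None
    global_pst: float
    h2: float
    sample_size_correction: bool


def _variance_components(
    y: np.ndarray, codes: np.ndarray, k: int
) -> tuple[float, float]:
    """Method-of-moments one-way random-effects (sigma2_B, sigma2_W);
    negative between-group estimates truncate to zero."""
    n_g = np.bincount(codes, minlength=k).astype(float)
    sums = np.bincount(codes, weights=y, minlength=k)
    means = sums / n_g
    N = len(y)
    ss_within = float(((y - means[codes]) ** 2).sum())
    msw = ss_within / (N - k)
    grand = y.mean()
    msb = float((n_g * (means - grand) ** 2).sum()) / (k - 1)
    n0 = (N - (n_g**2).sum() / N) / (k - 1)
    s2b = max((msb - msw) / n0, 0.0)
    return s2b, msw


def pst_variance_components(
    trait_adjusted,
    grouping,
    h2: float = 1.0,
    n_boot: int = 1000,
    trait: str = "trait",
    rng: np.random.Generator | int | None = None,
) -> PstResult:
    """Pst from one-way variance components with a bootstrap percentile CI.

    Pst = sigma2_B / (sigma2_B + 2 h2 sigma2_W).  The bootstrap unit is the
    individual within its group (group sizes preserved).  Fully degenerate
    input (both components zero) yields NaN.
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(trait_adjusted, dtype=float)
    labels = pd.Series(grouping).astype(str)
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("Pst needs >= 2 groups")
    codes = labels.map({g: i for i, g in enumerate(names)}).to_numpy()
    k = len(names)
    s2b, s2w = _variance_components(y, codes, k)
    if s2b == 0 and s2w == 0:
        return PstResult(trait, np.nan, np.nan, np.nan, 0.0, 0.0, h2, n_boot)
    pst = s2b / (s2b + 2 * h2 * s2w)
    if n_boot == 0:
        return PstResult(
            trait, float(pst), np.nan, np.nan, s2b, s2w, h2, 0
        )

    group_rows = [np.flatnonzero(codes == i) for i in range(k)]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        yb = np.empty_like(y)
        for rows in group_rows:
            yb[rows] = y[rows[rng.integers(0, len(rows), size=len(rows))]]
        b2, w2 = _variance_components(yb, codes, k)
        boots[b] = b2 / (b2 + 2 * h2 * w2) if (b2 + w2) > 0 else np.nan
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return PstResult(trait, float(pst), float(lo), float(hi), s2b, s2w, h2, n_boot)


def _codivergence(
    M: np.ndarray,  # (k groups, t traits) standardized group means
    w: np.ndarray,  # group weights, sum 1
    n_g: np.ndarray,
    correct: bool,
) -> np.ndarray:
    """Codivergence matrix of weighted-centred standardized group means,
    scaled by 1/(1 - sum w^2) so that in the balanced one-trait case its
    weighted diagonal mean is exactly sigma2_B / sigma2_W; the diagonal
    correction removes the sampling variance of each group mean."""
    k, t = M.shape
    Z = M - w @ M
    denom = 1.0 - float((w**2).sum())
    C = (Z @ Z.T) / (t * denom)
    if correct:
        for i in range(k):
            samp = (1 - w[i]) ** 2 / n_g[i] + sum(
                w[j] ** 2 / n_g[j] for j in range(k) if j != i
            )
            C[i, i] -= samp / denom
    return C


def r_matrix(
    trait_table_adjusted: pd.DataFrame | np.ndarray,
    grouping,
    h2: float = 1.0,
    sample_size_correction: bool = True,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> RMatrixResult:
    """Relationship (R) matrix, Mahalanobis D2, and global Pst from traits.

    Traits are standardized by their pooled within-group SD; the
    codivergence matrix of centred group means is scaled by 1/(2 h2) and
    renormalized by 1/(1 + g), g = sum_i w_i r_ii, so that the weighted mean
    of the reported diagonal equals global Pst = g / (1 + g).  D2_ij =
    r_ii + r_jj - 2 r_ij (clipped at 0 against correction-induced negatives)
    with a bootstrap-over-individuals SE when ``n_boot`` > 0.
    """
    rng = np.random.default_rng(rng)
    X = (
        trait_table_adjusted.to_numpy(dtype=float)
        if isinstance(trait_table_adjusted, pd.DataFrame)
        else np.atleast_2d(np.asarray(trait_table_adjusted, dtype=float).T).T
    )
    if X.ndim == 1:
        X = X[:, None]
    labels = pd.Series(grouping).astype(str)
    names = sorted(labels.unique())
    k = len(names)
    if k < 2:
        raise ValueError("R-matrix needs >= 2 groups")
    codes = labels.map({g: i for i, g in enumerate(names)}).to_numpy()
    n_g = np.bincount(codes, minlength=k).astype(float)
    if (n_g < 2).any():
        raise ValueError("every group needs >= 2 individuals")
    w = n_g / n_g.sum()

    R, gpst = _r_from_data(X, codes, n_g, w, h2, sample_size_correction)
    d2 = _d2_from_r(R)
    d2_se = None
    if n_boot > 0:
        group_rows = [np.flatnonzero(codes == i) for i in range(k)]
        boots = np.empty((n_boot, k, k))
        for b in range(n_boot):
            Xb = np.empty_like(X)
            for rows in group_rows:
                Xb[rows] = X[rows[rng.integers(0, len(rows), size=len(rows))]]
            Rb, _ = _r_from_data(Xb, codes, n_g, w, h2, sample_size_correction)
            boots[b] = _d2_from_r(Rb)
        d2_se = pd.DataFrame(boots.std(axis=0, ddof=1), index=names, columns=names)
    Rdf = pd.DataFrame(R, index=names, columns=names)
    return RMatrixResult(
        group_labels=names,
        r_matrix=Rdf,
        rii=pd.Series(np.diag(R), index=names, name="rii"),
        d2=pd.DataFrame(d2, index=names, columns=names),
        d2_se=d2_se,
        global_pst=gpst,
        h2=h2,
        sample_size_correction=sample_size_correction,
    )


def _r_from_data(X, codes, n_g, w, h2, correct) -> tuple[np.ndarray, float]:
    k = len(n_g)
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, codes, X)
    means = sums / n_g[:, None]
    resid = X - means[codes]
    pooled_var = (resid**2).sum(axis=0) / (len(X) - k)
    pooled_var = np.where(pooled_var > 0, pooled_var, 1.0)  # flat trait guard
    M = means / np.sqrt(pooled_var)
    C = _codivergence(M, w, n_g, correct)
    R = C / (2 * h2)
    g = float(w @ np.diag(R))
    if g <= -1:  # pathological over-correction; report unnormalized
        return R, np.nan
    return R / (1.0 + g), g / (1.0 + g)


def _d2_from_r(R: np.ndarray) -> np.ndarray:
    rii = np.diag(R)
    d2 = rii[:, None] + rii[None, :] - 2 * R
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def classify_selection(
    pst_results: dict[str, PstResult],
    fst_ci: tuple[float, float],
) -> pd.DataFrame:
    """Classify each trait by comparing Pst and Fst confidence intervals.

    ``selection`` when the Pst lower limit clears the Fst upper limit,
    ``below-neutral`` when the Pst upper limit sits under the Fst lower
    limit, ``drift`` when the intervals overlap, ``indeterminate`` when a
    CI is missing.  With h2 fixed at 1 the call is conservative (biased
    toward missing selection, not toward inventing it).
    """
    fst_lo, fst_hi = fst_ci
    rows = []
    for trait, res in pst_results.items():
        if not np.isfinite(res.ci_low) or not np.isfinite(res.ci_high):
            label = "indeterminate"
        elif res.ci_low > fst_hi:
            label = "selection"
        elif res.ci_high < fst_lo:
            label = "below-neutral"
        else:
            label = "drift"
        rows.append(
            (trait, res.pst, res.ci_low, res.ci_high, fst_lo, fst_hi, label)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait",
            "Pst",
            "Pst_ci_low",
            "Pst_ci_high",
            "Fst_ci_low",
            "Fst_ci_high",
            "classification",
        ],
    )


def d2_vs_depth(
    trait_table_adjusted: pd.DataFrame,
    grouping,
    stratum_order: list[str],
    fst_pairwise: pd.DataFrame,
    h2: float = 1.0,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-trait paired D2 vs Fst across the three ordered strata.

    For each trait a one-trait R-matrix yields D2 (with bootstrap SE) for
    the (S1,S2), (S2,S3), (S1,S3) pairs alongside the corresponding pairwise
    Fst; ``monotone_increase`` flags D2 growing with depth separation.
    """
    if len(stratum_order) != 3:
        raise ValueError("expected exactly 3 ordered strata")
    rng = np.random.default_rng(rng)
    s1, s2, s3 = stratum_order
    pairs = [(s1, s2), (s2, s3), (s1, s3)]
    rows = []
    for trait in trait_table_adjusted.columns:
        res = r_matrix(
            trait_table_adjusted[[trait]],
            grouping,
            h2=h2,
            n_boot=n_boot,
            rng=rng,
        )
        d2 = {p: float(res.d2.loc[p[0], p[1]]) for p in pairs}
        se = {
            p: (float(res.d2_se.loc[p[0], p[1]]) if res.d2_se is not None else np.nan)
            for p in pairs
        }
        mono = d2[(s1, s3)] >= max(d2[(s1, s2)], d2[(s2, s3)])
        for p in pairs:
            rows.append(
                (
                    trait,
                    f"{p[0]} vs {p[1]}",
                    d2[p],
                    se[p],
                    float(fst_pairwise.loc[p[0], p[1]]),
                    mono,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["trait", "pair", "D2", "D2_se", "Fst", "monotone_increase"],
    )
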