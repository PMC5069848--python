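"""Trait preprocessing and clinal analysis across depth strata.

Size adjustment regresses log10(trait) on log10(standard length) — allometry
is multiplicative, so the log-log dialect is the default — and returns
internally studentized residuals, which have zero mean, roughly unit
variance, and are orthogonal to the size axis.  Clines are assessed by
one-way ANOVA with Fisher's LSD post hoc (classically unadjusted, gated on
the omnibus test), and within-group variance profiles with bootstrap CIs
separate the divergence-with-depth (character release) pattern from the
intermediate-peak (hybridization-consistent) one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence


def compute_buoyancy(weight_air, weight_water) -> np.ndarray:
    """Percent buoyancy: 100 * (weight_air - weight_water) / weight_air.

    Values above 100 (negative in-water weight) are permitted with a
    warning; non-positive in-air weight raises.
    """
    wa = np.asarray(weight_air, dtype=float)
    ww = np.asarray(weight_water, dtype=float)
    if (wa <= 0).any():
        raise ValueError("weight_air must be strictly positive")
    out = 100.0 * (wa - ww) / wa
    if (out > 100).any():
        warnings.warn(
            "buoyancy above 100% (negative in-water weight)", stacklevel=2
        )
    return out


def size_adjust(
    trait_values,
    sl_values,
    log_sl: bool = True,
    external: bool = False,
    ids=None,
) -> np.ndarray:
    """Size-adjusted trait: studentized residuals of log10(trait) on size.

    ``log_sl`` selects the regressor dialect (log10(SL), the default, or raw
    SL).  ``external=True`` switches to externally studentized residuals.
    Non-positive measurements raise, listing the offending individuals.
    """
    y = np.asarray(trait_values, dtype=float)
    x = np.asarray(sl_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("trait and SL must be equal-length vectors")
    if len(y) < 3:
        raise ValueError("size adjustment needs n >= 3")
    bad = np.flatnonzero((y <= 0) | (x <= 0))
    if bad.size:
        names = [ids[i] for i in bad] if ids is not None else bad.tolist()
        raise ValueError(f"non-positive measurements for: {names}")
    X = sm.add_constant(np.log10(x) if log_sl else x)
    ylog = np.log10(y)
    fit = sm.OLS(ylog, X).fit()
    # perfect allometry leaves only floating-point dust in the residuals;
    # studentizing 0/0 would amplify it, so report exact zeros instead
    if fit.ssr <= 1e-24 * max(float(((ylog - ylog.mean()) ** 2).sum()), 1e-30):
        return np.zeros_like(ylog)
    infl = OLSInfluence(fit)
    if external:
        return np.asarray(infl.resid_studentized_external)
    return np.asarray(infl.resid_studentized_internal)


@dataclass
class AnovaResult:
    trait: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: pd.DataFrame
    lsd: pd.DataFrame | None  # None when the omnibus test is not significant
    dropped_groups: list[str] = field(default_factory=list)


def anova_lsd(
    trait_values, grouping, trait: str = "trait", alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA with Fisher's LSD post hoc.

    Singleton groups are dropped with a warning.  The LSD table (pairwise
    mean differences with pooled-MSE t-tests, unadjusted P, df = N - k) is
    produced only when the omnibus F-test rejects at ``alpha``; group means
    carry per-group t-based 95% CIs.
    """
    y = np.asarray(trait_values, dtype=float)
    labels = pd.Series(grouping).astype(str)
    dropped = []
    sizes = labels.value_counts()
    for g in sizes.index[sizes < 2]:
        dropped.append(g)
    if dropped:
        warnings.warn(f"dropping singleton groups: {dropped}", stacklevel=2)
        keep = ~labels.isin(dropped).to_numpy()
        y, labels = y[keep], labels[keep].reset_index(drop=True)
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations")
    groups = [y[(labels == g).to_numpy()] for g in names]
    f_stat, p = stats.f_oneway(*groups)
    N, k = len(y), len(names)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - k)
    means = pd.DataFrame(
        {
            "group": names,
            "n": [len(g) for g in groups],
            "mean": [g.mean() for g in groups],
        }
    )
    half = [
        stats.t.ppf(0.975, len(g) - 1) * g.std(ddof=1) / np.sqrt(len(g))
        for g in groups
    ]
    means["ci_low"] = means["mean"] - half
    means["ci_high"] = means["mean"] + half
    lsd = None
    if p <= alpha:
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                diff = groups[i].mean() - groups[j].mean()
                se = np.sqrt(mse * (1 / len(groups[i]) + 1 / len(groups[j])))
                t = diff / se
                rows.append(
                    (
                        names[i],
                        names[j],
                        diff,
                        2 * stats.t.sf(abs(t), N - k),
                    )
                )
        lsd = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "P"])
    return AnovaResult(
        trait, float(f_stat), k - 1, N - k, float(p), means, lsd, dropped
    )


@dataclass
class VarianceProfile:
    trait: str
    groups: list[str]
    variances: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    trend: str  # increasing / decreasing / none
    intermediate_peak: bool


def variance_profile(
    trait_values,
    grouping,
    depth_order: list[str],
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> VarianceProfile:
    """Within-group variance along the depth order with bootstrap 95% CIs.

    A trend is declared only when successive CIs are pairwise disjoint in
    the same direction along the depth order; an interior group whose CI
    sits above both ends flags the hybridization-consistent
    intermediate-peak pattern.  Groups of fewer than 5 observations get no
    CI (and block trend classification).
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(trait_values, dtype=float)
    labels = pd.Series(grouping).astype(str)
    if len(depth_order) < 3:
        raise ValueError("need >= 3 depth-ordered groups")
    missing = sorted(set(depth_order) - set(labels.unique()))
    if missing:
        raise ValueError(f"depth_order names absent from grouping: {missing}")
    var = np.empty(len(depth_order))
    lo = np.full(len(depth_order), np.nan)
    hi = np.full(len(depth_order), np.nan)
    for i, g in enumerate(depth_order):
        vals = y[(labels == g).to_numpy()]
        var[i] = vals.var(ddof=1)
        if len(vals) >= 5:
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boots = vals[idx].var(axis=1, ddof=1)
            lo[i], hi[i] = np.quantile(boots, [0.025, 0.975])
    trend = "none"
    if not np.isnan(lo).any():
        if all(lo[i + 1] > hi[i] for i in range(len(var) - 1)):
            trend = "increasing"
        elif all(hi[i + 1] < lo[i] for i in range(len(var) - 1)):
            trend = "decreasing"
    peak = False
    if not np.isnan(lo).any():
        interior = range(1, len(var) - 1)
        peak = any(
            lo[i] > hi[0] and lo[i] > hi[-1] and var[i] == var.max()
            for i in interior
        )
    return VarianceProfile(
        "trait", list(depth_order), var, lo, hi, trend, peak
    )
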