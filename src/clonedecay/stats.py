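"""Group-comparison tests for mutation counts, spectra and trait tables.

The binomial likelihood-ratio test compares nonsynonymous/total proportions
between groups of counting units (the closed-form group-factor binomial GLM
LRT).  Nesting (SNPs within individuals, individuals within clones) is
handled either by aggregating counts to the nesting unit or by cluster
permutation, which permutes group labels at the cluster level and so
preserves within-cluster dependence.  Permutation p-values use the +1
correction and never return zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import xlogy

__all__ = [
    "TestResult",
    "binomial_lrt",
    "permutation_test",
    "ks_statistic",
    "ks_permutation",
    "pearson_ci",
    "variance_f_test",
    "welch_t",
    "contingency_test",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    n_perm: int | None = None
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# Binomial LRT
# ---------------------------------------------------------------------------

def _binom_ll(k, n, p):
    """Binomial log-likelihood kernel (combinatorial constants omitted: they
    cancel in the likelihood ratio)."""
    return float(xlogy(k, p).sum() + xlogy(n - k, 1.0 - p).sum())


def binomial_lrt(successes, totals, groups) -> TestResult:
    """Likelihood-ratio test of equal success proportions across groups.

    Fits the binomial model with and without the group term; the statistic is
    2 x the log-likelihood difference, compared with chi-square on
    (n_groups - 1) df.  Groups with zero totals are dropped with a warning.
    For nested data, aggregate counts to the nesting unit first or use
    :func:`permutation_test` with clusters.
    """
    k = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    g = np.asarray(groups)
    if np.any(k > n):
        raise ValueError("successes exceed totals")
    labels = [lb for lb in np.unique(g)]
    agg = {lb: (k[g == lb].sum(), n[g == lb].sum()) for lb in labels}
    empty = [lb for lb, (_, tot) in agg.items() if tot == 0]
    if empty:
        warnings.warn(f"dropping zero-total groups: {empty}", stacklevel=2)
        labels = [lb for lb in labels if lb not in empty]
    if len(labels) < 2:
        raise ValueError("binomial LRT needs >= 2 non-empty groups")

    ks = np.array([agg[lb][0] for lb in labels])
    ns = np.array([agg[lb][1] for lb in labels])
    p_pool = ks.sum() / ns.sum()
    p_grp = ks / ns
    ll_null = _binom_ll(ks, ns, np.full(len(labels), p_pool))
    ll_full = _binom_ll(ks, ns, p_grp)
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    df = len(labels) - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(
        method="binomial_lrt", statistic=stat, p_value=p, df=df,
        estimate=float(p_grp[0] - p_grp[-1]) if len(labels) == 2 else None,
        extra={"group_proportions": dict(zip(map(str, labels), map(float, p_grp)))},
    )


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _two_groups(labels):
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    a_mask = labels == uniq[0]
    if a_mask.all() or (~a_mask).all():
        raise ValueError("one group is empty")
    return uniq, a_mask


def _abs_mean_diff(a, b):
    return abs(float(np.mean(a)) - float(np.mean(b)))


def permutation_test(
    values,
    labels,
    statistic_fn=None,
    n_perm: int = 999,
    seed: int = 0,
    clusters=None,
) -> TestResult:
    """Two-group permutation test; p = (1 + #{perm >= obs}) / (1 + n_perm).

    ``statistic_fn(a, b)`` maps the two groups' values to a scalar; larger
    means more extreme (default: absolute difference of means).  With
    ``clusters``, group labels are permuted at the cluster level (every unit
    of a cluster moves together), preserving within-cluster dependence.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if statistic_fn is None:
        statistic_fn = _abs_mean_diff
    uniq, a_mask = _two_groups(labels)
    rng = np.random.default_rng(seed)

    def stat_for(mask):
        return statistic_fn(values[mask], values[~mask])

    obs = stat_for(a_mask)
    hits = 0
    if clusters is None:
        for _ in range(n_perm):
            perm = rng.permutation(a_mask)
            if stat_for(perm) >= obs:
                hits += 1
    else:
        clusters = np.asarray(clusters)
        uc = np.unique(clusters)
        clab = np.array([labels[clusters == c][0] for c in uc])
        for c in uc:
            if not (labels[clusters == c] == clab[uc == c][0]).all():
                raise ValueError(f"cluster {c} spans both groups")
        ca_mask = clab == uniq[0]
        for _ in range(n_perm):
            perm_c = rng.permutation(ca_mask)
            unit_mask = np.isin(clusters, uc[perm_c])
            if stat_for(unit_mask) >= obs:
                hits += 1
    p = (1 + hits) / (1 + n_perm)
    return TestResult(
        method="permutation", statistic=float(obs), p_value=p,
        n_perm=n_perm, seed=seed,
    )


def ks_statistic(a, b) -> float:
    """Two-sample Kolmogorov–Smirnov statistic (max CDF distance)."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    ca = np.searchsorted(a, grid, side="right") / a.size
    cb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(ca - cb).max())


def ks_permutation(dist_a, dist_b, n_perm: int = 999, seed: int = 0) -> TestResult:
    """Permutation Kolmogorov–Smirnov test (vectorised label shuffling)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("one group is empty")
    obs = ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    order = np.argsort(pooled, kind="mergesort")
    rng = np.random.default_rng(seed)
    base = np.zeros(n, dtype=bool)
    base[:na] = True
    perms = np.tile(base, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    m = perms[:, order]  # membership of group A along the sorted pooled values
    ca = np.cumsum(m, axis=1) / na
    cb = np.cumsum(~m, axis=1) / (n - na)
    stats_perm = np.abs(ca - cb).max(axis=1)
    # ties: evaluating CDFs at every pooled point is exact for the sup distance
    hits = int((stats_perm >= obs - 1e-12).sum())
    p = (1 + hits) / (1 + n_perm)
    return TestResult(
        method="ks_permutation", statistic=obs, p_value=p, n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def pearson_ci(x, y, conf: float = 0.95) -> TestResult:
    """Pearson correlation with Fisher-z confidence interval and t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    n = x.size
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = sps.norm.ppf(0.5 + conf / 2)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    else:
        lo = hi = float("nan")
    return TestResult(
        method="pearson", statistic=float(r), p_value=float(p),
        df=n - 2, estimate=float(r), ci_low=float(lo), ci_high=float(hi),
    )


def variance_f_test(a, b) -> TestResult:
    """Two-sided F test of equal variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    F = va / vb
    d1, d2 = a.size - 1, b.size - 1
    p = 2 * min(sps.f.sf(F, d1, d2), sps.f.cdf(F, d1, d2))
    return TestResult(
        method="variance_f", statistic=float(F), p_value=float(min(p, 1.0)),
        df=(d1, d2), estimate=float(va / vb),
    )


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return TestResult(
        method="welch_t", statistic=float(t), p_value=float(p), df=float(df),
        estimate=float(np.mean(a) - np.mean(b)),
    )


def contingency_test(table) -> TestResult:
    """Fisher exact test for 2x2 tables, chi-square otherwise."""
    tab = np.asarray(table, dtype=float)
    if tab.shape == (2, 2):
        odds, p = sps.fisher_exact(tab)
        return TestResult(
            method="fisher_exact", statistic=float(odds), p_value=float(p),
            estimate=float(odds),
        )
    res = sps.chi2_contingency(tab)
    return TestResult(
        method="chi2_contingency", statistic=float(res.statistic),
        p_value=float(res.pvalue), df=float(res.dof),
    )
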