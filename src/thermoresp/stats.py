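"""Classical statistical tests implemented from their formulas.

The pipeline's IPI and delay comparisons rest on four primitives: the
unpaired two-sample t test (pooled-variance Student form by default, Welch
by flag), the paired t test, one-way ANOVA, and Pearson correlation with
ordinary-least-squares slope and intercept.  Test statistics, degrees of
freedom and estimators are computed here from the textbook formulas;
tail probabilities come from the vetted t and F distribution functions in
``scipy.special`` (``stdtr``, ``fdtrc``).

Degenerate-variance conventions (the data can genuinely produce these):

* unpaired, both samples zero variance: equal means -> t = 0, p = 1;
  unequal means -> Welch limit, |t| = inf, p = 0, df clamped >= 1;
* paired, differences have zero spread: zero mean -> t = 0, p = 1;
  nonzero mean -> p = 0; both carry ``degenerate=True``;
* ANOVA with zero between-group scatter -> F = 0, p = 1; zero
  within-group scatter with spread means -> F = inf, p = 0;
* perfectly collinear points -> r = +/-1, p = 0, ``degenerate=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import fdtrc, stdtr

__all__ = [
    "TTestResult",
    "AnovaResult",
    "RegressionResult",
    "ttest_unpaired",
    "ttest_paired",
    "anova_oneway",
    "pearson_r",
    "holm_correction",
]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "mean_diff": self.mean_diff, "degenerate": self.degenerate}


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"F": self.F, "df_between": self.df_between,
                "df_within": self.df_within, "p": self.p,
                "degenerate": self.degenerate}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "r": self.r,
                "p": self.p, "n": self.n, "degenerate": self.degenerate}


def _t_sf2(t: float, df: float) -> float:
    """Two-sided p-value from the t distribution: 2 P(T_df >= |t|)."""
    return float(2.0 * stdtr(df, -abs(t)))


def ttest_unpaired(x, y, variant: str = "pooled") -> TTestResult:
    """Two-sample t test on independent samples.

    ``variant="pooled"`` is the classical Student test with pooled variance
    and df = n1 + n2 - 2; ``variant="welch"`` uses per-sample variances with
    Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    m1, m2 = np.mean(x), np.mean(y)
    v1 = np.var(x, ddof=1)
    v2 = np.var(y, ddof=1)
    diff = float(m1 - m2)

    if v1 == 0 and v2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=float(n1 + n2 - 2), p=1.0,
                               mean_diff=0.0, degenerate=True)
        t = np.inf if diff > 0 else -np.inf
        return TTestResult(t=float(t), df=1.0, p=0.0, mean_diff=diff,
                           degenerate=True)

    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        df = max(float(df), 1.0)
    t = diff / se
    return TTestResult(t=float(t), df=df, p=_t_sf2(t, df), mean_diff=diff)


def ttest_paired(x, y) -> TTestResult:
    """Paired t test: one-sample t on the differences x - y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError(f"paired samples differ in length: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    d = x - y
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = float(n - 1)
    if sd == 0:
        if md == 0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0, degenerate=True)
        t = np.inf if md > 0 else -np.inf
        return TTestResult(t=float(t), df=df, p=0.0, mean_diff=md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    return TTestResult(t=float(t), df=df, p=_t_sf2(t, df), mean_diff=md)


def anova_oneway(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA via the between/within decomposition."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has n = {len(g)} < 2")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    dfb, dfw = k - 1, n - k
    if ssb == 0:
        return AnovaResult(F=0.0, df_between=dfb, df_within=dfw, p=1.0,
                           degenerate=(ssw == 0))
    if ssw == 0:
        return AnovaResult(F=float("inf"), df_between=dfb, df_within=dfw, p=0.0,
                           degenerate=True)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(fdtrc(dfb, dfw, F))
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw, p=p)


def pearson_r(x, y) -> RegressionResult:
    """Pearson correlation with OLS slope/intercept.

    The p-value uses the exact null distribution via
    t = r sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in x or y")
    sxy = float(np.sum(dx * dy))
    r = sxy / np.sqrt(sxx * syy)
    r = min(1.0, max(-1.0, r))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if abs(r) == 1.0:
        return RegressionResult(slope=slope, intercept=intercept, r=r, p=0.0,
                                n=n, degenerate=True)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return RegressionResult(slope=slope, intercept=intercept, r=float(r),
                            p=_t_sf2(t, n - 2), n=n)


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj
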