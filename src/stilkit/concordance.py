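"""Agreement and comparison statistics for multi-reader score panels.

Implements the statistical conventions of a multi-pathologist sTIL reader
study: Lin's concordance correlation coefficient (CCC) with a Fisher-z
asymptotic confidence interval, per-case coefficient of variation (COV)
across raters, nonparametric Bland-Altman limits of agreement at the
2.5th/97.5th percentiles of the paired differences, McNemar's test for
paired concordant/discordant status, and t / chi-squared comparisons.

A score panel is a pandas DataFrame indexed by slide with one column per
reader (NaN = reader did not score that slide). Human and automated readers
are distinguished by the caller; panel operations here treat columns
uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError


@dataclass
class AgreementStat:
    estimate: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class BAResult:
    """Nonparametric Bland-Altman summary: mean difference and the
    2.5th/97.5th percentile limits of agreement."""

    mean_diff: float
    loa_low: float
    loa_high: float
    n: int


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient
# ---------------------------------------------------------------------------


def lins_ccc(x, y, ci_level: float = 0.95) -> AgreementStat:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ρc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with biased (divide-by-n)
    moments, per Lin's original estimator. The confidence interval uses the
    Fisher z-transform with Lin's asymptotic variance (erratum-corrected
    form). Raises DegenerateStatisticError when both vectors are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise DegenerateStatisticError("both vectors constant and equal; CCC undefined")
    if sx2 == 0 and sy2 == 0:
        raise DegenerateStatisticError("both vectors constant; CCC undefined")
    rho_c = 2.0 * sxy / denom

    # CI: Fisher z of rho_c with Lin's asymptotic variance.
    if sx2 == 0 or sy2 == 0 or abs(rho_c) >= 1.0:
        # Pearson r undefined or perfect concordance: CI collapses to the point.
        return AgreementStat(float(rho_c), float(rho_c), float(rho_c), n)
    r = sxy / np.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    if r == 0:
        return AgreementStat(float(rho_c), float("nan"), float("nan"), n)
    rc2 = rho_c**2
    var_z = (
        (1 - r**2) * rc2 / ((1 - rc2) * r**2)
        + 2 * rho_c**3 * (1 - rho_c) * u**2 / (r * (1 - rc2) ** 2)
        - rho_c**4 * u**4 / (2 * r**2 * (1 - rc2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(rho_c)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = np.tanh(z - zcrit * np.sqrt(var_z)), np.tanh(z + zcrit * np.sqrt(var_z))
    return AgreementStat(float(rho_c), float(lo), float(hi), n)


def pairwise_ccc(panel: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise CCC matrix over panel readers (pairwise-complete slides).

    Returns a readers × readers DataFrame of AgreementStat (diagonal:
    estimate 1). A pair sharing fewer than ``min_shared`` slides, or whose
    shared scores are degenerate, is marked unavailable (None).
    """
    readers = list(panel.columns)
    out = pd.DataFrame(index=readers, columns=readers, dtype=object)
    for i, a in enumerate(readers):
        for j, b in enumerate(readers):
            if i == j:
                n = int(panel[a].notna().sum())
                out.loc[a, b] = AgreementStat(1.0, 1.0, 1.0, n)
                continue
            if j < i:
                out.loc[a, b] = out.loc[b, a]
                continue
            shared = panel[[a, b]].dropna()
            if len(shared) < min_shared:
                out.loc[a, b] = None
                continue
            try:
                out.loc[a, b] = lins_ccc(shared[a].to_numpy(), shared[b].to_numpy())
            except DegenerateStatisticError:
                out.loc[a, b] = None
    return out


# ---------------------------------------------------------------------------
# Coefficient of variation across raters
# ---------------------------------------------------------------------------


@dataclass
class CovSummary:
    per_slide: pd.Series
    mean: float
    sd: float
    n: int


def cov_per_case(panel: pd.DataFrame, min_readers: int = 2) -> CovSummary:
    """Per-slide coefficient of variation across readers, plus mean ± SD.

    COV = sample SD (ddof=1) / mean of each slide's scores. Slides with mean
    0 get COV 0 by convention; slides with fewer than ``min_readers``
    non-missing scores are excluded with a warning.
    """
    counts = panel.notna().sum(axis=1)
    excluded = counts < min_readers
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} slide(s) with < {min_readers} readers excluded from COV",
            stacklevel=2,
        )
    sub = panel[~excluded]
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    cov = pd.Series(np.where(means == 0, 0.0, sds / means.replace(0, np.nan)), index=sub.index)
    cov = cov.fillna(0.0)
    return CovSummary(cov, float(cov.mean()), float(cov.std(ddof=1)) if len(cov) > 1 else 0.0, len(cov))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


def bland_altman(x, y) -> BAResult:
    """Nonparametric Bland-Altman analysis of paired scores.

    Differences d = x − y; the centre line is mean(d) and the limits of
    agreement are the 2.5th and 97.5th percentiles of d under the
    h = (n − 1)p + 1 linear-interpolation convention (numpy's default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    d = x - y
    lo, hi = np.percentile(d, [2.5, 97.5], method="linear")
    return BAResult(float(d.mean()), float(lo), float(hi), d.size)


# ---------------------------------------------------------------------------
# McNemar's test
# ---------------------------------------------------------------------------


def mcnemar_test(b: int, c: int, exact_threshold: int = 25) -> float:
    """Two-sided McNemar p-value from the discordant-pair counts.

    Exact binomial when b + c < ``exact_threshold``; otherwise chi-squared
    with continuity correction (|b − c| − 1)² / (b + c). b = c = 0 gives 1.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ValueError("b and c must be non-negative integers")
    b, c = int(b), int(c)
    n = b + c
    if n == 0:
        return 1.0
    if n < exact_threshold:
        p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
        return float(min(p, 1.0))
    statistic = (max(abs(b - c) - 1, 0)) ** 2 / n
    return float(stats.chi2.sf(statistic, df=1))


# ---------------------------------------------------------------------------
# Mean comparisons and categorical tests
# ---------------------------------------------------------------------------


def mean_tests(x, y, paired: bool = False) -> tuple[float, float]:
    """Student's two-sample t (pooled variance) or paired t; returns (t, p).

    Raises DegenerateStatisticError when the relevant variance is zero
    (constant nonzero paired differences, or zero pooled variance). Paired
    samples that agree exactly everywhere return (0, 1) by convention;
    identical groups with spread yield t = 0, p = 1 through the normal path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test needs equal-length vectors")
        d = x - y
        if d.size < 2 or np.var(d, ddof=1) == 0:
            if d.size >= 2 and np.all(d == 0):
                return 0.0, 1.0
            raise DegenerateStatisticError("paired differences have zero variance")
        t, p = stats.ttest_rel(x, y)
        return float(t), float(p)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise DegenerateStatisticError("zero pooled variance; t statistic undefined")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def chi_square_test(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table), correction=correction)
    return float(res.statistic), float(res.pvalue)
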