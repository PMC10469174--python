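"""Neoadjuvant chemotherapy response analysis.

Miller-Payne grades (1-5, tumor-cellularity reduction after neoadjuvant
chemotherapy) are dichotomized into responders (grade 4-5, >90% reduction)
and non-responders (grade 1-3). sTIL scores are stratified into low (<10),
intermediate (10-49) and high (≥50) groups. Binary logistic regression is
fit from first principles by iteratively reweighted least squares (IRLS)
with Wald standard errors from the inverse observed information; odds
ratios are exp(coefficient) with exp(coef ± 1.96·SE) confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .concordance import mean_tests
from .errors import DegenerateStatisticError, InvalidRecordError, SeparationError

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"


@dataclass
class StratumConfig:
    low_cut: float = 10.0
    high_cut: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut <= 100:
            raise InvalidRecordError("need 0 < low_cut < high_cut <= 100")


def mp_responder(grade: int) -> bool:
    """Responder flag from a Miller-Payne grade: grade 4-5 = responder."""
    if grade not in (1, 2, 3, 4, 5):
        raise InvalidRecordError(f"Miller-Payne grade must be in 1..5, got {grade!r}")
    return grade >= 4


def stil_stratum(score: float, cfg: StratumConfig | None = None) -> str:
    """Stratify a sTIL percentage: low (< low_cut), intermediate, high (≥ high_cut)."""
    cfg = cfg or StratumConfig()
    if not 0 <= score <= 100:
        raise InvalidRecordError(f"sTIL score must be in [0, 100], got {score!r}")
    if score < cfg.low_cut:
        return LOW
    if score < cfg.high_cut:
        return INTERMEDIATE
    return HIGH


# ---------------------------------------------------------------------------
# Logistic regression by IRLS
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    odds_ratio: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    p_values: np.ndarray
    n_iter: int
    converged: bool
    log_likelihood: float
    names: list[str]
    ll_path: list[float] | None = None  # per-iteration log-likelihood (non-decreasing)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "odds_ratio": self.odds_ratio,
                "or_ci_low": self.or_ci_low,
                "or_ci_high": self.or_ci_high,
                "p": self.p_values,
            },
            index=self.names,
        )


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log σ(η) for y=1, log σ(−η) for y=0, numerically stable
    return float(np.sum(np.where(y == 1, -np.logaddexp(0, -eta), -np.logaddexp(0, eta))))


def fit_logistic(
    X,
    y,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    ci_level: float = 0.95,
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression via IRLS.

    ``X`` is the full design matrix (include an intercept column yourself or
    via :func:`add_intercept`); ``y`` is a 0/1 outcome. Convergence is the
    max absolute coefficient change falling below ``tol``. Diverging
    coefficients (complete or quasi-complete separation) raise
    SeparationError with the offending estimates attached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n×p and y length n")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    beta = np.zeros(p)
    ll_path = [_log_likelihood(X, y, beta)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = special.expit(X @ beta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = X @ beta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        ll = _log_likelihood(X, y, beta)
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError(
                "coefficients diverging: complete or quasi-complete separation", coefficients=beta
            )
        ll_path.append(ll)
        if step < tol:
            converged = True
            break
    mu = special.expit(X @ beta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    zstat = beta / se
    return LogisticFit(
        coef=beta,
        se=se,
        odds_ratio=np.exp(beta),
        or_ci_low=np.exp(beta - zcrit * se),
        or_ci_high=np.exp(beta + zcrit * se),
        p_values=2.0 * stats.norm.sf(np.abs(zstat)),
        n_iter=it,
        converged=converged,
        log_likelihood=_log_likelihood(X, y, beta),
        names=list(names),
        ll_path=ll_path,
    )


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    return np.column_stack([np.ones(X.shape[0]), X])


def two_by_two_or(a: int, b: int, c: int, d: int, ci_level: float = 0.95) -> tuple[float, float, float]:
    """Closed-form odds ratio ad/bc with the Woolf log-SE √(1/a+1/b+1/c+1/d).

    Reference oracle for the single-binary-predictor logistic fit.
    """
    if min(a, b, c, d) <= 0:
        raise DegenerateStatisticError("all four cells must be positive")
    or_ = a * d / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    return float(or_), float(np.exp(np.log(or_) - zcrit * se)), float(np.exp(np.log(or_) + zcrit * se))


# ---------------------------------------------------------------------------
# Cohort-level response analysis
# ---------------------------------------------------------------------------


def response_analysis(
    cohort: pd.DataFrame,
    score_col: str,
    subset: str = "all",
    stratum_cfg: StratumConfig | None = None,
) -> dict:
    """Responder-vs-non-responder comparison of one sTIL reading mode.

    Computes (i) group mean ± SD with Student's two-sample t, and (ii) a
    logistic fit of responder status on sTIL-stratum indicators
    (high-vs-low, intermediate-vs-low). ``subset`` restricts to one
    molecular subtype ('all', 'HER2_positive', 'TNBC'). Degenerate inputs
    (constant scores, empty strata) mark the affected result unavailable
    rather than raising.
    """
    stratum_cfg = stratum_cfg or StratumConfig()
    df = cohort if subset == "all" else cohort[cohort["subtype"] == subset]
    if df.empty:
        raise InvalidRecordError(f"subset {subset!r} is empty")
    scores = df[score_col].to_numpy(dtype=float)
    resp = df["responder"].to_numpy(dtype=bool)
    out: dict = {
        "subset": subset,
        "score_col": score_col,
        "n": int(len(df)),
        "n_responder": int(resp.sum()),
        "n_non_responder": int((~resp).sum()),
        "mean_responder": float(scores[resp].mean()) if resp.any() else float("nan"),
        "sd_responder": float(scores[resp].std(ddof=1)) if resp.sum() > 1 else float("nan"),
        "mean_non_responder": float(scores[~resp].mean()) if (~resp).any() else float("nan"),
        "sd_non_responder": float(scores[~resp].std(ddof=1)) if (~resp).sum() > 1 else float("nan"),
    }
    try:
        t, p = mean_tests(scores[resp], scores[~resp], paired=False)
        out["t_stat"], out["t_p"] = t, p
    except (DegenerateStatisticError, ValueError):
        out["t_stat"] = out["t_p"] = None

    strata = np.array([stil_stratum(s, stratum_cfg) for s in scores])
    out["stratum_counts"] = {k: int((strata == k).sum()) for k in (LOW, INTERMEDIATE, HIGH)}
    if (strata == LOW).sum() == 0 or ((strata == HIGH).sum() == 0 and (strata == INTERMEDIATE).sum() == 0):
        out["logistic"] = None
        return out
    cols, names = [np.ones(len(df))], ["intercept"]
    contrasts = []
    for level in (INTERMEDIATE, HIGH):
        if (strata == level).sum() > 0:
            cols.append((strata == level).astype(float))
            names.append(f"{level}_vs_low")
            contrasts.append(f"{level}_vs_low")
    X = np.column_stack(cols)
    try:
        fit = fit_logistic(X, resp.astype(float), names=names)
        out["logistic"] = {
            name: {
                "odds_ratio": float(fit.odds_ratio[i]),
                "ci_low": float(fit.or_ci_low[i]),
                "ci_high": float(fit.or_ci_high[i]),
                "p": float(fit.p_values[i]),
            }
            for i, name in enumerate(names)
            if name in contrasts
        }
    except (SeparationError, ValueError):
        out["logistic"] = None
    return out
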