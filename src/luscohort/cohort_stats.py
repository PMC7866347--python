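"""Cohort statistics: exact binomial CIs, contingency and rank tests,
Fleiss' kappa, and logistic regression for the outcome association.

Standard tests are delegated to scipy.stats and statsmodels; this module
fixes the conventions used throughout the package (Clopper-Pearson intervals
by default, Yates continuity correction on 2x2 tables, two-sided tests,
Wald CIs for odds ratios) and returns typed results on the reporting scale
(percentages for proportions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ProportionEstimate",
    "OrEstimate",
    "proportion_ci",
    "chisq_contingency",
    "mann_whitney",
    "kruskal_wallis",
    "fleiss_kappa",
    "logistic_or",
]


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its confidence interval, in percent."""

    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.point <= self.ci_high <= 100:
            raise ValueError("proportion CI must satisfy 0 <= low <= point <= high <= 100")


@dataclass(frozen=True)
class OrEstimate:
    """An odds ratio with 95% Wald CI; ``converged`` False means no estimate."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    adjusted_for: list = field(default_factory=list)
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not (
            0 < self.ci_low <= self.odds_ratio <= self.ci_high
        ):
            raise ValueError("OR CI must satisfy 0 < low <= OR <= high")


def proportion_ci(
    x: int, n: int, method: str = "clopper_pearson", confidence: float = 0.95
) -> ProportionEstimate:
    """Binomial proportion with exact (Clopper-Pearson) or Wilson CI.

    The exact interval uses beta-distribution quantiles; it is the default
    because study-style reporting of small-cohort proportions conventionally
    uses it.  Values are returned in percent.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= x <= n:
        raise ValueError("numerator must lie in [0, n]")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(x, n, alpha=1.0 - confidence, method=sm_method)
    return ProportionEstimate(
        numerator=x,
        denominator=n,
        point=100.0 * x / n,
        ci_low=100.0 * float(lo),
        ci_high=100.0 * float(hi),
        method=method,
    )


def chisq_contingency(
    table: Sequence[Sequence[float]], yates: bool = True
) -> tuple[float, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Yates continuity correction is applied only to 2x2 tables (scipy ignores
    the flag for larger tables, matching convention).  Returns (statistic, p).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact enumeration is used for small samples (n1 + n2 <= 12, no ties);
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    small = a.size + b.size <= 12 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if small else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction; p from chi-square (k-1 df).

    With all pooled values identical (H undefined in scipy) returns (0, 1):
    complete ties carry no evidence against the null.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def fleiss_kappa(ratings: Sequence[Sequence[int]], raters: int) -> float:
    """Fleiss' kappa from an items x categories count matrix.

    Each row must sum to the (fixed) number of raters.  Perfect agreement
    returns exactly 1.0, including the degenerate case where every rater
    puts every item in the same single category (where the chance-agreement
    denominator vanishes).
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise ValueError("ratings must be an items x categories matrix")
    if raters < 2:
        raise ValueError("at least two raters are required")
    if not np.all(table.sum(axis=1) == raters):
        raise ValueError("every row must sum to the rater count")
    # per-item observed agreement
    p_obs = ((table * (table - 1)).sum(axis=1) / (raters * (raters - 1))).mean()
    if p_obs == 1.0:
        return 1.0
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def logistic_or(
    outcome: Sequence[int],
    exposure: Sequence[int],
    covariates: Optional[np.ndarray] = None,
    covariate_names: Optional[list[str]] = None,
) -> OrEstimate:
    """Odds ratio for a binary exposure from a logistic regression.

    Maximum-likelihood fit by Newton/IRLS (tolerance 1e-10 on the score,
    max 50 iterations); the OR is ``exp`` of the exposure coefficient with a
    95% Wald CI.  Complete separation or non-convergence yields
    ``converged=False`` with a diagnostic message and no silent estimate.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and exposure must have equal length")
    names = list(covariate_names) if covariate_names else []
    cols = [x]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != y.size:
            cov = cov.T
        if cov.shape[0] != y.size:
            raise ValueError("covariates must have one row per observation")
        cols.extend(cov[:, j] for j in range(cov.shape[1]))
        if not names:
            names = [f"x{j + 1}" for j in range(cov.shape[1])]
    design = sm.add_constant(np.column_stack(cols), prepend=True)

    def _failed(msg: str) -> OrEstimate:
        return OrEstimate(
            odds_ratio=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            adjusted_for=names,
            converged=False,
            message=msg,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(y, design).fit(
                method="newton", tol=1e-10, maxiter=50, disp=False, warn_convergence=False
            )
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning) as err:
        return _failed(f"separation or singular fit detected: {err}")
    if not fit.mle_retvals.get("converged", False):
        return _failed("IRLS did not converge within 50 iterations")
    beta = fit.params[1]
    se = fit.bse[1]
    if abs(beta) > 15 or not np.isfinite(se):
        return _failed("quasi-complete separation: exposure coefficient diverged")
    z = stats.norm.ppf(0.975)
    return OrEstimate(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        adjusted_for=names,
        converged=True,
    )
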