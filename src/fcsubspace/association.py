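"""Community-size regression, clinical group statistics, and effect sizes.

Covers the behavioral-association stage (OLS of a clinical score on
per-community node counts, with optional symptom covariates and BH-FDR
across the community predictors) and the demographic/clinical comparisons:
Mann-Whitney U with a tie-corrected normal z and r = z/sqrt(N) effect
sizes, the 2x2 Pearson chi-square without continuity correction,
Bonferroni adjustment, and an overall-F power calculation from the
noncentral F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "MannWhitneyResult",
    "fit_size_regression",
    "mann_whitney",
    "chi_square_2x2",
    "effect_size_r",
    "bonferroni",
    "pearson_r",
    "regression_power",
]


@dataclass
class RegressionResult:
    coefficients: pd.DataFrame  # index: predictor; columns: coef, t, p, q
    f_pvalue: float
    r_squared: float
    n: int
    dropped_community: int | None = None


def fit_size_regression(
    sizes: np.ndarray,
    behavior: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    drop_largest: bool = True,
) -> RegressionResult:
    """OLS of a behavioral score on per-community node counts.

    Because community sizes sum to R for every subject, entering all K
    columns alongside an intercept is exactly collinear; the largest
    community's column is dropped by default (``drop_largest=False`` keeps
    all columns and relies on rank checking, which will raise). BH-FDR is
    applied across the community predictors only, not the covariates.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.ndim != 2:
        raise ValueError("sizes must be subjects x communities")
    n, k = x.shape
    names = [f"community_{j}" for j in range(k)]
    dropped = None
    if drop_largest:
        dropped = int(np.argmax(x.sum(axis=0)))
        keep = [j for j in range(k) if j != dropped]
        x = x[:, keep]
        names = [names[j] for j in keep]
    cov_names: list[str] = []
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov_names = list(covariates.columns)
            c = covariates.to_numpy(dtype=float)
        else:
            c = np.atleast_2d(np.asarray(covariates, dtype=float))
            if c.shape[0] != n:
                c = c.T
            cov_names = [f"covariate_{j}" for j in range(c.shape[1])]
        x = np.column_stack([x, c])
        names = names + cov_names
    if n <= x.shape[1] + 1:
        raise ValueError(f"n={n} too small for {x.shape[1]} predictors plus intercept")
    design = sm.add_constant(pd.DataFrame(x, columns=names))
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        resid_rank = [
            col
            for col in design.columns
            if np.linalg.matrix_rank(design.drop(columns=col).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns include {resid_rank}")
    fit = sm.OLS(y, design).fit()
    comm_names = [nm for nm in names if nm.startswith("community_")]
    q = pd.Series(np.nan, index=names)
    _, q_comm, _, _ = multipletests(fit.pvalues[comm_names], method="fdr_bh")
    q[comm_names] = q_comm
    coef = pd.DataFrame(
        {"coef": fit.params[names], "t": fit.tvalues[names], "p": fit.pvalues[names], "q": q}
    )
    return RegressionResult(
        coefficients=coef,
        f_pvalue=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        n=n,
        dropped_community=dropped,
    )


@dataclass
class MannWhitneyResult:
    U: float
    z: float
    p: float
    r: float


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    U is min(U_A, U_B); z carries the sign of (U_A - n_A n_B / 2) and uses
    the tie-corrected standard deviation without continuity correction;
    the effect size is r = z / sqrt(n_A + n_B).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([a, b])
    n = na + nb
    ranks = stats.rankdata(pooled)
    u_a = ranks[:na].sum() - na * (na + 1) / 2
    u_b = na * nb - u_a
    u = min(u_a, u_b)
    mu = na * nb / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(U=float(u), z=0.0, p=1.0, r=0.0)
    z = (u_a - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(U=float(u), z=float(z), p=float(p), r=float(z / np.sqrt(n)))


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in the 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def effect_size_r(z: float, n: int) -> float:
    """r = z / sqrt(N); |r| of .1/.3/.5 read as small/medium/large."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return float(z) / np.sqrt(n)


def bonferroni(p_values, m: int) -> np.ndarray:
    """min(1, m*p) elementwise; m must cover the whole family."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than the {p.size} p-values given")
    return np.minimum(1.0, m * p)


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y)[0])


def regression_power(f2: float, n: int, n_predictors: int, alpha: float = 0.05) -> float:
    """Power of the overall F-test at Cohen's f^2 via the noncentral F.

    Numerator df u = n_predictors, denominator df v = n - u - 1,
    noncentrality lambda = f^2 * n.
    """
    if f2 <= 0:
        raise ValueError("f2 must be positive")
    u = n_predictors
    v = n - u - 1
    if v <= 0:
        raise ValueError("denominator df <= 0")
    nc = f2 * n
    f_crit = stats.f.isf(alpha, u, v)
    return float(stats.ncf.sf(f_crit, u, v, nc))
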