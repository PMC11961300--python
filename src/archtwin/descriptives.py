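"""Cohort descriptives and group comparisons for twin trait tables.

Works on the long twin table (``family_id, twin, zygosity, sex, stage,
trait, value``): means/SDs by zygosity and sex, Bonferroni-corrected
zygosity and sex contrasts, a family-clustered Gaussian comparison (fixed
group effects with a compound-symmetry within-family covariance, fitted
by maximum likelihood), Welch's t-test for unclustered comparisons such
as the attrition check, z-score outlier flagging and a Shapiro-Wilk
normality check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "bonferroni_threshold",
    "group_compare",
    "welch_compare",
    "flag_outliers",
    "normality_check",
    "FamilyGLSFit",
    "fit_family_gls",
]


@dataclass(frozen=True)
class GroupSummary:
    trait: str
    stage: str
    group: str  # overall | MZ | DZ | male | female
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    contrast: str
    estimate: float  # group mean difference (first-named group minus second)
    se: float
    statistic: float
    p_value: float
    method: str
    loglik: Optional[float] = None


@dataclass(frozen=True)
class FamilyGLSFit:
    """ML fit of y = X beta + eps with exchangeable within-family errors."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma: float
    rho: float
    loglik: float
    columns: tuple


def summarize(df: pd.DataFrame) -> list[GroupSummary]:
    """Means and sample SDs (n-1 denominator) per trait x stage for the
    overall sample and the MZ/DZ and male/female subgroups."""
    out: list[GroupSummary] = []
    for (trait, stage), sub in df.groupby(["trait", "stage"], sort=True):
        groups = {
            "overall": sub,
            "MZ": sub[sub.zygosity == "MZ"],
            "DZ": sub[sub.zygosity == "DZ"],
            "male": sub[sub.sex == "M"],
            "female": sub[sub.sex == "F"],
        }
        for label, g in groups.items():
            v = g["value"].dropna()
            if len(v) == 0:
                continue
            out.append(
                GroupSummary(
                    trait=trait,
                    stage=str(stage),
                    group=label,
                    mean=float(v.mean()),
                    sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                    n=int(len(v)),
                )
            )
    return out


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def flag_outliers(values, threshold: float = 3.0) -> np.ndarray:
    """Flag |z| >= threshold; values are reported, never removed."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0:
        return np.zeros(v.shape, dtype=bool)
    return np.abs((v - v.mean()) / sd) >= threshold


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (logged, never gating)."""
    stat, p = stats.shapiro(np.asarray(values, dtype=float))
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# family-clustered Gaussian comparison


def _family_blocks(y: np.ndarray, X: np.ndarray, fam: np.ndarray):
    """Split rows into singleton and size-2 family blocks."""
    order = np.argsort(fam, kind="stable")
    y, X, fam = y[order], X[order], fam[order]
    _, start, counts = np.unique(fam, return_index=True, return_counts=True)
    if np.any(counts > 2):
        raise ValueError("families larger than two members are not supported")
    idx2 = start[counts == 2]
    idx1 = start[counts == 1]
    return y, X, idx2, idx1


def _cs_loglik_terms(y, X, idx2, idx1, sigma2, rho):
    """Sufficient pieces of the compound-symmetry ML problem.

    Returns (XtWX, XtWy, quad_fn, logdet, n) where quad_fn(beta) evaluates
    the GLS quadratic form for given beta.
    """
    p = X.shape[1]
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    logdet = 0.0
    n = y.size
    # 2x2 blocks: Sigma = sigma2 [[1, rho], [rho, 1]]
    if idx2.size:
        det = sigma2**2 * (1 - rho**2)
        logdet += idx2.size * math.log(det)
        w_d = 1.0 / (sigma2 * (1 - rho**2))
        w_o = -rho * w_d
        y1, y2 = y[idx2], y[idx2 + 1]
        X1, X2 = X[idx2], X[idx2 + 1]
        XtWX += w_d * (X1.T @ X1 + X2.T @ X2) + w_o * (X1.T @ X2 + X2.T @ X1)
        XtWy += w_d * (X1.T @ y1 + X2.T @ y2) + w_o * (X1.T @ y2 + X2.T @ y1)
    if idx1.size:
        logdet += idx1.size * math.log(sigma2)
        Xs, ys = X[idx1], y[idx1]
        XtWX += (Xs.T @ Xs) / sigma2
        XtWy += (Xs.T @ ys) / sigma2

    def quad(beta):
        q = 0.0
        if idx2.size:
            r1 = y[idx2] - X[idx2] @ beta
            r2 = y[idx2 + 1] - X[idx2 + 1] @ beta
            w_d = 1.0 / (sigma2 * (1 - rho**2))
            w_o = -rho * w_d
            q += w_d * (r1 @ r1 + r2 @ r2) + 2 * w_o * (r1 @ r2)
        if idx1.size:
            r = y[idx1] - X[idx1] @ beta
            q += (r @ r) / sigma2
        return q

    return XtWX, XtWy, quad, logdet, n


def fit_family_gls(
    y, X, family_ids, columns=(), rho_free: bool = True
) -> FamilyGLSFit:
    """Maximum-likelihood fit of a Gaussian fixed-effects model with an
    exchangeable (compound-symmetry) covariance within twin families.

    The fixed effects are profiled out by GLS at each candidate
    (sigma, rho); the two variance parameters are optimised on
    unconstrained scales (log sigma, atanh rho). ``rho_free=False`` pins
    the within-family correlation at zero (independence model), which is
    useful as a nested baseline.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    fam = np.asarray(family_ids)
    y, X, idx2, idx1 = _family_blocks(y, X, fam)

    def negll(theta):
        sigma2 = math.exp(2.0 * theta[0])
        rho = math.tanh(theta[1]) if rho_free else 0.0
        XtWX, XtWy, quad, logdet, n = _cs_loglik_terms(y, X, idx2, idx1, sigma2, rho)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return 1e12
        return 0.5 * (n * math.log(2 * math.pi) + logdet + quad(beta))

    x0 = [math.log(max(y.std(), 1e-6)), 0.3 if rho_free else 0.0]
    if rho_free:
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        theta = res.x
    else:
        res = optimize.minimize_scalar(lambda a: negll([a, 0.0]),
                                       bounds=(-20, 20), method="bounded",
                                       options={"xatol": 1e-12})
        theta = [res.x, 0.0]
    sigma2 = math.exp(2.0 * theta[0])
    rho = math.tanh(theta[1]) if rho_free else 0.0
    XtWX, XtWy, quad, logdet, n = _cs_loglik_terms(y, X, idx2, idx1, sigma2, rho)
    beta = np.linalg.solve(XtWX, XtWy)
    cov = np.linalg.inv(XtWX)
    ll = -0.5 * (n * math.log(2 * math.pi) + logdet + quad(beta))
    return FamilyGLSFit(beta=beta, cov_beta=cov, sigma=math.sqrt(sigma2),
                        rho=rho, loglik=float(ll), columns=tuple(columns))


def welch_compare(a, b, contrast: str = "") -> ComparisonResult:
    """Welch two-sample t-test (unequal variances)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = stats.ttest_ind(a, b, equal_var=False)
    se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return ComparisonResult(
        contrast=contrast,
        estimate=float(a.mean() - b.mean()),
        se=float(se),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="welch_t",
    )


_CONTRASTS = {
    "MZ_vs_DZ": ("zygosity", "MZ", "DZ"),
    "M_vs_F": ("sex", "M", "F"),
}


def group_compare(
    df: pd.DataFrame, contrast: str, clustered: bool = True
) -> ComparisonResult:
    """Compare trait means between zygosity or sex groups.

    Clustered: ML fit of value ~ sex + zygosity (+ stage dummies when
    several stages are present) with an exchangeable within-family
    covariance; Wald z-test on the contrast coefficient. Unclustered:
    Welch's t-test on the two raw groups (used for the attrition
    comparison).
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    col, lvl_a, lvl_b = _CONTRASTS[contrast]
    sub = df.dropna(subset=["value"])
    a = sub.loc[sub[col] == lvl_a, "value"].to_numpy()
    b = sub.loc[sub[col] == lvl_b, "value"].to_numpy()
    if min(a.size, b.size) < 2:
        raise ValueError(f"contrast {contrast}: each group needs >= 2 observations")
    if not clustered:
        return welch_compare(a, b, contrast)

    cols = ["intercept", "sex_M", "zygosity_MZ"]
    design = [
        np.ones(len(sub)),
        (sub["sex"] == "M").to_numpy(float),
        (sub["zygosity"] == "MZ").to_numpy(float),
    ]
    stages = sorted(sub["stage"].unique())
    for s in stages[1:]:
        cols.append(f"stage_{s}")
        design.append((sub["stage"] == s).to_numpy(float))
    X = np.column_stack(design)
    fit = fit_family_gls(sub["value"].to_numpy(), X, sub["family_id"].to_numpy(), cols)
    j = cols.index("sex_M" if col == "sex" else "zygosity_MZ")
    est = float(fit.beta[j])
    se = math.sqrt(fit.cov_beta[j, j])
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult(
        contrast=contrast, estimate=est, se=se, statistic=float(z),
        p_value=float(p), method="family_gls_wald", loglik=fit.loglik,
    )
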