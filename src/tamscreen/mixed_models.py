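"""Random-intercept linear mixed models fitted by (restricted) maximum likelihood.

The model is y = X beta + Z u + e with a single grouping factor (donor),
u ~ N(0, sigma2_d I) and e ~ N(0, sigma2_e I). The fit profiles beta and
sigma2_e out in closed form via generalized least squares, leaving a
one-dimensional optimization over the variance ratio theta = sigma2_d /
sigma2_e. For a random intercept the per-donor covariance blocks are
I + theta * J, whose inverse (I - theta/(1 + theta n_i) J) and log-determinant
(log(1 + theta n_i)) are available in closed form, so each likelihood
evaluation is O(n).

Downstream conveniences cover the study's analyses: the donor intraclass
correlation ICC = sigma2_d / (sigma2_d + sigma2_e) with its likelihood-ratio
test against ordinary least squares, Tukey-Kramer pairwise contrasts for
treatment factors, Nakagawa marginal/conditional R^2, the
inverse-transformed dose-response fit, the exosomal/free VEGF ratio, and the
battery of two-group / one-sample comparisons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("tamscreen")

__all__ = [
    "MixedModelFit",
    "ContrastResult",
    "fit_random_intercept",
    "lrt_random_intercept",
    "pairwise_contrasts",
    "fixed_effect_ftest",
    "treatment_design",
    "r2_nakagawa",
    "dose_response_fit",
    "exosome_vegf_ratio",
    "two_group_compare",
    "ols_loglik",
]

_THETA_MAX = 1e6


@dataclass
class MixedModelFit:
    """Converged random-intercept fit.

    Fixed coefficients are in response units; sigma2_donor / sigma2_resid in
    squared response units; icc = sigma2_donor / (sigma2_donor +
    sigma2_resid). df_denominator = n_obs - rank(X) - (n_donors - 1), a
    containment-style approximation.
    """

    beta: np.ndarray
    beta_se: np.ndarray
    beta_ci: np.ndarray  # (p, 2)
    coef_names: list[str]
    sigma2_donor: float
    sigma2_resid: float
    icc: float
    loglik: float
    n_obs: int
    n_donors: int
    df_denominator: int
    method: str
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")
    cov_beta: np.ndarray = field(default=None, repr=False)
    theta: float = field(default=float("nan"), repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_names,
                "estimate": self.beta,
                "se": self.beta_se,
                "ci_lo": self.beta_ci[:, 0],
                "ci_hi": self.beta_ci[:, 1],
            }
        )


@dataclass
class ContrastResult:
    """One Tukey-Kramer pairwise contrast between factor levels."""

    pair: tuple[str, str]
    estimate: float
    se: float
    df: int
    t: float
    p_adjusted: float


def _group_structure(donor: Sequence) -> tuple[np.ndarray, np.ndarray, int]:
    codes, _ = pd.factorize(np.asarray(donor), sort=True)
    q = codes.max() + 1
    counts = np.bincount(codes, minlength=q)
    return codes, counts, q


def _profile_quantities(
    theta: float, y: np.ndarray, X: np.ndarray, codes: np.ndarray, counts: np.ndarray
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """GLS beta, profiled residual quadratic form, log|V0|, and XtWX at theta.

    W = V0^{-1} with V0 = I + theta ZZ': per donor block inverse is
    I - theta/(1+theta n_i) J, applied without forming the matrix.
    """
    shrink = theta / (1.0 + theta * counts)  # per donor
    # Accumulate group sums
    def wprod(A: np.ndarray) -> np.ndarray:
        # W @ A for column(s) A
        if A.ndim == 1:
            gs = np.bincount(codes, weights=A, minlength=len(counts))
            return A - shrink[codes] * gs[codes]
        out = np.empty_like(A)
        for j in range(A.shape[1]):
            out[:, j] = wprod(A[:, j])
        return out

    WX = wprod(X)
    Wy = wprod(y)
    XtWX = X.T @ WX
    XtWy = X.T @ Wy
    beta = np.linalg.solve(XtWX, XtWy)
    r = y - X @ beta
    quad = float(r @ wprod(r))
    logdet_v0 = float(np.sum(np.log1p(theta * counts)))
    return beta, quad, logdet_v0, XtWX


def _profiled_loglik(
    theta: float, y: np.ndarray, X: np.ndarray, codes: np.ndarray, counts: np.ndarray,
    method: str,
) -> float:
    n, p = X.shape
    beta, quad, logdet_v0, XtWX = _profile_quantities(theta, y, X, codes, counts)
    if method == "ml":
        s2 = quad / n
        if s2 <= 0:
            return -np.inf
        return -0.5 * (n * math.log(2 * math.pi * s2) + logdet_v0 + n)
    s2 = quad / (n - p)
    if s2 <= 0:
        return -np.inf
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * math.log(2 * math.pi * s2) + logdet_v0 + logdet_xwx + (n - p)
    )


def fit_random_intercept(
    y,
    design,
    donor,
    method: Literal["ml", "reml"] = "ml",
    coef_names: list[str] | None = None,
) -> MixedModelFit:
    """Fit y = X beta + u_donor + e by profiled (RE)ML.

    The likelihood is maximized over theta = sigma2_d/sigma2_e by bounded
    scalar optimization on log(theta) refined to high precision, with the
    boundary theta = 0 checked explicitly (no-donor-effect fits land exactly
    on the boundary instead of a spurious interior optimum). beta and
    sigma2_e come from generalized least squares at the optimum.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and design row count differ")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R = np.linalg.qr(X)
        aliased = [i for i in range(p) if abs(R[min(i, R.shape[0] - 1), i]) < 1e-10]
        names = coef_names or [f"x{i}" for i in range(p)]
        raise ValueError(f"singular design; aliased columns: {[names[i] for i in aliased]}")
    if n <= rank:
        raise ValueError("need n_obs > rank(design)")
    codes, counts, q = _group_structure(donor)
    if q < 2:
        raise ValueError("random effect unidentifiable: need >= 2 donors")

    def neg_ll_log(lt: float) -> float:
        return -_profiled_loglik(math.exp(lt), y, X, codes, counts, method)

    # coarse log-spaced grid then high-precision Brent refinement
    grid = np.linspace(math.log(1e-8), math.log(_THETA_MAX), 61)
    vals = np.array([neg_ll_log(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg_ll_log, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    theta = math.exp(res.x)
    ll = -res.fun
    ll0 = _profiled_loglik(0.0, y, X, codes, counts, method)
    if ll0 >= ll - 1e-12:
        theta, ll = 0.0, ll0

    beta, quad, _, XtWX = _profile_quantities(theta, y, X, codes, counts)
    s2e = quad / n if method == "ml" else quad / (n - p)
    s2d = theta * s2e
    icc = s2d / (s2d + s2e) if (s2d + s2e) > 0 else 0.0
    cov_beta = s2e * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    df_den = n - rank - (q - 1)
    tcrit = stats.t.ppf(0.975, df=max(df_den, 1))
    ci = np.column_stack([beta - tcrit * se, beta + tcrit * se])
    fit = MixedModelFit(
        beta=beta,
        beta_se=se,
        beta_ci=ci,
        coef_names=coef_names or [f"x{i}" for i in range(p)],
        sigma2_donor=float(s2d),
        sigma2_resid=float(s2e),
        icc=float(icc),
        loglik=float(ll),
        n_obs=n,
        n_donors=int(q),
        df_denominator=int(df_den),
        method=method,
        cov_beta=cov_beta,
        theta=float(theta),
    )
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit, X)
    return fit


def ols_loglik(y, design) -> float:
    """Gaussian ML log-likelihood of the ordinary least-squares fit."""
    y = np.asarray(y, float).ravel()
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    n = len(y)
    s2 = float(r @ r) / n
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


def lrt_random_intercept(fit_full: MixedModelFit, y, design) -> tuple[float, int, float, float]:
    """LRT of the donor random intercept against OLS with the same fixed effects.

    Returns (chi2, df=1, p_chi2_df1, p_boundary) where p_chi2_df1 follows
    the plain chi-square(1) convention and p_boundary the boundary-corrected
    0.5*chi2_0 + 0.5*chi2_1 mixture (always <= the plain p).
    """
    if fit_full.method != "ml":
        raise ValueError("LRT requires an ML fit; refit with method='ml'")
    ll0 = ols_loglik(y, design)
    chi2 = max(0.0, 2.0 * (fit_full.loglik - ll0))
    p_plain = float(stats.chi2.sf(chi2, df=1))
    p_boundary = 0.5 * p_plain if chi2 > 0 else 1.0
    return chi2, 1, p_plain, p_boundary


def pairwise_contrasts(
    fit: MixedModelFit, factor_levels: list[str]
) -> list[ContrastResult]:
    """Tukey-Kramer adjusted all-pairs contrasts of a single treatment factor.

    The design must be intercept + reference-coded dummies for
    ``factor_levels`` (first level = reference), as produced by
    :func:`treatment_design`. Adjustment uses the studentized-range
    distribution with the fit's denominator df.
    """
    k = len(factor_levels)
    if k < 2:
        raise ValueError("factor needs >= 2 levels")
    if len(fit.beta) != k:
        raise ValueError("design/levels mismatch: expected intercept + k-1 dummies")
    # cell means: mu_1 = b0, mu_j = b0 + b_j
    L = np.zeros((k, k))
    L[:, 0] = 1.0
    for j in range(1, k):
        L[j, j] = 1.0
    mu = L @ fit.beta
    cov_mu = L @ fit.cov_beta @ L.T
    df = max(fit.df_denominator, 1)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        est = mu[j] - mu[i]
        var = cov_mu[i, i] + cov_mu[j, j] - 2 * cov_mu[i, j]
        se = math.sqrt(max(var, 0.0))
        t = est / se if se > 0 else np.inf * np.sign(est)
        p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
        out.append(
            ContrastResult(
                pair=(factor_levels[j], factor_levels[i]),
                estimate=float(est),
                se=se,
                df=df,
                t=float(t),
                p_adjusted=min(max(p, np.nextafter(0, 1)), 1.0),
            )
        )
    return out


def fixed_effect_ftest(fit: MixedModelFit, term_indices: Sequence[int]) -> tuple[float, int, int, float]:
    """Wald F-test of a block of fixed-effect coefficients.

    F = (L beta)' (L C L')^{-1} (L beta) / rank(L) with C the fitted
    coefficient covariance, referred to F(rank(L), df_denominator)
    (containment denominator df). Returns (F, df1, df2, p).
    """
    idx = list(term_indices)
    b = fit.beta[idx]
    C = fit.cov_beta[np.ix_(idx, idx)]
    df1 = len(idx)
    F = float(b @ np.linalg.solve(C, b)) / df1
    df2 = max(fit.df_denominator, 1)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def treatment_design(condition: Sequence) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded dummy design for one categorical factor."""
    cond = pd.Categorical(np.asarray(condition))
    levels = list(cond.categories)
    X = np.column_stack(
        [np.ones(len(cond))] + [(cond.codes == j).astype(float) for j in range(1, len(levels))]
    )
    return X, levels


def r2_nakagawa(fit: MixedModelFit, design) -> tuple[float, float]:
    """Marginal and conditional R^2 of a random-intercept fit.

    r2_marginal = var(X beta) / (var(X beta) + sigma2_d + sigma2_e);
    conditional adds sigma2_d to the numerator.
    """
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    fitted = X @ fit.beta
    s2f = float(np.var(fitted))
    total = s2f + fit.sigma2_donor + fit.sigma2_resid
    if total <= 0:
        raise ValueError("zero total variance")
    return s2f / total, (s2f + fit.sigma2_donor) / total


def dose_response_fit(
    table: pd.DataFrame,
    transform: Literal["inverse", "identity"] = "inverse",
    method: Literal["ml", "reml"] = "ml",
) -> tuple[MixedModelFit, pd.DataFrame]:
    """Mixed-model dose-response fit with optional inverse transformation.

    ``table`` has columns donor, dose, response. With transform="inverse"
    the model is 1/response ~ dose + (1 | donor); predicted means per dose
    are back-transformed as 1 / fitted. Returns (fit, predictions frame).
    """
    for col in ("donor", "dose", "response"):
        if col not in table.columns:
            raise ValueError(f"dose table missing column {col!r}")
    if table["dose"].nunique() < 2:
        raise ValueError("dose effect unidentifiable: need >= 2 dose levels")
    y = table["response"].to_numpy(float)
    if transform == "inverse":
        bad = np.flatnonzero(y <= 0)
        if bad.size:
            raise ValueError(f"non-positive responses under inverse transform at rows {bad.tolist()}")
        resp = 1.0 / y
    else:
        resp = y
    dose = table["dose"].to_numpy(float)
    X = np.column_stack([np.ones_like(dose), dose])
    fit = fit_random_intercept(resp, X, table["donor"], method=method,
                               coef_names=["intercept", "dose"])
    doses = np.sort(table["dose"].unique())
    lin = fit.beta[0] + fit.beta[1] * doses
    pred = 1.0 / lin if transform == "inverse" else lin
    predictions = pd.DataFrame({"dose": doses, "predicted_mean": pred})
    return fit, predictions


def exosome_vegf_ratio(lysed_exosome_vegf: float, depleted_vegf: float) -> float:
    """Ratio of exosome-associated to free VEGF in volume-matched fractions.

    NaN (with a logged warning) when the free-VEGF denominator is not
    positive.
    """
    if depleted_vegf <= 0:
        logger.warning("exosome_vegf_ratio undefined: depleted fraction VEGF <= 0")
        return float("nan")
    return float(lysed_exosome_vegf) / float(depleted_vegf)


def two_group_compare(
    a,
    b=None,
    reference: float | None = None,
    test: Literal["welch_t", "student_t", "wilcoxon", "kruskal", "one_sample_t"] = "welch_t",
    groups: list | None = None,
    normality_check: bool = False,
) -> dict:
    """Two-group / multi-group / one-sample location comparisons.

    welch_t (default) and student_t are two-sided t-tests; wilcoxon is the
    exact-when-possible rank-sum test; kruskal takes ``groups`` (a list of
    samples); one_sample_t compares ``a`` to ``reference``. With
    normality_check on, a Shapiro-Wilk pre-test at alpha = 0.05 on each
    group routes to wilcoxon on failure and welch_t otherwise (decision
    logged).
    """
    a = np.asarray(a, float)
    if normality_check and test in ("welch_t", "student_t", "wilcoxon"):
        samples = [a] + ([np.asarray(b, float)] if b is not None else [])
        normal = all(stats.shapiro(s).pvalue > 0.05 for s in samples if len(s) >= 3)
        routed = "welch_t" if normal else "wilcoxon"
        logger.info("two_group_compare: Shapiro-Wilk routing chose %s", routed)
        test = routed
    if test == "one_sample_t":
        if reference is None:
            raise ValueError("one_sample_t requires a reference value")
        if np.ptp(a) == 0:
            # zero-variance sample: statistic 0/p 1 at the reference, else undefined
            if a[0] == reference:
                return {"test": test, "statistic": 0.0, "df": len(a) - 1, "p": 1.0, "ci": (a[0], a[0])}
        res = stats.ttest_1samp(a, popmean=reference)
        ci = res.confidence_interval()
        return {"test": test, "statistic": float(res.statistic), "df": int(res.df),
                "p": float(res.pvalue), "ci": (float(ci.low), float(ci.high))}
    if test == "kruskal":
        if groups is None or len(groups) < 2:
            raise ValueError("kruskal requires groups=[sample, sample, ...]")
        res = stats.kruskal(*groups)
        return {"test": test, "statistic": float(res.statistic),
                "df": len(groups) - 1, "p": float(res.pvalue), "ci": None}
    if b is None:
        raise ValueError(f"{test} requires a second sample")
    b = np.asarray(b, float)
    if test in ("welch_t", "student_t"):
        res = stats.ttest_ind(a, b, equal_var=(test == "student_t"))
        ci = res.confidence_interval()
        return {"test": test, "statistic": float(res.statistic), "df": float(res.df),
                "p": float(res.pvalue), "ci": (float(ci.low), float(ci.high))}
    if test == "wilcoxon":
        method = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return {"test": test, "statistic": float(res.statistic), "df": None,
                "p": float(res.pvalue), "ci": None}
    raise ValueError(f"unknown test {test!r}")
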