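"""Spearman rank-correlation machinery for the phenotype screens.

Two uses: the 21 pairwise cytokine-cytokine correlations of donor-averaged
polarization scores, and the genome-wide screen of each gene's expression
against an analyte's modified z-scores. Multiple testing is controlled by
Benjamini-Hochberg step-up everywhere, plus a Storey-type q-value
(pi0 estimated at lambda = 0.5) for the gene screen.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionBundle
from .scoring import PolarizationScoreMatrix

logger = logging.getLogger("tamscreen")

__all__ = [
    "spearman_rho",
    "spearman_pvalue",
    "adjust_fdr",
    "pairwise_cytokine_correlations",
    "gene_score_screen",
]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with mid-rank tie handling.

    Pearson correlation of average ranks; NaN when either ranked vector has
    zero variance (e.g. a constant input).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_rho needs two equal-length vectors, n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("spearman_rho: zero rank variance, correlation undefined")
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _exact_null_rhos(n: int) -> np.ndarray:
    """|rho| over all n! rank permutations of an untied sample (n <= 9)."""
    base = np.arange(1, n + 1, dtype=float)
    base = base - base.mean()
    denom = base @ base
    out = np.empty(math.factorial(n))
    for i, perm in enumerate(itertools.permutations(base)):
        out[i] = base @ np.asarray(perm) / denom
    return out


def spearman_pvalue(
    rho: float, n: int, method: Literal["exact_enumeration", "t_approx"] = "t_approx",
    ties: bool = False,
) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    exact_enumeration (n <= 9, no ties) counts the fraction of the n! rank
    permutations with |rho| at least as large as observed; t_approx uses
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.
    """
    if np.isnan(rho):
        return float("nan")
    if n < 3:
        raise ValueError("n >= 3 required")
    if method == "exact_enumeration":
        if ties:
            logger.warning("exact Spearman p requested with ties; using t approximation")
        elif n <= 9:
            null = _exact_null_rhos(n)
            return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        else:
            logger.warning("exact Spearman p only enumerated for n <= 9; using t approximation")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def adjust_fdr(p_values, method: Literal["bh", "storey"] = "bh") -> np.ndarray:
    """BH step-up adjusted p-values or Storey q-values.

    NaN entries propagate as NaN and are excluded from the effective number
    of tests m. Storey estimates pi0 at lambda = 0.5 as
    min(1, #{p > 0.5} / (0.5 m)) and enforces cumulative-min monotonicity.
    """
    p = np.asarray(p_values, float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    if method == "bh":
        scale = m / np.arange(1, m + 1)
    elif method == "storey":
        pi0 = min(1.0, np.sum(pv > 0.5) / (0.5 * m)) if m else 1.0
        pi0 = max(pi0, 1.0 / m)
        scale = pi0 * m / np.arange(1, m + 1)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    adj = np.minimum.accumulate((ranked * scale)[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def pairwise_cytokine_correlations(
    score_matrix: PolarizationScoreMatrix,
    p_method: Literal["exact_enumeration", "t_approx"] = "t_approx",
) -> pd.DataFrame:
    """All unordered analyte-pair Spearman correlations of per-unit mean scores.

    For 7 retained analytes this yields exactly C(7,2) = 21 rows. BH
    adjustment spans all pairs; pairs sharing fewer than 3 units are
    reported with missing statistics.
    """
    analytes = score_matrix.retained_analytes
    if len(analytes) < 2:
        raise ValueError("need >= 2 retained analytes")
    wide = score_matrix.per_unit.pivot(index="unit", columns="analyte", values="mean_score")
    wide = wide.drop(index=[u for u in score_matrix.control_units if u in wide.index])
    rows = []
    for a, b in itertools.combinations(sorted(analytes), 2):
        sub = wide[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            rows.append({"analyte_a": a, "analyte_b": b, "rho": np.nan, "p_raw": np.nan, "n": n})
            continue
        rho = spearman_rho(sub[a], sub[b])
        has_ties = sub[a].duplicated().any() or sub[b].duplicated().any()
        p = spearman_pvalue(rho, n, p_method, ties=has_ties)
        rows.append({"analyte_a": a, "analyte_b": b, "rho": rho, "p_raw": p, "n": n})
    df = pd.DataFrame(rows)
    df["p_adj_bh"] = adjust_fdr(df["p_raw"], "bh")
    return df


def gene_score_screen(
    bundle: ExpressionBundle,
    score_matrix: PolarizationScoreMatrix,
    analyte: str,
    matrix_choice: Literal["normalized", "counts_tpm_both"] = "normalized",
    q_method: Literal["storey", "bh"] = "storey",
) -> pd.DataFrame:
    """Genome-wide Spearman screen of gene expression vs polarization score.

    For each gene with non-zero expression variance across the shared
    samples, correlates its expression (normalized matrix by default, or
    both matrices reported separately) with the analyte's donor-mean
    modified z-scores. Returns one row per gene (and per matrix) with rho,
    raw p (t approximation), BH-adjusted p and Storey q-value.
    """
    scores = score_matrix.unit_scores(analyte)
    shared = [s for s in bundle.sample_ids if s in scores.index]
    if not shared:
        raise ValueError("no shared samples between expression bundle and scores")
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(shared)}")
    y = scores.loc[shared].to_numpy(float)
    matrices = (
        {"normalized": bundle.normalized}
        if matrix_choice == "normalized"
        else {"counts": bundle.counts.astype(float), "normalized": bundle.normalized}
    )
    frames = []
    ry = stats.rankdata(y)
    ry_c = ry - ry.mean()
    ry_norm = math.sqrt(ry_c @ ry_c)
    n = len(shared)
    for label, mat in matrices.items():
        X = mat[shared].to_numpy(float)
        var_ok = np.ptp(X, axis=1) > 0
        n_dropped = int((~var_ok).sum())
        if n_dropped:
            logger.info("gene_score_screen[%s]: excluded %d zero-variance gene(s)", label, n_dropped)
        Xv = X[var_ok]
        rx = np.apply_along_axis(stats.rankdata, 1, Xv)
        rx_c = rx - rx.mean(axis=1, keepdims=True)
        rho = (rx_c @ ry_c) / (np.sqrt(np.einsum("ij,ij->i", rx_c, rx_c)) * ry_norm)
        rho = np.clip(rho, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.abs(rho) >= 1.0] = 0.0
        df = pd.DataFrame(
            {
                "gene": np.asarray(bundle.gene_ids)[var_ok],
                "rho": rho,
                "p_raw": p,
                "n": n,
                "matrix_used": label,
            }
        )
        df["p_adj_bh"] = adjust_fdr(df["p_raw"], "bh")
        df["q_value"] = adjust_fdr(df["p_raw"], q_method)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["analyte"] = analyte
    return out
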