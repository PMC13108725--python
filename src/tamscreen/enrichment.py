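"""Pre-ranked gene set enrichment analysis (weighted Kolmogorov-Smirnov).

Given a gene list ranked by a signed metric (here the shrunken log2
fold-changes from the quartile DE stage), each gene set's enrichment score
(ES) is the maximal deviation from zero of a running sum that steps up by
|metric|^p / sum_hits |metric|^p at member positions and down by
1/(N - N_hit) elsewhere. Significance comes from a gene-permutation null:
random member sets of the same size scored on the fixed ranking. The
normalized enrichment score (NES) divides the ES by the mean |null ES| of
matching sign; permutation p-values use the add-one estimator and are
BH-adjusted across sets, with a classic GSEA-style FDR q reported
alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import adjust_fdr
from .io import GeneSetCollection

logger = logging.getLogger("tamscreen")

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "null_es_distribution",
    "preranked_gsea",
]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    p_adj: float
    fdr_q: float
    size_used: int
    gene_ratio: float
    leading_edge: list[str]


def _prepare_ranking(ranked: list[tuple[str, float]]) -> tuple[np.ndarray, np.ndarray]:
    genes = np.array([g for g, _ in ranked])
    scores = np.array([s for _, s in ranked], float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    # stable sort: descending score, ties broken by gene id for determinism
    order = np.lexsort((genes, -scores))
    return genes[order], scores[order]


def _es_from_positions(
    scores_sorted: np.ndarray, hit_pos: np.ndarray, p: float
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for member positions on a sorted ranking."""
    N = len(scores_sorted)
    n_hit = len(hit_pos)
    if n_hit == 0 or n_hit >= N:
        raise ValueError("need 1 <= |members in ranking| < N")
    weights = np.abs(scores_sorted[hit_pos]) ** p
    wsum = weights.sum()
    if wsum == 0:  # all hit scores exactly zero: fall back to unweighted steps
        weights = np.ones(n_hit)
        wsum = float(n_hit)
    steps = np.full(N, -1.0 / (N - n_hit))
    steps[hit_pos] = weights / wsum
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def enrichment_score(
    ranked: list[tuple[str, float]], members, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score for one gene set.

    Returns (es, running_sum, leading_edge). The leading edge holds the
    member genes at or before the running-sum extremum for positive ES, and
    at or after it for negative ES.
    """
    genes, scores = _prepare_ranking(ranked)
    member_mask = np.isin(genes, list(members))
    hit_pos = np.flatnonzero(member_mask)
    if hit_pos.size == 0:
        raise KeyError("no gene-set members present in the ranking")
    if hit_pos.size == len(genes):
        raise ValueError("gene set covers the entire ranking (miss step undefined)")
    es, running = _es_from_positions(scores, hit_pos, weight_exponent)
    ext = int(np.argmax(np.abs(running)))
    if es >= 0:
        le = genes[hit_pos[hit_pos <= ext]]
    else:
        le = genes[hit_pos[hit_pos >= ext]]
    return es, running, list(le)


def null_es_distribution(
    ranked: list[tuple[str, float]],
    set_size: int,
    n_permutations: int,
    seed: int | np.random.Generator = 0,
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Gene-permutation null: ES of uniformly random member sets of the given
    size, scored on the fixed ranking. Reproducible under the seed."""
    if n_permutations < 100:
        raise ValueError("n_permutations >= 100 required")
    genes, scores = _prepare_ranking(ranked)
    N = len(genes)
    if set_size >= N:
        raise ValueError("set_size must be < number of ranked genes")
    if set_size == N - 1:
        logger.info("null_es_distribution: near-degenerate set size N-1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    absw = np.abs(scores) ** weight_exponent
    miss = -1.0 / (N - set_size)
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        pos = np.sort(rng.choice(N, size=set_size, replace=False))
        w = absw[pos]
        wsum = w.sum()
        if wsum == 0:
            w = np.ones(set_size)
            wsum = float(set_size)
        # running sum evaluated only where extrema can occur: at each hit
        # (local peak) and just before the next hit (local trough)
        hits_cum = np.cumsum(w / wsum)
        at_hit = hits_cum + (pos - np.arange(set_size)) * miss
        next_pos = np.append(pos[1:], N)
        before_next = hits_cum + (next_pos - 1 - np.arange(set_size)) * miss
        cand = np.concatenate([at_hit, before_next])
        # also the pre-first-hit trough
        if pos[0] > 0:
            cand = np.append(cand, pos[0] * miss)
        out[b] = cand[np.argmax(np.abs(cand))]
    return out


def preranked_gsea(
    ranked: list[tuple[str, float]],
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    min_size: int = 10,
    max_size: int = 500,
    seed: int = 0,
    alpha: float = 0.25,
    nes_min: float = 1.0,
) -> pd.DataFrame:
    """Run pre-ranked GSEA over a gene-set collection.

    Sets are filtered to [min_size, max_size] members after intersection
    with the ranking. Per set: ES; NES = ES / mean(|null ES| of matching
    sign); add-one permutation p within the same-sign null; BH-adjusted p
    across sets; GSEA-style FDR q from pooled NES tail ratios. A set is
    flagged enriched when p_adj <= alpha and |NES| >= nes_min.
    """
    genes, scores = _prepare_ranking(ranked)
    gene_set = set(genes)
    ranked_sorted = list(zip(genes, scores))
    used: list[tuple[str, frozenset]] = []
    for name, members in collection.items():
        inter = members & gene_set
        if not inter:
            logger.info("preranked_gsea: set %r has no genes in the ranking; skipped", name)
            continue
        if not (min_size <= len(inter) <= max_size):
            continue
        used.append((name, frozenset(inter)))
    if not used:
        raise ValueError("no gene sets within the size bounds after intersection")
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    all_nes = []
    null_nes_pool = []
    for name, inter in used:
        es, _, le = enrichment_score(ranked_sorted, inter, weight_exponent)
        size = len(inter)
        if size not in null_cache:
            null_cache[size] = null_es_distribution(
                ranked_sorted, size, n_permutations, rng, weight_exponent
            )
        null = null_cache[size]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.mean(np.abs(same)) if same.size else np.mean(np.abs(null))
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size) if same.size else 1.0
        null_nes = np.where(null >= 0, null / (np.mean(null[null >= 0]) if (null >= 0).any() else 1.0),
                            null / (np.mean(np.abs(null[null < 0])) if (null < 0).any() else 1.0))
        null_nes_pool.append(null_nes)
        all_nes.append(nes)
        rows.append(
            {
                "set_name": name,
                "es": es,
                "nes": nes,
                "p_perm": float(p),
                "size_used": size,
                "gene_ratio": len(le) / size,
                "leading_edge": "|".join(le),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = adjust_fdr(df["p_perm"], "bh")
    pooled_null = np.concatenate(null_nes_pool)
    obs = np.asarray(all_nes)
    fdr = np.empty(len(obs))
    for i, v in enumerate(obs):
        if v >= 0:
            null_tail = np.mean(pooled_null >= v)
            obs_tail = np.mean(obs >= v)
        else:
            null_tail = np.mean(pooled_null <= v)
            obs_tail = np.mean(obs <= v)
        fdr[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    df["fdr_q"] = fdr
    df["enriched"] = (df["p_adj"] <= alpha) & (df["nes"].abs() >= nes_min)
    return df.sort_values("p_perm", kind="mergesort").reset_index(drop=True)
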