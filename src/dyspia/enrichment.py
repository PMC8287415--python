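"""Pathway enrichment over a ranked gene-pair background.

Background pairs are ranked by descending dysregulation score.  For a
pathway P with m pairs among the N ranked pairs, a weighted running sum is
walked down the list: hits add |score|^p / N_R (N_R the sum of |score|^p over
P's pairs), misses subtract 1 / (N - m).  The pathway score (DysPS) is the
running sum's maximum deviation from zero — the signed extremum of larger
magnitude.  With weight exponent p = 0 this is exactly the two-sample
Kolmogorov-Smirnov statistic on the hit vs miss rank distributions; the
default p = 1 weights each hit by its dysregulation strength.

Significance comes from label permutations: each shuffle preserves group
sizes, the standardization and every pair score are recomputed under the
shuffled labels, the list is re-ranked, and every pathway is re-scored — one
shared shuffle serves all pathways.  The nominal p-value compares the
observed DysPS with the same-sign portion of its own null and carries a
pseudocount so p is never zero; Benjamini-Hochberg is applied across all
tested pathways.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .background import restrict_to_expression, build_combined_background
from .datamodel import (
    BackgroundSet,
    DysGpsTable,
    DyspiaError,
    EnrichmentResult,
    ExpressionMatrix,
    NullDistribution,
    PathwayIndex,
    PathwayPairSet,
    PhenotypeLabels,
    RankedPairList,
    ValidationError,
)
from .scoring import _dysgps_scores, compute_dysgps

logger = logging.getLogger(__name__)

__all__ = [
    "rank_pairs",
    "build_pathway_index",
    "enrichment_score",
    "all_enrichment_scores",
    "permutation_null",
    "nominal_pvalue",
    "bh_fdr",
    "classify_direction",
    "run_dyspia",
]


def _ranking_order(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending, ties broken by pair label ascending."""
    return np.lexsort((labels, -scores))


def rank_pairs(table: DysGpsTable) -> RankedPairList:
    """Sort background pairs by descending score (ties: canonical label ascending)."""
    scores = table.scores
    if np.isnan(scores).any():
        bad = int(np.flatnonzero(np.isnan(scores))[0])
        raise ValidationError(f"NaN score for pair {table.pairs[bad].label}")
    labels = np.array([p.label for p in table.pairs])
    order = _ranking_order(scores, labels)
    return RankedPairList(
        pairs=[table.pairs[i] for i in order], scores=scores[order]
    )


def build_pathway_index(
    ranked: RankedPairList,
    pathways: Sequence[PathwayPairSet],
    min_size: int = 5,
    max_size: int = 5000,
) -> PathwayIndex:
    """1-based hit positions of each pathway's usable pairs in the ranked list.

    A pair is *usable* if it is present in the ranked background; pathways
    with a usable-pair count outside [min_size, max_size] are skipped and
    logged.
    """
    pos_of = {p: i + 1 for i, p in enumerate(ranked.pairs)}
    ids, names, positions, skipped = [], [], [], []
    for pw in pathways:
        pos = sorted(pos_of[p] for p in pw.pairs if p in pos_of)
        if len(pos) < min_size:
            skipped.append((pw.pathway_id, f"only {len(pos)} usable pairs (< {min_size})"))
            continue
        if len(pos) > max_size:
            skipped.append((pw.pathway_id, f"{len(pos)} usable pairs (> {max_size})"))
            continue
        if len(pos) >= ranked.N:
            skipped.append((pw.pathway_id, "pathway covers the entire background"))
            continue
        ids.append(pw.pathway_id)
        names.append(pw.name)
        positions.append(np.asarray(pos, dtype=np.int64))
    for pid, why in skipped:
        logger.info("pathway %s skipped: %s", pid, why)
    return PathwayIndex(
        pathway_ids=ids, names=names, positions=positions, N=ranked.N, skipped=skipped
    )


def enrichment_score(
    ranked: RankedPairList | np.ndarray,
    positions: np.ndarray,
    p_exp: float = 1.0,
) -> float:
    """Pathway score by the full O(N) running sum (reference form).

    ``positions`` are the 1-based ranks of the pathway's pairs.  Returns the
    extremum of larger magnitude; an exact magnitude tie returns the positive
    extremum.
    """
    scores = ranked.scores if isinstance(ranked, RankedPairList) else np.asarray(ranked)
    N = scores.shape[0]
    positions = np.asarray(positions, dtype=np.int64)
    m = positions.size
    if not 1 <= m < N:
        raise ValidationError("pathway must have between 1 and N-1 pairs")
    hit = np.zeros(N, dtype=bool)
    hit[positions - 1] = True
    w = np.abs(scores[positions - 1]) ** p_exp
    n_r = w.sum()
    if n_r == 0:
        raise ValidationError(
            "all pathway pairs have zero |score|; hit weights are undefined"
        )
    step = np.full(N, -1.0 / (N - m))
    step[positions - 1] = w / n_r
    running = np.cumsum(step)
    s_max = float(running.max())
    s_min = float(running.min())
    return s_max if abs(s_max) >= abs(s_min) else s_min


def _fast_scores_for_ranking(
    abs_scores_p: np.ndarray,
    positions_list: Sequence[np.ndarray],
    N: int,
) -> np.ndarray:
    """Pathway scores touching only hit positions.

    The running sum rises only at hits and falls linearly between them, so
    its maximum lies at a hit position and its minimum immediately before a
    hit or at the end of the list (where the sum is exactly zero).
    ``abs_scores_p`` is |score|^p aligned with the ranked list.
    """
    out = np.empty(len(positions_list))
    for k, pos in enumerate(positions_list):
        m = pos.size
        n_miss = N - m
        w = abs_scores_p[pos - 1]
        n_r = w.sum()
        if n_r == 0:
            raise ValidationError("all pathway pairs have zero |score|")
        cw = np.cumsum(w) / n_r
        drop = (pos - np.arange(1, m + 1)) / n_miss
        tops = cw - drop          # value at each hit position
        bots = tops - w / n_r     # value one slot before each hit
        s_max = float(tops.max())
        s_min = min(float(bots.min()), 0.0)
        out[k] = s_max if abs(s_max) >= abs(s_min) else s_min
    return out


def all_enrichment_scores(
    ranked: RankedPairList, index: PathwayIndex, p_exp: float = 1.0
) -> np.ndarray:
    """Scores for every indexed pathway via the hit-position shortcut.

    Agrees with :func:`enrichment_score` pathway by pathway (the shortcut
    evaluates the same extrema without walking the whole list).
    """
    if index.N != ranked.N:
        raise ValidationError("pathway index was built against a different ranking")
    abs_p = np.abs(ranked.scores) ** p_exp
    return _fast_scores_for_ranking(abs_p, index.positions, ranked.N)


def _label_masks(
    n_samples: int, n_case: int, n_perm: int, seed: int | None
) -> tuple[np.ndarray, bool]:
    """Case masks for the permutation null; exhaustive when feasible.

    When C(n_samples, n_case) <= n_perm every distinct case/control split is
    enumerated once; otherwise ``n_perm`` random group-size-preserving
    shuffles are drawn.
    """
    n_distinct = math.comb(n_samples, n_case)
    if n_distinct <= n_perm:
        logger.warning(
            "only %d distinct label splits exist; using exhaustive enumeration "
            "instead of %d random permutations", n_distinct, n_perm,
        )
        masks = np.zeros((n_distinct, n_samples), dtype=bool)
        for row, case_idx in enumerate(combinations(range(n_samples), n_case)):
            masks[row, list(case_idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n_samples), dtype=bool)
    for row in range(n_perm):
        masks[row, rng.permutation(n_samples)[:n_case]] = True
    return masks, False


def permutation_null(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    bg: BackgroundSet,
    pathways: Sequence[PathwayPairSet],
    n_perm: int = 1000,
    seed: int | None = 0,
    min_size: int = 5,
    max_size: int = 5000,
    p_exp: float = 1.0,
) -> NullDistribution:
    """Null pathway scores from label permutations shared across pathways.

    Each shuffle preserves the group sizes; standardization, every pair
    score, the ranking and every pathway score are recomputed per shuffle.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    observed = compute_dysgps(expr, labels, bg)
    ranked = rank_pairs(observed)
    index = build_pathway_index(ranked, pathways, min_size, max_size)
    null = _permutation_null_scores(
        expr, labels, bg, index, n_perm=n_perm, seed=seed, p_exp=p_exp
    )
    return null


def _permutation_null_scores(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    bg: BackgroundSet,
    index: PathwayIndex,
    n_perm: int,
    seed: int | None,
    p_exp: float,
) -> NullDistribution:
    """Core permutation loop over a prebuilt pathway index."""
    case = labels.case_mask(expr.sample_ids)
    n_samples = case.size
    n_case = int(case.sum())
    ia = np.fromiter((expr.row_index(p.gene_a) for p in bg.pairs), dtype=np.intp)
    ib = np.fromiter((expr.row_index(p.gene_b) for p in bg.pairs), dtype=np.intp)
    pair_labels = np.array([p.label for p in bg.pairs])
    # map pathway hit positions back to background indices (ranking-independent)
    obs_scores = _dysgps_scores(expr.values, case, ia, ib)
    obs_order = _ranking_order(obs_scores, pair_labels)
    pathway_bg_idx = [obs_order[pos - 1] for pos in index.positions]

    masks, exhaustive = _label_masks(n_samples, n_case, n_perm, seed)
    values = np.empty((masks.shape[0], len(index)))
    rank_of = np.empty(len(bg), dtype=np.int64)
    for row in range(masks.shape[0]):
        scores = _dysgps_scores(expr.values, masks[row], ia, ib)
        order = _ranking_order(scores, pair_labels)
        rank_of[order] = np.arange(1, len(bg) + 1)
        abs_p = np.abs(scores[order]) ** p_exp
        positions = [np.sort(rank_of[idx]) for idx in pathway_bg_idx]
        values[row] = _fast_scores_for_ranking(abs_p, positions, len(bg))
    return NullDistribution(
        pathway_ids=list(index.pathway_ids),
        values=values,
        seed=seed,
        exhaustive=exhaustive,
    )


def nominal_pvalue(observed: float, null_values: np.ndarray) -> float:
    """Permutation p-value against the same-sign portion of the null.

    For a non-negative observation: p = (1 + #{v >= 0 and v >= obs}) /
    (1 + #{v >= 0}); mirrored for negative observations over the
    non-positive portion.  The pseudocount keeps p in (0, 1].
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValidationError("null distribution is empty")
    if observed >= 0:
        portion = null_values[null_values >= 0]
        hits = int(np.sum(portion >= observed))
    else:
        portion = null_values[null_values <= 0]
        hits = int(np.sum(portion <= observed))
    if portion.size == 0:
        logger.warning(
            "no null values share the sign of the observed score; p-value set to 1"
        )
        return 1.0
    return (1 + hits) / (1 + portion.size)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify_direction(dysps: float, fdr: float, alpha: float = 0.05) -> str:
    """gain / loss of correlation call at FDR threshold ``alpha``."""
    if fdr < alpha and dysps > 0:
        return "gain"
    if fdr < alpha and dysps < 0:
        return "loss"
    return "not_significant"


def run_dyspia(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    pathways: Sequence[PathwayPairSet],
    bg: BackgroundSet | None = None,
    n_perm: int = 1000,
    seed: int | None = 0,
    min_size: int = 5,
    max_size: int = 5000,
    p_exp: float = 1.0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Full pipeline: background -> pair scores -> ranking -> pathway scores
    -> permutation null -> nominal p -> BH-FDR -> direction calls.

    When ``bg`` is None a combined background is built from the pathways'
    own edges plus an equally sized random sample of pairs over the genes
    they mention.  Results are sorted by p-value ascending, then |DysPS|
    descending.
    """
    if bg is None:
        bg = build_combined_background(pathways, seed=0 if seed is None else seed)
    bg = restrict_to_expression(bg, expr, labels)
    table = compute_dysgps(expr, labels, bg)
    ranked = rank_pairs(table)
    index = build_pathway_index(ranked, pathways, min_size, max_size)
    if len(index) == 0:
        raise DyspiaError(
            f"no pathway passed the usable-pair size filter "
            f"[{min_size}, {max_size}]; skipped: {index.skipped[:10]}"
        )
    observed = all_enrichment_scores(ranked, index, p_exp)
    null = _permutation_null_scores(
        expr, labels, bg, index, n_perm=n_perm, seed=seed, p_exp=p_exp
    )
    pvals = np.array(
        [nominal_pvalue(observed[k], null.values[:, k]) for k in range(len(index))]
    )
    fdrs = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            pathway_id=index.pathway_ids[k],
            name=index.names[k],
            n_pairs_used=int(index.positions[k].size),
            dysps=float(observed[k]),
            pval=float(pvals[k]),
            fdr=float(fdrs[k]),
            direction=classify_direction(float(observed[k]), float(fdrs[k]), alpha),
        )
        for k in range(len(index))
    ]
    results.sort(key=lambda r: (r.pval, -abs(r.dysps), r.pathway_id))
    return results
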