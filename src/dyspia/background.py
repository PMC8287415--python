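"""Construction of the combined gene-pair background.

The background a pathway is ranked against has two parts: the *observed*
background (the union of all curated pathway edges) and a *random* background
(unordered gene pairs sampled uniformly without replacement from the gene
universe).  The two parts are merged with single inclusion — a pair present
in both is kept once and flagged ``both``.  Random sampling of unordered
pairs is done directly (each of the C(m, 2) pairs equally likely), which is
distributionally identical to sampling ordered pairs and keeping the
ascending half.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np

from .datamodel import (
    BackgroundSet,
    ExpressionMatrix,
    GenePair,
    PathwayPairSet,
    PhenotypeLabels,
    SelfPairError,
    ValidationError,
)

logger = logging.getLogger(__name__)


def canonical_pair(g1: str, g2: str) -> GenePair:
    """Return the canonical (ascending byte-order) form of an unordered pair.

    Raises :class:`SelfPairError` if ``g1 == g2``.
    """
    if g1 == g2:
        raise SelfPairError(f"gene {g1!r} paired with itself")
    return GenePair(g1, g2) if g1 < g2 else GenePair(g2, g1)


def build_observed_background(pathways: Sequence[PathwayPairSet]) -> set[GenePair]:
    """Union of all pathway edge sets (the observed part of the background)."""
    if not pathways:
        raise ValidationError("at least one pathway is required")
    observed: set[GenePair] = set()
    for pw in pathways:
        observed |= pw.pairs
    return observed


def _unrank_pairs(k: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Map pair indices k in [0, C(m,2)) to (i, j) with i < j.

    Index space enumerates pairs row by row: all pairs (0, j), then (1, j), ...
    """
    k = np.asarray(k, dtype=np.int64)
    # float solve for the row, then exact integer correction (+/- 1 at most)
    i = np.floor((2 * m - 1 - np.sqrt((2 * m - 1) ** 2 - 8.0 * k)) / 2).astype(np.int64)
    i = np.clip(i, 0, m - 2)

    def offset(row: np.ndarray) -> np.ndarray:
        return row * (2 * m - row - 1) // 2

    while True:
        too_high = offset(i) > k
        if not too_high.any():
            break
        i[too_high] -= 1
    while True:
        too_low = offset(i + 1) <= k
        too_low &= i + 1 <= m - 2
        if not too_low.any():
            break
        i[too_low] += 1
    j = k - offset(i) + i + 1
    return i, j


def sample_random_background(
    universe: Sequence[str], n_pairs: int, seed: int
) -> set[GenePair]:
    """Sample ``n_pairs`` distinct unordered pairs uniformly from ``universe``.

    Deterministic given ``seed``.  Duplicated universe symbols are collapsed
    with a warning; a request exceeding C(m, 2) raises.
    """
    symbols = sorted(set(universe))
    if len(symbols) < len(universe):
        logger.warning(
            "gene universe contained %d duplicate symbols; collapsed",
            len(universe) - len(symbols),
        )
    m = len(symbols)
    if m < 2:
        raise ValidationError("gene universe needs at least 2 genes")
    total = m * (m - 1) // 2
    if n_pairs > total:
        raise ValidationError(
            f"cannot draw {n_pairs} distinct pairs from a universe of {m} genes "
            f"(only {total} pairs exist)"
        )
    rng = np.random.default_rng(seed)
    if n_pairs * 2 >= total:
        # dense regime: an explicit draw without replacement is affordable
        ks = rng.choice(total, size=n_pairs, replace=False)
    else:
        # sparse regime: rejection sampling of indices until n distinct
        chosen: set[int] = set()
        while len(chosen) < n_pairs:
            draw = rng.integers(0, total, size=int((n_pairs - len(chosen)) * 1.2) + 8)
            for k in draw.tolist():
                if len(chosen) >= n_pairs:
                    break
                chosen.add(k)
        ks = np.fromiter(chosen, dtype=np.int64)
    i, j = _unrank_pairs(np.asarray(ks, dtype=np.int64), m)
    return {GenePair(symbols[a], symbols[b]) for a, b in zip(i.tolist(), j.tolist())}


def combine_backgrounds(
    observed: Iterable[GenePair],
    random: Iterable[GenePair],
    universe_size: int | None = None,
) -> BackgroundSet:
    """Merge observed and random pairs; intersection members are flagged ``both``."""
    observed = set(observed)
    random = set(random)
    pairs: list[GenePair] = []
    provenance: list[str] = []
    for p in observed | random:
        pairs.append(p)
        if p in observed and p in random:
            provenance.append("both")
        elif p in observed:
            provenance.append("observed")
        else:
            provenance.append("random")
    n_common = sum(1 for f in provenance if f == "both")
    logger.info(
        "combined background: %d observed + %d random - %d common = %d pairs",
        len(observed), len(random), n_common, len(pairs),
    )
    return BackgroundSet(pairs=pairs, provenance=provenance, universe_size=universe_size)


def restrict_to_expression(
    bg: BackgroundSet, expr: ExpressionMatrix, labels: PhenotypeLabels
) -> BackgroundSet:
    """Drop background pairs that cannot be scored on this dataset.

    A pair is kept only if both genes are measured and both have nonzero
    variance within *each* phenotype group (required for the within-group
    standardization).  Performing the filter here keeps the ranked-list
    length fixed across label permutations.
    """
    case = labels.case_mask(expr.sample_ids)
    usable: dict[str, bool] = {}

    def gene_usable(g: str) -> bool:
        if g not in usable:
            if g not in expr:
                usable[g] = False
            else:
                row = expr.row(g)
                usable[g] = row[case].std() > 0 and row[~case].std() > 0
        return usable[g]

    kept_pairs: list[GenePair] = []
    kept_prov: list[str] = []
    n_missing = 0
    n_zero_var = 0
    for pair, prov in zip(bg.pairs, bg.provenance):
        if pair.gene_a not in expr or pair.gene_b not in expr:
            n_missing += 1
            continue
        if not (gene_usable(pair.gene_a) and gene_usable(pair.gene_b)):
            n_zero_var += 1
            continue
        kept_pairs.append(pair)
        kept_prov.append(prov)
    logger.info(
        "background restriction: kept %d/%d pairs (%d dropped: gene unmeasured, "
        "%d dropped: zero within-group variance)",
        len(kept_pairs), len(bg), n_missing, n_zero_var,
    )
    if not kept_pairs:
        raise ValidationError("no background pairs measurable in this dataset")
    return BackgroundSet(
        pairs=kept_pairs, provenance=kept_prov, universe_size=bg.universe_size
    )


def build_combined_background(
    pathways: Sequence[PathwayPairSet],
    universe: Sequence[str] | None = None,
    n_random: int | None = None,
    seed: int = 0,
) -> BackgroundSet:
    """Convenience wrapper: observed pairs from pathways + a random sample.

    Defaults mirror the roughly 1:1 observed-to-random composition of the
    combined background: ``n_random`` defaults to the observed count, and the
    universe defaults to all genes appearing in the pathways.
    """
    observed = build_observed_background(pathways)
    if universe is None:
        universe = sorted({g for p in observed for g in p})
    if n_random is None:
        n_random = len(observed)
    n_random = min(n_random, len(set(universe)) * (len(set(universe)) - 1) // 2)
    random = sample_random_background(universe, n_random, seed)
    return combine_backgrounds(observed, random, universe_size=len(set(universe)))
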