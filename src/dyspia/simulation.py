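"""Synthetic benchmark: bivariate-normal gene pairs and planted pathways.

Every background pair gets its own private pair of genes drawn from a
bivariate normal with unit variances and correlation r1 in cases, r2 in
controls.  The default composition (100,000 pairs) is:

* NDG   — 95,000 non-dysregulated pairs, r1 = r2 ~ U[-1, 1];
* GCDG  — 5 x 500 gain-of-correlation pairs with shift d in {0.4, ..., 0.8}:
          r1 ~ U[d - 1, 1], r2 = r1 - d (cases more co-expressed);
* LCDG  — 5 x 500 loss-of-correlation pairs: r1 ~ U[-1, 1 - d], r2 = r1 + d.

1,000 pathways are planted on top (200 at each size 20/40/60/80/100, of
which 20 per size are dysregulated, 100 in total).  A dysregulated pathway
draws round(p_dysgp * size) pairs from the dysregulated pool of its assigned
direction and strength — strong pathways sample shifts {0.7, 0.8}, weak ones
{0.4, 0.5}, split evenly between gain and loss — and the rest from the NDG
pool; null pathways draw entirely from NDG.  Pairs may recur across pathways
but never within one.

Detection is evaluated by ROC/AUC: pathways are ranked by nominal
permutation p-value (ties broken by |DysPS|), and the AUC discriminating the
truth-flagged dysregulated pathways from the null ones is computed with
midrank tie handling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .datamodel import (
    BackgroundSet,
    EnrichmentResult,
    ExpressionMatrix,
    GenePair,
    PathwayPairSet,
    PhenotypeLabels,
    ValidationError,
)
from .enrichment import run_dyspia

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedData",
    "simulate_gene_pair",
    "generate_pair_background",
    "generate_pathways",
    "pathway_ranking_score",
    "roc_auc",
    "run_simulation_study",
]

NDG = "NDG"
GCDG = "GCDG"
LCDG = "LCDG"


@dataclass(frozen=True)
class SimConfig:
    """Study design for one simulated dataset.

    Defaults are the full benchmark: 100,000 background pairs (95% NDG, 5%
    dysregulated across five correlation shifts per direction), 100 case and
    100 control samples, and 1,000 pathways of which 100 are dysregulated.
    ``scaled`` shrinks every count proportionally for quick studies.
    """

    n_ndg: int = 95_000
    n_per_delta: int = 500
    deltas: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8)
    n_case: int = 100
    n_control: int = 100
    pathway_sizes: tuple[int, ...] = (20, 40, 60, 80, 100)
    pathways_per_size: int = 200
    dysregulated_per_size: int = 20
    p_dysgp: float = 0.2
    strong_deltas: tuple[float, ...] = (0.7, 0.8)
    weak_deltas: tuple[float, ...] = (0.4, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_dysgp <= 1:
            raise ValidationError("p_dysgp must lie in (0, 1]")
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("each group needs at least 2 samples")
        for d in self.deltas:
            if not 0 < d < 2:
                raise ValidationError(f"correlation shift {d} out of range")
        unknown = set(self.strong_deltas) | set(self.weak_deltas)
        if not unknown <= set(self.deltas):
            raise ValidationError("strong/weak shifts must be among the deltas")
        if not 0 <= self.dysregulated_per_size <= self.pathways_per_size:
            raise ValidationError("more dysregulated pathways than pathways")

    @property
    def n_dys_pairs(self) -> int:
        return 2 * len(self.deltas) * self.n_per_delta

    @property
    def n_pairs_total(self) -> int:
        return self.n_ndg + self.n_dys_pairs

    @property
    def n_pathways(self) -> int:
        return self.pathways_per_size * len(self.pathway_sizes)

    @property
    def n_dysregulated_pathways(self) -> int:
        return self.dysregulated_per_size * len(self.pathway_sizes)

    def scaled(self, factor: float) -> "SimConfig":
        """Proportionally smaller design (pathway sizes and samples unchanged)."""
        return replace(
            self,
            n_ndg=max(1, round(self.n_ndg * factor)),
            n_per_delta=max(1, round(self.n_per_delta * factor)),
            pathways_per_size=max(1, round(self.pathways_per_size * factor)),
            dysregulated_per_size=max(1, round(self.dysregulated_per_size * factor)),
        )


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset.

    Pair-level arrays are aligned with the background pair list; pathway
    fields are filled in by :func:`generate_pathways`.
    """

    pair_class: np.ndarray           # 'NDG' | 'GCDG' | 'LCDG' per pair
    r1: np.ndarray
    r2: np.ndarray
    delta: np.ndarray                # signed r2 - r1 (0 for NDG)
    pathway_ids: list[str] = field(default_factory=list)
    dysregulated: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    direction: list[str] = field(default_factory=list)    # 'gain'|'loss'|'null'
    strength: list[str] = field(default_factory=list)     # 'strong'|'weak'|'null'


@dataclass
class SimulatedData:
    expr: ExpressionMatrix
    labels: PhenotypeLabels
    background: BackgroundSet
    truth: SimTruth
    pathways: list[PathwayPairSet] = field(default_factory=list)


def simulate_gene_pair(
    r1: float, r2: float, n1: int, n2: int, rng: np.random.Generator
) -> np.ndarray:
    """Two expression rows of length n1 + n2 (cases first, then controls).

    Cases are drawn from a bivariate normal with unit variances and
    correlation ``r1``, controls with correlation ``r2``.
    """
    for r in (r1, r2):
        if abs(r) > 1:
            raise ValidationError(f"|correlation| must be <= 1, got {r}")
    rows = np.empty((2, n1 + n2))
    for sl, r, n in ((slice(0, n1), r1, n1), (slice(n1, n1 + n2), r2, n2)):
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        rows[0, sl] = z1
        rows[1, sl] = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * z2
    return rows


def _class_blocks(cfg: SimConfig) -> list[tuple[str, int, float]]:
    """Generation order of Table-style pair blocks: (class, count, shift)."""
    blocks = [(GCDG, cfg.n_per_delta, d) for d in cfg.deltas]
    blocks.append((NDG, cfg.n_ndg, 0.0))
    blocks.extend((LCDG, cfg.n_per_delta, d) for d in cfg.deltas)
    return blocks


def generate_pair_background(cfg: SimConfig, with_pathways: bool = True) -> SimulatedData:
    """Expression, labels, background and pair-level truth for one design.

    Each pair uses its own two genes; generation is vectorized per class
    block with an independent child random stream per block, so the blocks'
    draws do not interfere.
    """
    n1, n2 = cfg.n_case, cfg.n_control
    total = cfg.n_pairs_total
    blocks = _class_blocks(cfg)
    children = np.random.SeedSequence(cfg.seed).spawn(len(blocks) + 1)

    pair_class = np.empty(total, dtype=object)
    r1_all = np.empty(total)
    r2_all = np.empty(total)
    values = np.empty((2 * total, n1 + n2))

    start = 0
    for (cls, count, d), child in zip(blocks, children):
        rng = np.random.default_rng(child)
        if cls == NDG:
            r1 = rng.uniform(-1.0, 1.0, size=count)
            r2 = r1.copy()
        elif cls == GCDG:
            r1 = rng.uniform(d - 1.0, 1.0, size=count)
            r2 = r1 - d
        else:
            r1 = rng.uniform(-1.0, 1.0 - d, size=count)
            r2 = r1 + d
        sl = slice(start, start + count)
        pair_class[sl] = cls
        r1_all[sl] = r1
        r2_all[sl] = r2
        rows = slice(2 * start, 2 * (start + count))
        # vectorized bivariate normal per condition
        for cols, r in ((slice(0, n1), r1), (slice(n1, n1 + n2), r2)):
            ncols = cols.stop - cols.start
            z1 = rng.standard_normal((count, ncols))
            z2 = rng.standard_normal((count, ncols))
            values[rows.start:rows.stop:2, cols] = z1
            values[rows.start + 1:rows.stop:2, cols] = (
                r[:, None] * z1 + np.sqrt(np.maximum(0.0, 1.0 - r * r))[:, None] * z2
            )
        start += count

    width = len(str(total))
    gene_ids = []
    pairs = []
    for i in range(total):
        a = f"P{i:0{width}d}A"
        b = f"P{i:0{width}d}B"
        gene_ids.extend((a, b))
        pairs.append(GenePair(a, b))
    sample_ids = [f"case_{i:03d}" for i in range(n1)] + [
        f"ctrl_{i:03d}" for i in range(n2)
    ]
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    labels = PhenotypeLabels(
        {s: ("case" if i < n1 else "control") for i, s in enumerate(sample_ids)}
    )
    bg = BackgroundSet(pairs=pairs, provenance=["observed"] * total)
    # BackgroundSet sorts lexicographically; zero-padded names keep the
    # generation order, so truth arrays stay aligned.
    truth = SimTruth(
        pair_class=pair_class, r1=r1_all, r2=r2_all, delta=r2_all - r1_all
    )
    data = SimulatedData(expr=expr, labels=labels, background=bg, truth=truth)
    if with_pathways:
        generate_pathways(cfg, data, np.random.default_rng(children[-1]))
    return data


def generate_pathways(
    cfg: SimConfig, data: SimulatedData, rng: np.random.Generator
) -> list[PathwayPairSet]:
    """Plant pathways on a generated background and record their truth flags.

    Per pathway size, ``pathways_per_size`` pathways are created and the
    first ``dysregulated_per_size`` of them are dysregulated, cycling through
    (gain, strong), (loss, strong), (gain, weak), (loss, weak).
    """
    truth = data.truth
    cls = truth.pair_class
    ndg_pool = np.flatnonzero(cls == NDG)
    pools: dict[tuple[str, str], np.ndarray] = {}
    for direction, klass in (("gain", GCDG), ("loss", LCDG)):
        for strength, shifts in (("strong", cfg.strong_deltas), ("weak", cfg.weak_deltas)):
            mask = (cls == klass) & np.isin(
                np.round(np.abs(truth.delta), 6), np.round(shifts, 6)
            )
            pools[(direction, strength)] = np.flatnonzero(mask)

    categories = [("gain", "strong"), ("loss", "strong"), ("gain", "weak"), ("loss", "weak")]
    pathways: list[PathwayPairSet] = []
    ids: list[str] = []
    flags: list[bool] = []
    directions: list[str] = []
    strengths: list[str] = []
    bg_pairs = data.background.pairs

    for size in cfg.pathway_sizes:
        if size > ndg_pool.size:
            raise ValidationError(
                f"pathway size {size} exceeds the NDG pool ({ndg_pool.size})"
            )
        n_dys_pairs = round(cfg.p_dysgp * size)
        for j in range(cfg.pathways_per_size):
            pid = f"pw_s{size:03d}_{j:03d}"
            if j < cfg.dysregulated_per_size:
                direction, strength = categories[j % len(categories)]
                pool = pools[(direction, strength)]
                if n_dys_pairs > pool.size:
                    raise ValidationError(
                        f"pathway {pid}: needs {n_dys_pairs} pairs from the "
                        f"{direction}/{strength} pool of {pool.size}"
                    )
                dys_idx = rng.choice(pool, size=n_dys_pairs, replace=False)
                ndg_idx = rng.choice(ndg_pool, size=size - n_dys_pairs, replace=False)
                members = np.concatenate([dys_idx, ndg_idx])
                flags.append(True)
                directions.append(direction)
                strengths.append(strength)
            else:
                members = rng.choice(ndg_pool, size=size, replace=False)
                flags.append(False)
                directions.append("null")
                strengths.append("null")
            ids.append(pid)
            pathways.append(
                PathwayPairSet(
                    pathway_id=pid,
                    name=pid,
                    pairs=frozenset(bg_pairs[i] for i in members),
                )
            )
    truth.pathway_ids = ids
    truth.dysregulated = np.asarray(flags, dtype=bool)
    truth.direction = directions
    truth.strength = strengths
    data.pathways = pathways
    logger.info(
        "generated %d pathways (%d dysregulated) over %d background pairs",
        len(pathways), int(truth.dysregulated.sum()), len(bg_pairs),
    )
    return pathways


def pathway_ranking_score(pvals: np.ndarray, dysps: np.ndarray) -> np.ndarray:
    """Detection score: higher means called dysregulated earlier.

    Pathways are ordered by p-value ascending with ties broken by |DysPS|
    descending; equal (p, |DysPS|) tuples share a dense rank so AUC midrank
    handling applies.
    """
    pvals = np.asarray(pvals, dtype=float)
    mag = np.abs(np.asarray(dysps, dtype=float))
    order = np.lexsort((-mag, pvals))
    new_group = np.ones(order.size, dtype=int)
    new_group[1:] = (pvals[order][1:] != pvals[order][:-1]) | (
        mag[order][1:] != mag[order][:-1]
    )
    dense = np.cumsum(new_group)
    score = np.empty(order.size)
    score[order] = -dense.astype(float)
    return score


def roc_auc(scores: np.ndarray, truth_flags: np.ndarray) -> float:
    """AUC of ``scores`` for discriminating truth-flagged pathways (midrank ties)."""
    truth_flags = np.asarray(truth_flags, dtype=bool)
    if truth_flags.all() or not truth_flags.any():
        raise ValidationError("AUC undefined: only one class present")
    return float(roc_auc_score(truth_flags, np.asarray(scores, dtype=float)))


def evaluate_run(
    results: Sequence[EnrichmentResult], truth: SimTruth
) -> dict[str, float]:
    """Pooled and per-size AUC of a pipeline run against the planted truth."""
    flag_of = dict(zip(truth.pathway_ids, truth.dysregulated.tolist()))
    ids = [r.pathway_id for r in results]
    flags = np.array([flag_of[i] for i in ids], dtype=bool)
    score = pathway_ranking_score(
        np.array([r.pval for r in results]), np.array([r.dysps for r in results])
    )
    sizes = np.array([int(i.split("_")[1][1:]) for i in ids])
    out = {"pooled": roc_auc(score, flags)}
    for s in sorted(set(sizes.tolist())):
        sel = sizes == s
        out[str(s)] = roc_auc(score[sel], flags[sel])
    return out


def run_simulation_study(
    p_dysgps: Sequence[float] = (0.2, 0.3, 0.4, 0.5, 0.6),
    base: SimConfig | None = None,
    n_perm: int = 1000,
    seeds: Sequence[int] = (0,),
    min_size: int = 5,
    max_size: int = 5000,
) -> pd.DataFrame:
    """AUC table over the dysregulated-pair-proportion grid.

    One full pipeline run per (p_dysgp, seed); rows report the pooled AUC
    over all pathways plus per-size AUCs.
    """
    base = base or SimConfig()
    rows = []
    for p in p_dysgps:
        for seed in seeds:
            cfg = replace(base, p_dysgp=p, seed=int(seed))
            data = generate_pair_background(cfg)
            results = run_dyspia(
                data.expr, data.labels, data.pathways, bg=data.background,
                n_perm=n_perm, seed=int(seed), min_size=min_size, max_size=max_size,
            )
            aucs = evaluate_run(results, data.truth)
            for group, auc in aucs.items():
                rows.append(
                    {"p_dysgp": p, "seed": int(seed), "group": group, "auc": auc}
                )
            logger.info("p_dysgp=%.2f seed=%d pooled AUC=%.4f", p, seed, aucs["pooled"])
    return pd.DataFrame(rows)
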