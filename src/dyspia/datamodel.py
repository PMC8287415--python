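"""Core data containers shared by every stage of the pipeline.

The atomic unit throughout is the *canonical gene pair*: an unordered pair of
gene symbols stored with the lexicographically smaller symbol first (byte-wise
comparison, no case folding).  Pathways are sets of such pairs — edges, not
genes — and the background against which pathways are ranked is an ordered
list of pairs with a provenance flag saying whether each pair came from
curated pathway edges, from random sampling of the gene universe, or both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

CASE = "case"
CONTROL = "control"

_PROVENANCE = ("observed", "random", "both")


class DyspiaError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DyspiaError):
    """An input object violates a documented invariant."""


class SelfPairError(ValidationError):
    """A gene was paired with itself."""


class ZeroVarianceError(DyspiaError):
    """A gene has no within-group variance, so it cannot be standardized."""


class ParseError(DyspiaError):
    """A file could not be parsed; the message names the offending location."""


class GenePair(NamedTuple):
    """Canonical unordered gene pair (``gene_a < gene_b`` byte-wise)."""

    gene_a: str
    gene_b: str

    @property
    def label(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"

    def is_canonical(self) -> bool:
        return self.gene_a < self.gene_b


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values, any units (log or linear as given).

    Invariants: unique gene ids, unique sample ids, shape matches the id
    lists, all values finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    _row_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"{n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_samples != len(self.sample_ids):
            raise ValidationError(
                f"{n_samples} columns but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")
        self._row_of = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self._row_of

    def row_index(self, gene: str) -> int:
        try:
            return self._row_of[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in expression matrix")

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.row_index(gene)]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )


class StandardizedMatrix(ExpressionMatrix):
    """Expression standardized per gene *within each phenotype group*.

    For every gene and every group the values over that group's samples have
    mean 0 and unbiased (n-1) standard deviation 1.
    """


@dataclass
class PhenotypeLabels:
    """Two-group sample labeling (``case`` vs ``control``).

    ``assignments`` maps each sample id to its group.  At least two samples
    per group are required (Welch variances need two); fewer than three per
    group triggers a stability warning.
    """

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        groups = set(self.assignments.values())
        if groups != {CASE, CONTROL}:
            raise ValidationError(
                f"exactly the groups {{'case', 'control'}} are required, got {sorted(groups)}"
            )
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("each group needs at least 2 samples")
        if self.n_case < 3 or self.n_control < 3:
            warnings.warn(
                "fewer than 3 samples in a group: variance estimates are unstable",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def n_case(self) -> int:
        return sum(1 for g in self.assignments.values() if g == CASE)

    @property
    def n_control(self) -> int:
        return sum(1 for g in self.assignments.values() if g == CONTROL)

    def case_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask over ``sample_ids`` marking case samples.

        Every sample id must be labeled.
        """
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValidationError(f"samples without phenotype label: {missing[:5]}")
        return np.array([self.assignments[s] == CASE for s in sample_ids], dtype=bool)

    def swapped(self) -> "PhenotypeLabels":
        """Labels with case and control exchanged."""
        flip = {CASE: CONTROL, CONTROL: CASE}
        return PhenotypeLabels({s: flip[g] for s, g in self.assignments.items()})

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str], case_label: str = CASE) -> "PhenotypeLabels":
        """Build labels from an arbitrary two-level mapping.

        ``case_label`` names the level mapped to ``case``; the single other
        level becomes ``control``.
        """
        levels = sorted(set(mapping.values()))
        if len(levels) != 2:
            raise ValidationError(f"exactly two groups required, got {levels}")
        if case_label not in levels:
            raise ValidationError(f"case label {case_label!r} not among groups {levels}")
        return cls(
            {s: (CASE if g == case_label else CONTROL) for s, g in mapping.items()}
        )


@dataclass
class PathwayPairSet:
    """A pathway represented by its regulated gene pairs (edges), not genes."""

    pathway_id: str
    name: str
    pairs: frozenset[GenePair]

    def __post_init__(self) -> None:
        self.pairs = frozenset(self.pairs)
        if not self.pairs:
            raise ValidationError(f"pathway {self.pathway_id!r} has no pairs")
        for p in self.pairs:
            if not p.is_canonical():
                raise ValidationError(
                    f"pathway {self.pathway_id!r} contains non-canonical pair {p}"
                )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class BackgroundSet:
    """Combined gene-pair background: curated pathway edges plus random pairs.

    Pairs are stored sorted lexicographically (gene_a, then gene_b) so that
    list order is deterministic; ``provenance`` is aligned with ``pairs``.
    """

    pairs: list[GenePair]
    provenance: list[str]
    universe_size: int | None = None

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.provenance):
            raise ValidationError("provenance must be aligned with pairs")
        for prov in set(self.provenance):
            if prov not in _PROVENANCE:
                raise ValidationError(f"unknown provenance flag {prov!r}")
        order = sorted(range(len(self.pairs)), key=lambda i: self.pairs[i])
        self.pairs = [self.pairs[i] for i in order]
        self.provenance = [self.provenance[i] for i in order]
        seen: set[GenePair] = set()
        for p in self.pairs:
            if not p.is_canonical():
                raise ValidationError(f"non-canonical background pair {p}")
            if p in seen:
                raise ValidationError(f"duplicate background pair {p}")
            seen.add(p)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: GenePair) -> bool:
        return pair in self.index()

    _index_cache: dict[GenePair, int] | None = field(default=None, init=False, repr=False)

    def index(self) -> dict[GenePair, int]:
        """Map pair -> position in the (sorted) pair list."""
        if self._index_cache is None:
            self._index_cache = {p: i for i, p in enumerate(self.pairs)}
        return self._index_cache


@dataclass
class DysGpsTable:
    """Per-pair dysregulation scores (Welch t on CILP products) for one labeling."""

    pairs: list[GenePair]
    scores: np.ndarray
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.pairs),):
            raise ValidationError("one score per pair required")


@dataclass
class RankedPairList:
    """Background pairs sorted by descending score (ties: pair label ascending)."""

    pairs: list[GenePair]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.pairs),):
            raise ValidationError("one score per ranked pair required")
        if np.any(self.scores[:-1] < self.scores[1:]):
            raise ValidationError("ranked scores must be non-increasing")

    @property
    def N(self) -> int:
        return len(self.pairs)


@dataclass
class PathwayIndex:
    """1-based ranks of each pathway's usable pairs within a ranked list.

    ``positions[i]`` is a strictly increasing integer array for pathway
    ``pathway_ids[i]``; ``skipped`` records pathways excluded by the usable
    pair-count filter, with reasons.
    """

    pathway_ids: list[str]
    names: list[str]
    positions: list[np.ndarray]
    N: int
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pid, pos in zip(self.pathway_ids, self.positions):
            pos = np.asarray(pos)
            if pos.size == 0:
                raise ValidationError(f"pathway {pid!r} has no positions")
            if np.any(pos[:-1] >= pos[1:]):
                raise ValidationError(f"positions for {pid!r} not strictly increasing")
            if pos[0] < 1 or pos[-1] > self.N:
                raise ValidationError(f"positions for {pid!r} outside [1, N]")

    def __len__(self) -> int:
        return len(self.pathway_ids)


@dataclass
class NullDistribution:
    """Per-pathway null pathway scores from shared label permutations.

    ``values`` has shape (n_perm, n_pathways); the same label shuffle produced
    every pathway's value in a given row.
    """

    pathway_ids: list[str]
    values: np.ndarray
    seed: int | None
    exhaustive: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.pathway_ids):
            raise ValidationError("null values must be (n_perm, n_pathways)")

    @property
    def n_perm(self) -> int:
        return self.values.shape[0]


DIRECTIONS = ("gain", "loss", "not_significant")


@dataclass
class EnrichmentResult:
    """Final per-pathway call: score, permutation p-value, FDR, direction."""

    pathway_id: str
    name: str
    n_pairs_used: int
    dysps: float
    pval: float
    fdr: float
    direction: str

    def __post_init__(self) -> None:
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"pval must lie in (0, 1], got {self.pval}")
        if not (0.0 < self.fdr <= 1.0):
            raise ValidationError(f"fdr must lie in (0, 1], got {self.fdr}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.direction == "gain" and not self.dysps > 0:
            raise ValidationError("direction 'gain' requires a positive score")
        if self.direction == "loss" and not self.dysps < 0:
            raise ValidationError("direction 'loss' requires a negative score")
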