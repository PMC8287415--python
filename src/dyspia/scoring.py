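"""Per-pair dysregulation scoring.

Each gene is z-scored separately within the case and the control samples
(unbiased n-1 standard deviation throughout).  For a gene pair (i, j) the
per-sample product of the two standardized values

    y_k = z_ik * z_jk

is a single-sample co-expression observation: its mean over a group equals
((n - 1) / n) times the within-group Pearson correlation of the two genes.
The dysregulated gene-pair score (DysGPS) is the Welch two-sample t statistic
comparing these products between cases and controls,

    DysGPS = (mean_case(y) - mean_control(y)) / sqrt(s1^2/n1 + s2^2/n2),

positive when the pair is more co-expressed in cases.  DysGPS is used purely
as a ranking score; no parametric p-value (and hence no Welch degrees of
freedom) is ever computed.
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    BackgroundSet,
    DysGpsTable,
    ExpressionMatrix,
    GenePair,
    PhenotypeLabels,
    StandardizedMatrix,
    ZeroVarianceError,
)

__all__ = [
    "standardize_within_group",
    "cilp_products",
    "welch_t",
    "compute_dysgps",
]


def _standardize_values(values: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Group-wise z-scoring of every row; raises on zero within-group variance."""
    z = np.empty_like(values, dtype=float)
    for mask, group in ((case_mask, "case"), (~case_mask, "control")):
        sub = values[:, mask]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() == 0)
        if bad.size:
            raise ZeroVarianceError(
                f"gene row {int(bad[0])} has zero variance in group {group!r}"
            )
        z[:, mask] = (sub - mu) / sd
    return z


def standardize_within_group(
    expr: ExpressionMatrix, labels: PhenotypeLabels
) -> StandardizedMatrix:
    """Mean-center and scale every gene separately within each group.

    Raises :class:`ZeroVarianceError` naming the gene and group if a gene is
    constant within a group.
    """
    case = labels.case_mask(expr.sample_ids)
    try:
        z = _standardize_values(expr.values, case)
    except ZeroVarianceError as e:
        # re-raise with the gene symbol rather than the row number
        msg = str(e)
        row = int(msg.split()[2])
        group = "case" if "'case'" in msg else "control"
        raise ZeroVarianceError(
            f"gene {expr.gene_ids[row]!r} has zero variance in group {group!r}"
        ) from None
    return StandardizedMatrix(
        gene_ids=list(expr.gene_ids), sample_ids=list(expr.sample_ids), values=z
    )


def cilp_products(z: StandardizedMatrix, pair: GenePair) -> np.ndarray:
    """Per-sample product of the two standardized rows, in matrix sample order."""
    return z.row(pair.gene_a) * z.row(pair.gene_b)


def _welch_rows(y: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic, case minus control, unbiased variances."""
    yc = y[..., case_mask]
    yt = y[..., ~case_mask]
    n1 = yc.shape[-1]
    n2 = yt.shape[-1]
    m1 = yc.mean(axis=-1)
    m2 = yt.mean(axis=-1)
    v1 = yc.var(axis=-1, ddof=1)
    v2 = yt.var(axis=-1, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    if np.any(denom == 0):
        raise ZeroVarianceError(
            "both group variances of the pair products are zero; "
            "the Welch statistic is undefined"
        )
    return (m1 - m2) / denom


def welch_t(
    y: np.ndarray,
    labels: PhenotypeLabels,
    sample_ids: list[str] | None = None,
) -> float:
    """Welch two-sample t statistic of ``y`` between case and control.

    ``y`` is one value per sample; ``sample_ids`` gives its ordering and
    defaults to the labels' own insertion order.  Sign convention is case
    minus control, so a positive value means a higher mean product (stronger
    co-expression) in cases.
    """
    if sample_ids is None:
        sample_ids = labels.sample_ids
    y = np.asarray(y, dtype=float)
    if y.shape != (len(sample_ids),):
        raise ValueError("y must hold exactly one value per sample")
    return float(_welch_rows(y, labels.case_mask(sample_ids)))


def _dysgps_scores(
    values: np.ndarray, case_mask: np.ndarray, ia: np.ndarray, ib: np.ndarray
) -> np.ndarray:
    """Vectorized DysGPS for all pairs (rows ia vs rows ib) at once."""
    z = _standardize_values(values, case_mask)
    y = z[ia] * z[ib]
    return _welch_rows(y, case_mask)


def compute_dysgps(
    expr: ExpressionMatrix, labels: PhenotypeLabels, bg: BackgroundSet
) -> DysGpsTable:
    """DysGPS for every background pair (background already restricted to expr)."""
    case = labels.case_mask(expr.sample_ids)
    ia = np.fromiter((expr.row_index(p.gene_a) for p in bg.pairs), dtype=np.intp)
    ib = np.fromiter((expr.row_index(p.gene_b) for p in bg.pairs), dtype=np.intp)
    scores = _dysgps_scores(expr.values, case, ia, ib)
    return DysGpsTable(
        pairs=list(bg.pairs),
        scores=scores,
        n_case=int(case.sum()),
        n_control=int((~case).sum()),
    )
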