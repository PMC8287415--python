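"""Readers and writers for the package's plain-text formats.

Formats
-------
Expression
    TSV or CSV, genes in rows, one header row of sample ids, first column
    gene symbols.
Phenotype
    Two-column TSV ``sample_id<TAB>group`` with exactly two groups
    (``case`` / ``control``, or any two levels with ``case_label`` given).
Pathway pair files
    *pair_gmt* (native): ``pathway_id<TAB>description<TAB>GENEA|GENEB<TAB>...``
    — a GMT-style line whose tokens are ``|``-joined gene pairs.  There is no
    standard on-disk format for pathway *edge* sets, so this dialect is the
    package's own convention.
    *sif*: ``GENEA<TAB>relation<TAB>GENEB`` per line, with an optional fourth
    column giving the pathway id; lines without it fall into a single pathway
    named after the file stem.
Background
    Two-column TSV ``gene_a<TAB>gene_b`` (canonical order), optional third
    column ``provenance`` in {observed, random, both}.
Results
    TSV with columns pathway_id, name, n_pairs_used, DysPS, pval, FDR,
    direction, ordered by pval ascending then |DysPS| descending; reals are
    printed with 10 significant digits so the table round-trips losslessly.

Gene symbols are compared byte-wise; there is no case folding.  Missing
expression values are rejected by default (``missing="error"``); opt-in
row-mean imputation is available because silent imputation would change
scores.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .background import canonical_pair
from .datamodel import (
    BackgroundSet,
    DyspiaError,
    EnrichmentResult,
    ExpressionMatrix,
    GenePair,
    ParseError,
    PathwayPairSet,
    PhenotypeLabels,
    SelfPairError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "null", "."}

RESULT_COLUMNS = ["pathway_id", "name", "n_pairs_used", "DysPS", "pval", "FDR", "direction"]


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValidationError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")


def read_expression(
    path: str | os.PathLike,
    dialect: str = "tsv",
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    ``missing`` is ``"error"`` (default) or ``"impute-row-mean"``.  Duplicate
    gene rows keep the first occurrence with a warning.  Malformed numeric
    cells always raise :class:`ParseError` naming the cell.
    """
    if missing not in ("error", "impute-row-mean"):
        raise ValidationError(f"unknown missing-value policy {missing!r}")
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(
            f"expression matrix needs at least 2 samples, found {df.shape[1]}"
        )
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        warnings.warn(
            f"duplicate gene rows {dups[:5]}: keeping the first occurrence",
            stacklevel=2,
        )
        df = df[~df.index.duplicated(keep="first")]

    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    miss_mask = np.zeros(df.shape, dtype=bool)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(pd.Series(raw[:, j]), errors="coerce").to_numpy()
        bad = np.isnan(col)
        if bad.any():
            for i in np.flatnonzero(bad):
                token = str(raw[i, j]).strip()
                if token.lower() in _MISSING_TOKENS:
                    miss_mask[i, j] = True
                else:
                    raise ParseError(
                        f"malformed numeric cell {raw[i, j]!r} at gene "
                        f"{df.index[i]!r}, sample {df.columns[j]!r}"
                    )
        values[:, j] = col
    if miss_mask.any():
        if missing == "error":
            i, j = map(int, np.argwhere(miss_mask)[0])
            raise ParseError(
                f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r} "
                f"(pass missing='impute-row-mean' to impute)"
            )
        row_mean = np.nanmean(np.where(miss_mask, np.nan, values), axis=1)
        ii, jj = np.nonzero(miss_mask)
        values[ii, jj] = row_mean[ii]
        logger.info("imputed %d missing cells with row means", int(miss_mask.sum()))
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", float_format="%.10g")


def read_phenotype(path: str | os.PathLike, case_label: str | None = None) -> PhenotypeLabels:
    """Read two-column ``sample_id<TAB>group`` labels.

    If the file's groups are not literally ``case``/``control``,
    ``case_label`` must name the level to treat as case.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     dtype=str, comment="#")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"duplicate sample ids in phenotype file {path}")
    mapping = dict(zip(df["sample_id"], df["group"]))
    levels = set(mapping.values())
    if case_label is None:
        if levels != {"case", "control"}:
            raise ValidationError(
                f"phenotype groups {sorted(levels)} are not 'case'/'control'; "
                f"pass case_label to pick the case group"
            )
        return PhenotypeLabels(mapping)
    return PhenotypeLabels.from_mapping(mapping, case_label=case_label)


def write_phenotype(labels: PhenotypeLabels, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, group in labels.assignments.items():
            fh.write(f"{sample}\t{group}\n")


def _add_pair(pairs: set[GenePair], a: str, b: str, where: str) -> bool:
    """Canonicalize and add; self-pairs are dropped with a warning."""
    try:
        pairs.add(canonical_pair(a, b))
        return True
    except SelfPairError:
        warnings.warn(f"self-pair {a}|{b} dropped ({where})", stacklevel=3)
        return False


def read_pathway_pairs(path: str | os.PathLike, fmt: str = "pair_gmt") -> list[PathwayPairSet]:
    """Read pathway gene-pair sets in pair_gmt (native) or SIF format."""
    if fmt == "pair_gmt":
        return _read_pair_gmt(path)
    if fmt == "sif":
        return _read_sif(path)
    raise ValidationError(f"unknown pathway format {fmt!r} (expected 'pair_gmt' or 'sif')")


def _read_pair_gmt(path: str | os.PathLike) -> list[PathwayPairSet]:
    pathways: list[PathwayPairSet] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: pair_gmt line needs id, description and "
                    f"at least one pair token"
                )
            pid, desc, *tokens = fields
            if pid in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            seen_ids.add(pid)
            pairs: set[GenePair] = set()
            for tok in tokens:
                if tok == "":
                    continue
                if "|" not in tok:
                    raise ParseError(
                        f"{path}:{lineno}: token {tok!r} is not a GENEA|GENEB pair"
                    )
                a, _, b = tok.partition("|")
                _add_pair(pairs, a, b, f"{path}:{lineno}")
            if not pairs:
                warnings.warn(
                    f"pathway {pid!r} at {path}:{lineno} has no valid pairs; skipped",
                    stacklevel=2,
                )
                continue
            pathways.append(PathwayPairSet(pathway_id=pid, name=desc, pairs=frozenset(pairs)))
    return pathways


def _read_sif(path: str | os.PathLike) -> list[PathwayPairSet]:
    default_id = Path(path).stem
    grouped: dict[str, set[GenePair]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise ParseError(
                    f"{path}:{lineno}: SIF line needs 3 columns "
                    f"(source, relation, target) with an optional pathway id"
                )
            a, _, b = fields[:3]
            pid = fields[3] if len(fields) == 4 else default_id
            if pid not in grouped:
                grouped[pid] = set()
                order.append(pid)
            _add_pair(grouped[pid], a, b, f"{path}:{lineno}")
    pathways = []
    for pid in order:
        if not grouped[pid]:
            warnings.warn(f"pathway {pid!r} in {path} has no valid pairs; skipped",
                          stacklevel=2)
            continue
        pathways.append(PathwayPairSet(pathway_id=pid, name=pid, pairs=frozenset(grouped[pid])))
    return pathways


def write_pathway_pairs(pathways: Sequence[PathwayPairSet], path: str | os.PathLike) -> None:
    """Write pathways in the native pair_gmt dialect (pairs sorted for determinism)."""
    with open(path, "w") as fh:
        for pw in pathways:
            tokens = "\t".join(p.label for p in sorted(pw.pairs))
            fh.write(f"{pw.pathway_id}\t{pw.name}\t{tokens}\n")


def read_background(path: str | os.PathLike) -> BackgroundSet:
    """Read a background pair list (optional provenance column)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    cols = list(df.columns)
    if cols[:2] != ["gene_a", "gene_b"]:
        raise ParseError(
            f"background file {path} must start with columns gene_a, gene_b"
        )
    pairs = [canonical_pair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
    if "provenance" in cols:
        prov = list(df["provenance"])
    else:
        prov = ["observed"] * len(pairs)
    return BackgroundSet(pairs=pairs, provenance=prov)


def write_background(bg: BackgroundSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tprovenance\n")
        for pair, prov in zip(bg.pairs, bg.provenance):
            fh.write(f"{pair.gene_a}\t{pair.gene_b}\t{prov}\n")


def results_to_dataframe(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (r.pathway_id, r.name, r.n_pairs_used, r.dysps, r.pval, r.fdr, r.direction)
        for r in results
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.sort_values(
        by=["pval", "DysPS", "pathway_id"],
        key=lambda s: -s.abs() if s.name == "DysPS" else s,
        kind="stable",
    ).reset_index(drop=True)


def write_results(results: Sequence[EnrichmentResult], path: str | os.PathLike) -> None:
    """Write the result table (pval ascending, then |DysPS| descending)."""
    if not results:
        raise ValidationError("refusing to write an empty result table")
    df = results_to_dataframe(results)
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    except OSError as e:
        raise DyspiaError(f"cannot write results to {path}: {e}") from e


def read_results(path: str | os.PathLike) -> list[EnrichmentResult]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"result table {path} lacks columns {missing}")
    return [
        EnrichmentResult(
            pathway_id=str(pid),
            name=str(name),
            n_pairs_used=int(n),
            dysps=float(d),
            pval=float(p),
            fdr=float(f),
            direction=str(direction),
        )
        for pid, name, n, d, p, f, direction in zip(
            df["pathway_id"], df["name"], df["n_pairs_used"], df["DysPS"],
            df["pval"], df["FDR"], df["direction"],
        )
    ]
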