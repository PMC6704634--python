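"""Tab-separated readers and writers for expression matrices and result tables."""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import pandas as pd

from .design import NestedDesign
from .model import GeneClassification
from .selection import TargetCall

__all__ = ["MatrixParseError", "read_expression_matrix", "write_expression_matrix",
           "write_results", "write_classifications"]

logger = logging.getLogger(__name__)


class MatrixParseError(ValueError):
    """Malformed expression matrix file (missing/non-numeric cells, bad shape)."""


def read_expression_matrix(
    path: str, design: NestedDesign | None = None
) -> pd.DataFrame:
    """Read a gene x condition TSV: header row, first column gene/probe ids.

    If a design is given, columns are matched to its condition labels by
    header name; on mismatch the columns are taken positionally (with a
    warning) provided the count agrees.  Missing or non-numeric cells raise
    :class:`MatrixParseError` naming the offending row and column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise MatrixParseError(f"{path}: no expression columns after the id column")
    try:
        matrix = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        matrix = raw.apply(pd.to_numeric, errors="coerce")
    bad = matrix.isna() & raw.notna()
    missing = raw.isna()
    problems = bad | missing
    if problems.any().any():
        r, c = next(zip(*problems.to_numpy().nonzero()))
        kind = "missing value" if missing.iat[r, c] else f"non-numeric cell {raw.iat[r, c]!r}"
        # +2: header line plus 1-based counting
        raise MatrixParseError(
            f"{path}: {kind} at line {r + 2}, column {raw.columns[c]!r} "
            f"(gene {raw.index[r]!r})"
        )
    matrix = matrix.astype(float)
    if design is not None:
        expected = list(design.condition_labels)
        if matrix.shape[1] != len(expected):
            raise MatrixParseError(
                f"{path}: {matrix.shape[1]} expression columns, design expects "
                f"{len(expected)}"
            )
        if list(matrix.columns) == expected:
            pass
        elif set(matrix.columns) == set(expected):
            matrix = matrix[expected]
        else:
            warnings.warn(
                f"{path}: column headers do not match design condition labels; "
                "matching by position",
                UserWarning,
                stacklevel=2,
            )
            matrix.columns = expected
    matrix.index = matrix.index.astype(str)
    matrix.index.name = raw.index.name or "gene_id"
    return matrix


def write_expression_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_results(
    classifications: Sequence[GeneClassification],
    calls: Sequence[TargetCall],
    path: str,
    group_order: Sequence[str],
    annotation: pd.DataFrame | None = None,
) -> None:
    """Write the per-gene result table as TSV, deterministically.

    Columns: gene_id, [gene_symbol,] posterior_<g> per group (6 significant
    digits), assigned_group, posterior_assigned_3dp (assigned-group posterior
    at 3 decimals, the precision used in reports), log2fc, se, direction,
    selected.  Fold-change columns are filled only for genes with a target
    call.  Rows keep the classification order; reruns are byte-identical.
    """
    call_by_id = {t.gene_id: t for t in calls}
    symbol = None
    if annotation is not None:
        first = annotation.columns[0]
        symbol = annotation[first].astype(str).to_dict()

    header = ["gene_id"]
    if symbol is not None:
        header.append("gene_symbol")
    header += [f"posterior_{g}" for g in group_order]
    header += ["assigned_group", "posterior_assigned_3dp",
               "log2fc", "se", "direction", "selected"]

    lines = ["\t".join(header)]
    for c in classifications:
        row = [c.gene_id]
        if symbol is not None:
            row.append(symbol.get(c.gene_id, "NA"))
        row += [_fmt(c.fits[g].posterior) for g in group_order]
        row += [c.assigned_group, f"{c.assigned_posterior:.3f}"]
        call = call_by_id.get(c.gene_id)
        if call is None:
            row += ["NA", "NA", "NA", "NA"]
        else:
            row += [_fmt(call.log2fc), _fmt(call.se), call.direction,
                    "1" if call.selected else "0"]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("wrote %d rows to %s", len(classifications), path)


def write_classifications(
    classifications: Sequence[GeneClassification],
    path: str,
    group_order: Sequence[str],
) -> None:
    """Classification-only table: id, per-group posteriors, group, degenerate flag."""
    header = (["gene_id"] + [f"posterior_{g}" for g in group_order]
              + ["assigned_group", "degenerate"])
    lines = ["\t".join(header)]
    for c in classifications:
        lines.append("\t".join(
            [c.gene_id]
            + [_fmt(c.fits[g].posterior) for g in group_order]
            + [c.assigned_group, "1" if c.degenerate_flag else "0"]
        ))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
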