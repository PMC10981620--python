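"""Readers and writers for the pipeline's external formats.

Formats: expression TSV (features x samples), GMT gene-set collections,
GO annotation TSV, and generic result tables. Loaders validate strictly
and never drop data silently: every rejected row or line is listed in the
raised :class:`FormatError`'s report.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GoTermTable,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"  # fixed rendered precision for all written tables


class FormatError(ValueError):
    """A file violates the expected format.

    Attributes
    ----------
    report:
        List of human-readable strings, one per offending row/line/cell.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = list(report or [])


def read_expression_tsv(path, feature_kind: str, unit: str = "arbitrary") -> ExpressionMatrix:
    """Read a features x samples expression TSV.

    First row is the header of sample IDs; first column holds feature IDs.
    Any non-numeric or missing cell is a hard error (the correlation
    stages require complete vectors); the error report names every
    offending (row, column) cell.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")

    dupes = raw.index[raw.index.duplicated()].unique().tolist()
    if dupes:
        raise FormatError(
            f"{path}: duplicate feature IDs: {', '.join(map(str, dupes))}",
            report=[f"duplicate feature ID {d!r}" for d in dupes],
        )
    sdupes = raw.columns[raw.columns.duplicated()].unique().tolist()
    if sdupes:
        raise FormatError(
            f"{path}: duplicate sample IDs: {', '.join(map(str, sdupes))}",
            report=[f"duplicate sample ID {d!r}" for d in sdupes],
        )

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        report = []
        for gene, col in zip(*np.where(bad.to_numpy())):
            cell = raw.iat[gene, col]
            report.append(
                f"row {raw.index[gene]!r}, column {raw.columns[col]!r}: "
                f"non-numeric value {cell!r}"
            )
        raise FormatError(
            f"{path}: {len(report)} non-numeric cell(s); "
            f"first: {report[0]}",
            report=report,
        )
    return ExpressionMatrix(numeric.astype(float), feature_kind=feature_kind, unit=unit)


def write_expression_tsv(matrix: ExpressionMatrix, path, seed=None) -> None:
    """Write an expression matrix as TSV with a version comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        matrix.data.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index_label="feature_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: set_id <TAB> description <TAB> members...

    Duplicate members within a line are deduplicated; the total number of
    duplicates removed is logged as a warning. File order is preserved.
    """
    path = Path(path)
    sets = []
    n_dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected set_id, description, and at least one member",
                    report=[f"line {lineno}: {line[:80]!r}"],
                )
            set_id, description, *members = fields
            unique = list(dict.fromkeys(members))
            n_dupes += len(members) - len(unique)
            sets.append(GeneSet(set_id, description, frozenset(unique)))
    if n_dupes:
        logger.warning("%s: removed %d duplicate member(s) within lines", path, n_dupes)
    collection = GeneSetCollection(sets)
    collection.n_duplicates_removed = n_dupes
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a gene-set collection in GMT format (members sorted for determinism)."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def read_go_table(path) -> GoTermTable:
    """Read a GO annotation TSV with header ``term_id, name, description``.

    A missing description is accepted as empty; a duplicated term_id is an
    error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = ["term_id", "name", "description"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    dupes = df["term_id"][df["term_id"].duplicated()].unique().tolist()
    if dupes:
        raise FormatError(
            f"{path}: duplicate GO term IDs: {', '.join(dupes)}",
            report=[f"duplicate term_id {d!r}" for d in dupes],
        )
    return GoTermTable(df[required].copy())


def write_go_table(table: GoTermTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def write_results_table(records, path, seed=None, columns=None) -> None:
    """Write homogeneous result records (dataclasses or dicts) as a TSV.

    Column order is the dataclass field order (or the first record's key
    order); floats are rendered at 6 significant digits; list-valued
    fields are comma-joined. An empty record list produces a header-only
    file when the record type is known, otherwise an empty file with just
    the comment header.
    """
    path = Path(path)
    rows = []
    columns = list(columns) if columns is not None else None
    for rec in records:
        if dataclasses.is_dataclass(rec):
            d = dataclasses.asdict(rec)
        elif isinstance(rec, dict):
            d = dict(rec)
        else:
            raise TypeError(f"cannot serialise record of type {type(rec)}")
        if columns is None:
            columns = list(d)
        elif list(d) != columns:
            raise ValueError("heterogeneous records: differing fields")
        rows.append(
            {k: ",".join(map(str, v)) if isinstance(v, (list, tuple)) else v
             for k, v in d.items()}
        )
    df = pd.DataFrame(rows, columns=columns)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _comment_header(seed=None) -> str:
    from . import __version__

    line = f"# mirimmune {__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"
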