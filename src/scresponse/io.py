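"""Readers and writers for every on-disk artifact.

Formats: TSV (UTF-8, header row) for matrices, metadata, survival and DEG
tables; MatrixMarket MTX with sidecar ``.rows.txt``/``.cols.txt`` name files
for sparse matrices; GMT for gene sets; JSON for reports and truth. All
coordinates are identifier-based.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    validate_cell_metadata,
    validate_survival,
)
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

GENES_IN_ROWS = "genes_in_rows"
CELLS_IN_ROWS = "cells_in_rows"
_LAYOUTS = (GENES_IN_ROWS, CELLS_IN_ROWS)


def _check_layout(layout: str) -> None:
    if layout not in _LAYOUTS:
        raise ValidationError(f"layout must be one of {_LAYOUTS}, got {layout!r}")


def read_expression_matrix(path: str | Path, layout: str = GENES_IN_ROWS) -> ExpressionMatrix:
    """Read an expression matrix from TSV or MTX(+name files).

    ``layout`` states the on-disk orientation; the returned matrix is always
    rows = cells/samples, columns = genes. TSV files carry identifiers in the
    first column and header; ``foo.mtx`` expects ``foo.mtx.rows.txt`` and
    ``foo.mtx.cols.txt`` sidecars with one identifier per line.
    """
    _check_layout(layout)
    path = Path(path)
    if not path.exists():
        raise ParseError(f"expression matrix file not found: {path}")
    if path.suffix == ".mtx":
        frame = _read_mtx_frame(path)
    else:
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except ValueError as exc:
            raise ParseError(f"{path}: could not parse TSV matrix: {exc}") from exc
        non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
        if non_numeric:
            raise ParseError(f"{path}: non-numeric entries in columns {non_numeric[:5]}")
    if layout == GENES_IN_ROWS:
        frame = frame.T
    return ExpressionMatrix(frame)


def _read_mtx_frame(path: Path) -> pd.DataFrame:
    rows_path = path.with_suffix(path.suffix + ".rows.txt")
    cols_path = path.with_suffix(path.suffix + ".cols.txt")
    for sidecar in (rows_path, cols_path):
        if not sidecar.exists():
            raise ParseError(f"MTX name file missing: {sidecar}")
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: invalid MatrixMarket file: {exc}") from exc
    rows = rows_path.read_text().splitlines()
    cols = cols_path.read_text().splitlines()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(rows), len(cols)):
        raise ParseError(
            f"{path}: dimension mismatch; matrix is {dense.shape} but name files "
            f"give ({len(rows)}, {len(cols)})"
        )
    return pd.DataFrame(dense, index=rows, columns=cols)


def write_expression_matrix(
    X: ExpressionMatrix, path: str | Path, layout: str = GENES_IN_ROWS
) -> Path:
    """Write a matrix as TSV (default) or MTX+name files by suffix."""
    _check_layout(layout)
    path = Path(path)
    frame = X.data.T if layout == GENES_IN_ROWS else X.data
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(frame.to_numpy()))
        path.with_suffix(path.suffix + ".rows.txt").write_text(
            "\n".join(map(str, frame.index)) + "\n"
        )
        path.with_suffix(path.suffix + ".cols.txt").write_text(
            "\n".join(map(str, frame.columns)) + "\n"
        )
    else:
        frame.to_csv(path, sep="\t")
    return path


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Preserves file order of sets and of genes within sets. Duplicate genes
    within one set are dropped with a logged warning; duplicate set names and
    lines with fewer than three fields are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"GMT file not found: {path}")
    sets: list[tuple[str, list[str]]] = []
    names: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields; "
                "expected name, description and at least one gene"
            )
        name, _desc, *genes = fields
        name = name.strip()
        if name in names:
            raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        names.add(name)
        genes = [g.strip() for g in genes if g.strip()]
        if len(set(genes)) < len(genes):
            logger.warning("%s:%d: duplicate genes within set %r deduplicated", path, lineno, name)
        sets.append((name, genes))
    if not sets:
        raise ParseError(f"{path}: GMT file contains no gene sets")
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell metadata TSV."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_cell_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t", index=False)
    return path


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read and validate a survival TSV (sample_id, time, event[, group])."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"survival file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    return validate_survival(df)


def write_survival(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_survival(df).to_csv(path, sep="\t", index=False)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def read_json(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise ParseError(f"JSON file not found: {path}")
    return json.loads(path.read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
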