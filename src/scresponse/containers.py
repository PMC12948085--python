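"""In-memory containers: expression matrices, metadata tables, gene sets.

The pipeline works on labelled 2-D matrices (cells x genes for single-cell
data, samples x genes for bulk) on a log2(TPM+1)-like scale, per-cell
metadata, and ordered named gene sets. Containers validate their invariants
on construction so downstream stages can assume them.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

RESPONDER = "responder"
NON_RESPONDER = "non-responder"
RESPONSE_VALUES = (RESPONDER, NON_RESPONDER)
TIMEPOINT_VALUES = ("baseline", "post-treatment", "unknown")

#: RECIST-style clinical labels collapse onto the binary response vocabulary:
#: complete/partial response -> responder, progressive/stable disease -> non-responder.
CLINICAL_RESPONSE_MAP = {
    "CR": RESPONDER,
    "PR": RESPONDER,
    "PD": NON_RESPONDER,
    "SD": NON_RESPONDER,
    RESPONDER: RESPONDER,
    NON_RESPONDER: NON_RESPONDER,
}

METADATA_COLUMNS = ("cell_id", "sample_id", "patient_id", "response", "timepoint")
SURVIVAL_COLUMNS = ("sample_id", "time", "event")


def map_response(value: str) -> str:
    """Map a clinical response label onto the binary responder vocabulary."""
    key = str(value).strip()
    mapped = CLINICAL_RESPONSE_MAP.get(key) or CLINICAL_RESPONSE_MAP.get(key.upper())
    if mapped is None:
        raise ValidationError(
            f"response value {value!r} is outside the vocabulary "
            f"{sorted(set(CLINICAL_RESPONSE_MAP))}"
        )
    return mapped


class ExpressionMatrix:
    """A cells-x-genes (or samples-x-genes) expression matrix.

    Values are finite, non-negative reals on a log2(x+1) scale. Row
    identifiers are cells/samples, column identifiers are gene symbols;
    both must be unique. Gene symbols are matched case-sensitively after
    whitespace stripping; no alias resolution is attempted.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise ValidationError("ExpressionMatrix requires a pandas DataFrame")
        data = data.copy()
        data.index = data.index.astype(str).str.strip()
        data.columns = data.columns.astype(str).str.strip()
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate row identifiers: {dup}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate gene identifiers: {dup}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric entries")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "expression values must be finite and >= 0; offending entry "
                f"({data.index[i]!r}, {data.columns[j]!r}) = {values[i, j]!r}"
            )
        self._data = data.astype(float)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def row_ids(self) -> pd.Index:
        return self._data.index

    @property
    def gene_ids(self) -> pd.Index:
        return self._data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset(self, rows: Sequence[str] | None = None, genes: Sequence[str] | None = None) -> "ExpressionMatrix":
        data = self._data
        if rows is not None:
            missing = [r for r in rows if r not in data.index]
            if missing:
                raise ValidationError(f"rows absent from matrix: {missing[:5]}")
            data = data.loc[list(rows)]
        if genes is not None:
            missing = [g for g in genes if g not in data.columns]
            if missing:
                raise ValidationError(f"genes absent from matrix: {missing[:5]}")
            data = data[list(genes)]
        return ExpressionMatrix(data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"ExpressionMatrix({n} rows x {m} genes)"


class GeneSetCollection:
    """Ordered mapping of pathway name -> list of gene symbols.

    Set order and within-set gene order are preserved (they define the
    canonical gene-pathway image layout). Names are unique, no set is
    empty, and genes may belong to several sets.
    """

    def __init__(self, sets: Mapping[str, Sequence[str]] | Iterable[tuple[str, Sequence[str]]]):
        items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
        self._sets: dict[str, list[str]] = {}
        for name, genes in items:
            name = str(name).strip()
            genes = [str(g).strip() for g in genes]
            if name in self._sets:
                raise ValidationError(f"duplicate gene-set name: {name!r}")
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            # keep first occurrence of each gene (idempotent membership)
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g)
            self._sets[name] = list(seen)
        if not self._sets:
            raise ValidationError("gene-set collection is empty")

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def items(self) -> Iterator[tuple[str, list[str]]]:
        return ((k, list(v)) for k, v in self._sets.items())

    def all_genes(self) -> list[str]:
        """Union of member genes, in first-occurrence order."""
        seen: dict[str, None] = {}
        for genes in self._sets.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets, {len(self.all_genes())} genes)"


def validate_cell_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a per-cell metadata table.

    Required columns: cell_id, sample_id, patient_id, response, timepoint.
    Responses are mapped onto the binary vocabulary; every sample must map
    to exactly one response. Extra columns are preserved.
    """
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata is missing required columns: {missing}")
    df = df.copy()
    for col in ("cell_id", "sample_id", "patient_id"):
        df[col] = df[col].astype(str).str.strip()
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].unique().tolist()[:5]
        raise ValidationError(f"duplicate cell_id values: {dup}")
    if df["response"].isna().any():
        raise ValidationError("response is missing for some cells")
    df["response"] = df["response"].map(map_response)
    df["timepoint"] = df["timepoint"].astype(str).str.strip()
    bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINT_VALUES))
    if bad_tp:
        raise ValidationError(
            f"timepoint values outside vocabulary {TIMEPOINT_VALUES}: {bad_tp}"
        )
    per_sample = df.groupby("sample_id")["response"].nunique()
    conflicted = per_sample[per_sample > 1].index.tolist()
    if conflicted:
        raise ValidationError(
            f"samples mapping to more than one response: {conflicted[:5]}"
        )
    return df


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table: sample_id, time > 0, event in {0, 1}."""
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"survival table is missing required columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
    if (df["time"] <= 0).any() or not np.isfinite(df["time"]).all():
        bad = df.loc[df["time"] <= 0, "sample_id"].tolist()[:5]
        raise ValidationError(f"non-positive survival times for samples: {bad}")
    events = pd.to_numeric(df["event"], errors="raise")
    if not events.isin([0, 1]).all():
        raise ValidationError("event must be 0 (censored) or 1 (event)")
    df["event"] = events.astype(int)
    return df


def align_metadata(X: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Align metadata rows 1:1 with the matrix rows (inner identity join).

    Raises if any metadata cell is absent from the matrix or vice versa, so
    modelling stages only ever see cells present in both.
    """
    meta = validate_cell_metadata(meta)
    matrix_ids = set(X.row_ids)
    meta_ids = set(meta["cell_id"])
    orphan_meta = sorted(meta_ids - matrix_ids)
    orphan_matrix = sorted(matrix_ids - meta_ids)
    if orphan_meta or orphan_matrix:
        raise ValidationError(
            "matrix/metadata misalignment; "
            f"cells only in metadata: {orphan_meta[:5]} "
            f"(n={len(orphan_meta)}); cells only in matrix: {orphan_matrix[:5]} "
            f"(n={len(orphan_matrix)})"
        )
    meta = meta.set_index("cell_id", drop=False).loc[X.row_ids].reset_index(drop=True)
    return meta
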