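"""Expression-matrix and sample-metadata containers and TSV/CSV I/O.

The central container is :class:`ExpressionMatrix`: a dense genes x samples
matrix of log-scale expression values with unique gene and sample
identifiers.  Raw TPM matrices pass through :func:`filter_by_abundance`
(keep genes with TPM >= 0.5 in at least half the samples) and
:func:`log_transform` (``log2(TPM + 1)``) before modeling.

Files are plain delimited text: genes as rows, samples as columns, the
first column holding gene IDs.  Tab-delimited is the canonical dialect;
comma-delimited is accepted via ``dialect="csv"``.  Missing values are
rejected rather than imputed — the downstream linear-model machinery
assumes complete matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, IdentityError, ParseError

_DELIMS = {"tsv": "\t", "csv": ","}


def _delimiter(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise ParseError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise IdentityError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix with identifiers.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row of ``values``.
    sample_ids
        Unique sample identifiers, one per column of ``values``.
    values
        2-D float array of shape ``(len(gene_ids), len(sample_ids))``
        containing finite values (log2 scale after preprocessing).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.ndim != 2:
            raise ParseError("expression values must form a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise IdentityError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DomainError(
                "missing or non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to a boolean mask or ID list over genes."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            try:
                idx = np.array([pos[g] for g in mask_or_ids], dtype=int)
            except KeyError as exc:
                raise IdentityError(f"unknown gene identifier: {exc.args[0]!r}") from None
        return ExpressionMatrix([self.gene_ids[i] for i in idx], list(self.sample_ids),
                                self.values[idx])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise IdentityError(f"unknown sample identifier: {exc.args[0]!r}") from None
        return ExpressionMatrix(list(self.gene_ids), [self.sample_ids[i] for i in idx],
                                self.values[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample annotations: time in hours plus arbitrary covariates.

    ``table`` has one row per sample, indexed by sample ID, with a ``time``
    column (hours; interpreted modulo the period downstream) and any number
    of additional covariate columns (condition, subject, age, region, ...).
    """

    table: pd.DataFrame
    time_col: str = "time"

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise IdentityError(f"duplicate sample identifier: {dup!r}")
        if self.time_col not in self.table.columns:
            raise ConfigError(f"metadata is missing required time column {self.time_col!r}")
        times = pd.to_numeric(self.table[self.time_col], errors="coerce")
        if not np.all(np.isfinite(times.to_numpy(dtype=float))):
            raise DomainError("sample times must be finite numbers")
        self.table = self.table.copy()
        self.table[self.time_col] = times.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def time(self) -> np.ndarray:
        return self.table[self.time_col].to_numpy(dtype=float)

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise ConfigError(f"covariate {name!r} not found in sample metadata")
        return self.table[name]

    def aligned_to(self, expr: ExpressionMatrix) -> "SampleMetadata":
        """Reorder rows to match the expression matrix's sample order.

        The two sample-ID sets must be identical.
        """
        if set(self.sample_ids) != set(expr.sample_ids):
            missing = set(expr.sample_ids) - set(self.sample_ids)
            extra = set(self.sample_ids) - set(expr.sample_ids)
            raise IdentityError(
                f"metadata/expression sample mismatch; missing from metadata: "
                f"{sorted(missing)[:5]}, absent from expression: {sorted(extra)[:5]}"
            )
        return SampleMetadata(self.table.loc[expr.sample_ids], self.time_col)


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples expression table.

    First column = gene IDs, header row = sample IDs, numeric body.
    """
    sep = _delimiter(dialect)
    try:
        # round_trip parsing keeps every binary64 value bit-exact
        frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not read expression table {path}: {exc}") from exc
    if frame.shape[0] == 0:
        raise ParseError(f"no genes: expression table {path} has a header but no rows")
    if frame.shape[1] == 0:
        raise ParseError(f"no samples: expression table {path} has no data columns")
    for c, col in enumerate(frame.columns):
        if not pd.api.types.is_numeric_dtype(frame[col]):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            r = int(np.argmax(coerced.isna().to_numpy()))
            raise ParseError(
                f"non-numeric expression value {frame.iat[r, c]!r} at gene "
                f"{frame.index[r]!r} (row {r + 2}), sample {col!r} (column {c + 2})"
            )
    frame.index = frame.index.astype(str)
    return ExpressionMatrix(list(frame.index), list(map(str, frame.columns)),
                            frame.to_numpy(dtype=float))


def write_expression(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    # %.17g guarantees binary64 round-trips through the text format
    expr.to_frame().to_csv(path, sep=_delimiter(dialect), float_format="%.17g")


def read_metadata(path, dialect: str = "tsv", time_col: str = "time") -> SampleMetadata:
    """Read a per-sample metadata table (one row per sample, ``sample_id`` column)."""
    sep = _delimiter(dialect)
    try:
        frame = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"could not read metadata table {path}: {exc}") from exc
    if "sample_id" not in frame.columns:
        raise ParseError(f"metadata table {path} lacks a 'sample_id' column")
    frame = frame.set_index(frame["sample_id"].astype(str)).drop(columns="sample_id")
    frame.index.name = "sample_id"
    return SampleMetadata(frame, time_col=time_col)


def write_metadata(meta: SampleMetadata, path, dialect: str = "tsv") -> None:
    meta.table.to_csv(path, sep=_delimiter(dialect), index_label="sample_id")


def filter_by_abundance(tpm: ExpressionMatrix, min_tpm: float = 0.5,
                        min_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep genes with TPM >= ``min_tpm`` in at least ``min_fraction`` of samples.

    "At least half the samples" is read literally: the required count is
    ``ceil(min_fraction * n_samples)``.
    """
    if np.any(tpm.values < 0):
        raise DomainError("abundance filtering expects non-negative TPM values")
    required = math.ceil(min_fraction * tpm.n_samples)
    keep = (tpm.values >= min_tpm).sum(axis=1) >= required
    return tpm.subset_genes(keep)


def log_transform(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """Transform each TPM value ``v`` to ``log2(v + 1)``."""
    if np.any(tpm.values < 0):
        raise DomainError("log transform expects non-negative TPM values")
    return ExpressionMatrix(list(tpm.gene_ids), list(tpm.sample_ids),
                            np.log2(tpm.values + 1.0))


def write_results(table: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write a per-gene result table (gene_id, statistic, p/q values, coefficients)."""
    table.to_csv(path, sep=_delimiter(dialect), index=False)
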