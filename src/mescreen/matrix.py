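"""Reading, validating and writing the tabular artifacts of the screen.

The raw input is a gene-by-sample matrix of TPM (transcripts per million)
values: tab-separated text, UTF-8, a header row of sample identifiers whose
first column is the literal ``gene_id``, one row per gene.  Absence of
expression is encoded as an exact 0; missing cells are not permitted.  Gene
and sample identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

GENE_ID_COLUMN = "gene_id"

#: significant digits used when serializing floating-point result columns
FLOAT_DIGITS = 6

PathLike = Union[str, Path]


class MatrixFormatError(ValueError):
    """Raised when an input table violates the expression-matrix contract."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated nonnegative gene x sample TPM matrix.

    Wraps a :class:`pandas.DataFrame` with genes on the index and samples on
    the columns.  Construction validates the invariants: finite nonnegative
    values, unique gene and sample identifiers, non-empty shape.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise MatrixFormatError("empty expression matrix (no genes or no samples)")
        dup_genes = df.index[df.index.duplicated()].unique().tolist()
        if dup_genes:
            raise MatrixFormatError(f"duplicate gene id(s): {dup_genes}")
        dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise MatrixFormatError(f"duplicate sample id(s): {dup_samples}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_offender(df, lambda v: not _is_number(v))
            raise MatrixFormatError(f"non-numeric cell at (gene={bad[0]!r}, sample={bad[1]!r})")
        bad_mask = ~np.isfinite(values) | (values < 0)
        if bad_mask.any():
            g, s = np.argwhere(bad_mask)[0]
            raise MatrixFormatError(
                f"negative or non-finite TPM at (gene={df.index[g]!r}, "
                f"sample={df.columns[s]!r}): {values[g, s]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def _first_offender(df: pd.DataFrame, pred) -> tuple[str, str]:
    for gene, row in df.iterrows():
        for sample, v in row.items():
            if pred(v):
                return str(gene), str(sample)
    raise AssertionError("no offending cell found")  # pragma: no cover


def read_expression_matrix(path: PathLike, delimiter: str = "\t") -> ExpressionMatrix:
    """Read and validate a gene x sample TPM table.

    Parameters
    ----------
    path
        Delimited text file: header row of sample ids (first column
        ``gene_id``), one row per gene, nonnegative numeric cells.
    delimiter
        Field separator, tab by default.

    Raises
    ------
    MatrixFormatError
        On duplicate identifiers, negative/non-numeric cells, or an empty
        matrix; the message names the offending gene/sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = GENE_ID_COLUMN
    # coerce cell-wise so the error can cite coordinates
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        non_numeric = df.map(lambda v: not _is_number(v))
        g, s = _first_offender(df, lambda v: not _is_number(v)) if non_numeric.any().any() else ("?", "?")
        raise MatrixFormatError(f"non-numeric cell at (gene={g!r}, sample={s!r})")
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    """Write a TPM matrix as the tab-separated dialect `read_expression_matrix` accepts."""
    matrix.data.to_csv(path, sep="\t", index_label=GENE_ID_COLUMN, float_format=f"%.{FLOAT_DIGITS}g")


def write_results_table(records: pd.DataFrame, path: PathLike) -> None:
    """Write a per-gene results table as tab-separated text with a header.

    Floating-point columns are serialized at %.6g; an empty table yields a
    header-only file.  The parent directory must exist and be writable.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    records.to_csv(path, sep="\t", index=False, float_format=f"%.{FLOAT_DIGITS}g")


def read_results_table(path: PathLike) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")
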