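"""Matrix ingestion and preparation.

Reads sparse Matrix Market or delimited-text matrices into a
:class:`RawMatrix` and prepares them into the dense samples x features
layout the SVD core expects: orientation (transposing a features x samples
matrix, the usual on-disk layout for single-cell counts where genes are
rows), optional log transform with pseudocount, column mean-centering and
unit-variance scaling. Transformations are applied in the fixed order
transpose -> log -> center -> scale, and the full provenance is recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    DimensionMismatchError,
    InvalidValueError,
    MatrixParseError,
    OrientationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RawMatrix",
    "PrepProvenance",
    "PreparedMatrix",
    "read_matrix",
    "write_matrix",
    "prep_matrix",
]

ORIENTATIONS = ("samples_by_features", "features_by_samples", "unknown")


@dataclass
class RawMatrix:
    """A loaded matrix plus optional dimension names and declared orientation.

    ``values`` may be a dense ndarray or a scipy sparse matrix; sparsity is
    preserved until :func:`prep_matrix` densifies. NaN entries are rejected
    at construction.
    """

    values: Union[np.ndarray, sp.spmatrix]
    row_names: Optional[list[str]] = None
    col_names: Optional[list[str]] = None
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        n_rows, n_cols = self.shape
        if self.row_names is not None and len(self.row_names) != n_rows:
            raise DimensionMismatchError(
                f"dimension mismatch: {len(self.row_names)} row names for {n_rows} rows"
            )
        if self.col_names is not None and len(self.col_names) != n_cols:
            raise DimensionMismatchError(
                f"dimension mismatch: {len(self.col_names)} column names for {n_cols} columns"
            )
        data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
        if np.isnan(data).any():
            raise InvalidValueError("invalid value: matrix contains NaN entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def dense(self) -> np.ndarray:
        if self.is_sparse:
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)


@dataclass
class PrepProvenance:
    """Record of the transformations applied by :func:`prep_matrix`."""

    transposed: bool = False
    log_base: Optional[float] = None
    pseudocount: float = 1.0
    centered: bool = False
    scaled: bool = False
    zero_variance_policy: str = "drop"
    dropped_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "transposed": self.transposed,
            "log_base": self.log_base,
            "pseudocount": self.pseudocount,
            "centered": self.centered,
            "scaled": self.scaled,
            "zero_variance_policy": self.zero_variance_policy,
            "dropped_features": list(self.dropped_features),
        }


@dataclass
class PreparedMatrix:
    """Dense samples x features matrix ready for decomposition."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    provenance: PrepProvenance
    col_means: Optional[np.ndarray] = None
    col_sds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise InvalidValueError(
                f"prepared matrix needs >= 2 samples and >= 1 feature, got {n} x {m}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _read_sidecar(path: Path) -> Optional[list[str]]:
    if not path.exists():
        return None
    return [line.rstrip("\n") for line in path.read_text().splitlines()]


def _read_mtx(path: Path) -> RawMatrix:
    try:
        values = scipy.io.mmread(str(path))
    except (ValueError, TypeError, OSError) as exc:
        raise MatrixParseError(f"parse error in {path}: {exc}") from exc
    if sp.issparse(values):
        values = values.tocsr()
    # Sidecar names: data.mtx -> data.rownames.txt / data.colnames.txt
    stem = str(path.with_suffix(""))
    row_names = _read_sidecar(Path(stem + ".rownames.txt"))
    col_names = _read_sidecar(Path(stem + ".colnames.txt"))
    return RawMatrix(values=values, row_names=row_names, col_names=col_names)


def _read_delimited(
    path: Path,
    delimiter: str,
    header: bool,
    row_names_col: Optional[int],
) -> RawMatrix:
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if header else None,
            index_col=row_names_col,
        )
        values = df.to_numpy(dtype=np.float64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise MatrixParseError(f"parse error in {path}: {exc}") from exc
    row_names = [str(i) for i in df.index] if row_names_col is not None else None
    col_names = [str(c) for c in df.columns] if header else None
    return RawMatrix(values=values, row_names=row_names, col_names=col_names)


def read_matrix(
    path: Union[str, Path],
    format: Optional[str] = None,
    *,
    delimiter: str = ",",
    header: bool = True,
    row_names_col: Optional[int] = None,
    orientation: str = "unknown",
) -> RawMatrix:
    """Read a matrix from disk.

    Parameters
    ----------
    path:
        Input file. Matrix Market files may carry ``<stem>.rownames.txt``
        and ``<stem>.colnames.txt`` sidecars, one name per line.
    format:
        ``"mtx"`` or ``"delimited"``; inferred from the suffix when omitted
        (``.mtx`` -> mtx, anything else -> delimited).
    delimiter, header, row_names_col:
        Delimited-text options. ``row_names_col`` is the 0-based column
        index holding row names, or None.
    orientation:
        Declared orientation of the file's rows/columns, recorded on the
        returned :class:`RawMatrix`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "delimited"
    if format == "mtx":
        raw = _read_mtx(path)
    elif format == "delimited":
        raw = _read_delimited(path, delimiter, header, row_names_col)
    else:
        raise ValueError(f"unknown format {format!r}")
    raw.orientation = orientation
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    return raw


def write_matrix(raw: RawMatrix, path: Union[str, Path], delimiter: str = "\t") -> None:
    """Write a RawMatrix to disk.

    ``.mtx`` paths get Matrix Market coordinate format with name sidecars
    (``<stem>.rownames.txt`` / ``<stem>.colnames.txt``) when names are
    present; any other suffix gets delimited text with a header row of
    column names and a leading row-name column when names are present.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(raw.values))
        stem = str(path.with_suffix(""))
        if raw.row_names is not None:
            Path(stem + ".rownames.txt").write_text("\n".join(raw.row_names) + "\n")
        if raw.col_names is not None:
            Path(stem + ".colnames.txt").write_text("\n".join(raw.col_names) + "\n")
        return
    dense = raw.dense()
    with open(path, "w") as fh:
        col_names = raw.col_names or [f"col_{j}" for j in range(dense.shape[1])]
        lead = ["id"] if raw.row_names is not None else []
        fh.write(delimiter.join(lead + list(col_names)) + "\n")
        for i, row in enumerate(dense):
            cells = [raw.row_names[i]] if raw.row_names is not None else []
            cells += [repr(float(v)) for v in row]
            fh.write(delimiter.join(cells) + "\n")


def _resolve_orientation(raw: RawMatrix, orientation: str) -> str:
    if orientation != "auto":
        return orientation
    if raw.orientation != "unknown":
        return raw.orientation
    n_rows, n_cols = raw.shape
    if n_rows == n_cols:
        raise OrientationError(
            "orientation ambiguous: square matrix with no declared orientation"
        )
    # Single-cell matrices have far more cells (samples) than genes
    # (features); take the longer axis as samples.
    return "samples_by_features" if n_rows > n_cols else "features_by_samples"


def prep_matrix(
    raw: RawMatrix,
    orientation: str = "auto",
    log_base: Optional[Union[int, float, str]] = None,
    pseudocount: float = 1.0,
    center: bool = False,
    scale: bool = False,
    zero_variance_policy: str = "drop",
) -> PreparedMatrix:
    """Prepare a raw matrix into dense samples x features form.

    Transformations are applied in the fixed order
    transpose -> log(x + pseudocount) -> center -> scale.

    Parameters
    ----------
    orientation:
        ``"samples_by_features"``, ``"features_by_samples"``, or ``"auto"``.
        Auto uses the raw matrix's declared orientation if any; otherwise
        the longer axis is taken as samples and a square undeclared matrix
        is an error.
    log_base:
        ``2``, ``"e"`` (or ``numpy.e``), or None for no log transform.
        Requires a non-negative matrix, and a positive pseudocount if any
        entry is zero.
    center, scale:
        Column mean-centering and unit-variance scaling (sample standard
        deviation, n-1 denominator).
    zero_variance_policy:
        What to do with zero-variance columns when scaling: ``"drop"``
        (default, removed and recorded in provenance), ``"keep_zero"``
        (centered column left at zero), or ``"error"``.
    """
    if zero_variance_policy not in ("drop", "keep_zero", "error"):
        raise ValueError(f"unknown zero_variance_policy {zero_variance_policy!r}")
    if pseudocount < 0:
        raise InvalidValueError("pseudocount must be >= 0")

    resolved = _resolve_orientation(raw, orientation)
    if resolved == "unknown":
        raise OrientationError("orientation ambiguous: declared as unknown")

    values = raw.dense()
    transposed = resolved == "features_by_samples"
    if transposed:
        values = values.T.copy()

    n_samples, n_features = values.shape
    row_names = raw.col_names if transposed else raw.row_names
    col_names = raw.row_names if transposed else raw.col_names
    sample_ids = list(row_names) if row_names else [f"sample_{i}" for i in range(n_samples)]
    feature_ids = list(col_names) if col_names else [f"feature_{i}" for i in range(n_features)]

    base: Optional[float] = None
    if log_base is not None:
        base = float(np.e) if log_base in ("e", np.e) else float(log_base)
        if (values < 0).any():
            raise InvalidValueError("negative values under log transform")
        if pseudocount == 0 and (values == 0).any():
            raise InvalidValueError(
                "invalid value: zero entries require a positive pseudocount under log"
            )
        values = np.log(values + pseudocount) / np.log(base)

    prov = PrepProvenance(
        transposed=transposed,
        log_base=base,
        pseudocount=pseudocount,
        centered=center,
        scaled=scale,
        zero_variance_policy=zero_variance_policy,
    )

    col_means = col_sds = None
    if center or scale:
        col_means = values.mean(axis=0)
        col_sds = values.std(axis=0, ddof=1)

    if scale:
        zero_var = col_sds <= 0.0
        if zero_var.any():
            names = [feature_ids[i] for i in np.flatnonzero(zero_var)]
            if zero_variance_policy == "error":
                raise InvalidValueError(f"zero variance feature(s): {names}")
            if zero_variance_policy == "drop":
                logger.warning("dropping %d zero-variance feature(s): %s", len(names), names)
                warnings.warn(f"dropping zero-variance features: {names}", stacklevel=2)
                keep = ~zero_var
                values = values[:, keep]
                col_means = col_means[keep]
                col_sds = col_sds[keep]
                feature_ids = [f for f, k in zip(feature_ids, keep) if k]
                prov.dropped_features = names
            else:  # keep_zero: centered column stays at zero, no division
                prov.dropped_features = []

    if center:
        values = values - col_means
    if scale:
        safe_sds = np.where(col_sds > 0.0, col_sds, 1.0)
        values = values / safe_sds
        if zero_variance_policy == "keep_zero":
            values[:, col_sds <= 0.0] = 0.0

    return PreparedMatrix(
        values=values,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        provenance=prov,
        col_means=col_means,
        col_sds=col_sds,
    )
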