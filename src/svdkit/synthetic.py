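"""Synthetic fixtures with known ground truth.

Two generators cover the testing needs of the whole toolkit without any
external download:

* :func:`make_lowrank` — a matrix built as U diag(spectrum) V^T plus
  optional i.i.d. Gaussian noise, with the orthonormal factors and the
  planted spectrum returned alongside. Recovery of the planted spectrum is
  the primary correctness check for the decomposition routines.
* :func:`make_counts` — a sparse non-negative integer matrix emulating a
  single-cell / spatial expression count matrix (genes as rows, cells as
  columns): negative-binomial (Gamma-Poisson) draws around a low-rank
  non-negative rate matrix, the de facto noise model for sequencing
  counts. It is a fixture for the prep -> SVD pipeline, not a scientific
  model of any particular platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import scipy.sparse as sp

from .errors import InvalidValueError
from .io_prep import RawMatrix
from .svd import apply_sign_convention

__all__ = ["SyntheticTruth", "make_lowrank", "make_counts"]


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated matrix together with its planted factors and spectrum."""

    matrix: np.ndarray
    true_spectrum: np.ndarray
    true_U: np.ndarray
    true_V: np.ndarray
    noise_sd: float
    seed: int

    @property
    def rank(self) -> int:
        return self.true_spectrum.size

    def save_truth(self, path: Union[str, Path]) -> None:
        """Write the planted spectrum and generator parameters as JSON."""
        payload = {
            "true_spectrum": [float(s) for s in self.true_spectrum],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "shape": list(self.matrix.shape),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _random_orthonormal(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return q


def make_lowrank(
    n: int,
    m: int,
    spectrum: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Planted low-rank matrix: U diag(spectrum) V^T + noise_sd * G.

    U and V are seeded random orthonormal factors (QR of Gaussian), with
    the same sign convention as the decomposition routines applied so the
    planted factors are directly comparable to estimates. G has i.i.d.
    standard-normal entries. Reproducible from ``seed``.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if spectrum.ndim != 1 or spectrum.size == 0:
        raise InvalidValueError("invalid spectrum: need a 1-D non-empty vector")
    if (spectrum <= 0).any() or (np.diff(spectrum) > 0).any():
        raise InvalidValueError("invalid spectrum: must be positive and non-increasing")
    r = spectrum.size
    if n < 2 or m < 2 or r > min(n, m):
        raise InvalidValueError(
            f"invalid generator parameter: n={n}, m={m}, rank={r}"
        )
    if noise_sd < 0:
        raise InvalidValueError("invalid generator parameter: noise_sd < 0")
    rng = np.random.default_rng(seed)
    U = _random_orthonormal(rng, n, r)
    V = _random_orthonormal(rng, m, r)
    U, VT = apply_sign_convention(U, V.T)
    V = VT.T
    matrix = (U * spectrum) @ V.T
    if noise_sd > 0:
        matrix = matrix + noise_sd * rng.standard_normal((n, m))
    return SyntheticTruth(
        matrix=matrix, true_spectrum=spectrum, true_U=U, true_V=V,
        noise_sd=float(noise_sd), seed=seed,
    )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def make_counts(
    n_cells: int,
    n_genes: int,
    n_programs: int = 10,
    mean_depth: float = 300.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> RawMatrix:
    """Sparse expression-like count matrix (genes x cells).

    A rank-``n_programs`` non-negative rate matrix is built as the
    softplus of low-rank Gaussian factors plus a per-gene baseline, scaled
    so the expected total count per cell equals ``mean_depth``; counts are
    negative-binomial draws around the rates (Gamma-Poisson with shape
    ``dispersion``: variance mu + mu^2/dispersion, approaching Poisson as
    dispersion grows). Program strengths decay as 1/sqrt(j) with a total
    log-rate standard deviation of about 2 (a few fold-changes between
    cell populations), which reproduces the spectral profile of real
    scaled expression matrices: leading components carrying several
    percent of total variance each, on top of a flat sampling-noise bulk.
    Returned with ``features_by_samples`` orientation and auto-generated
    gene/cell names, matching the on-disk layout of single-cell count
    matrices.
    """
    if n_cells < 2 or n_genes < 2 or n_programs < 1:
        raise InvalidValueError("invalid generator parameter: dimensions too small")
    if n_programs > min(n_cells, n_genes):
        raise InvalidValueError(
            "invalid generator parameter: n_programs exceeds min(n_cells, n_genes)"
        )
    if mean_depth <= 0 or dispersion <= 0:
        raise InvalidValueError(
            "invalid generator parameter: mean_depth and dispersion must be positive"
        )
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n_genes, n_programs))
    H = rng.standard_normal((n_programs, n_cells))
    # decaying program strengths, total log-rate sd ~ 2 (realistic
    # between-population fold changes)
    weights = np.arange(1, n_programs + 1, dtype=np.float64) ** -0.5
    weights *= 2.0 / np.sqrt(np.sum(weights**2))
    baseline = rng.normal(0.0, 1.0, size=(n_genes, 1))
    rate = _softplus(baseline + (W * weights) @ H)
    rate *= mean_depth / rate.sum(axis=0).mean()
    lam = rng.gamma(shape=dispersion, scale=rate / dispersion)
    counts = rng.poisson(lam).astype(np.float64)
    gwidth = max(4, len(str(n_genes)))
    cwidth = max(4, len(str(n_cells)))
    return RawMatrix(
        values=sp.csr_matrix(counts),
        row_names=[f"gene_{i + 1:0{gwidth}d}" for i in range(n_genes)],
        col_names=[f"cell_{i + 1:0{cwidth}d}" for i in range(n_cells)],
        orientation="features_by_samples",
    )
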