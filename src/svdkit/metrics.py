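"""Validation metrics for truncated decompositions.

A truncated decomposition is judged against the exact truncated SVD of the
same matrix, which by the Eckart-Young theorem is the optimal rank-k
approximation in Frobenius norm:

* ``sse_ratio`` — candidate reconstruction SSE divided by the exact
  truncated reconstruction SSE at the same rank; 1 means the candidate
  captures exactly as much variance as the optimal rank-k truncation, and
  values above 1 quantify the excess error.
* ``frobenius_error`` — absolute (Frobenius-norm) and relative
  reconstruction error against the original matrix.
* ``ccc`` — Lin's concordance correlation coefficient,
  rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population
  (1/n) moment estimators, used to measure agreement of singular values
  and of PC score vectors between a candidate and the exact reference.
* ``align_signs`` — resolves the inherent sign ambiguity of singular
  vectors before any vector-wise comparison.

``compare_decompositions`` bundles all of these into one report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import MetricError, RankError
from .svd import SVDResult

__all__ = [
    "MetricsReport",
    "reconstruct",
    "sse_ratio",
    "frobenius_error",
    "ccc",
    "align_signs",
    "compare_decompositions",
]


def reconstruct(svd: SVDResult, k: Optional[int] = None) -> np.ndarray:
    """Rank-``k`` reconstruction ``U[:, :k] @ diag(S[:k]) @ Vt[:k]``."""
    if k is None:
        k = svd.k
    if k < 1:
        raise RankError(f"invalid rank: k={k}")
    if k > svd.k:
        raise RankError(f"insufficient components: requested {k}, have {svd.k}")
    return (svd.U[:, :k] * svd.S[:k]) @ svd.Vt[:k]


def sse_ratio(
    candidate: SVDResult,
    reference_exact: SVDResult,
    M: np.ndarray,
    k: int,
) -> float:
    """Candidate SSE over exact-truncated SSE at rank ``k``.

    By Eckart-Young the exact truncated SVD minimizes the rank-k
    reconstruction SSE, so the ratio is >= 1 (up to roundoff); 1 means the
    candidate captures the same variance as the optimal truncation.
    """
    M = np.asarray(M, dtype=np.float64)
    if candidate.k < k or reference_exact.k < k:
        raise RankError(f"insufficient components: need {k}")
    if reference_exact.method != "exact":
        raise MetricError("reference decomposition must use the exact method")
    for r in (candidate, reference_exact):
        if (r.n_samples, r.n_features) != M.shape:
            raise MetricError(
                f"shape mismatch: decomposition {r.n_samples}x{r.n_features} "
                f"vs matrix {M.shape[0]}x{M.shape[1]}"
            )
    num = float(np.linalg.norm(M - reconstruct(candidate, k), "fro") ** 2)
    den = float(np.linalg.norm(M - reconstruct(reference_exact, k), "fro") ** 2)
    # effectively-zero reference SSE: below roundoff relative to ||M||_F^2
    if den < max(1e-300, (1e-13 * np.linalg.norm(M, "fro")) ** 2):
        raise MetricError("reference SSE is zero: matrix has rank <= k")
    return num / den


def frobenius_error(
    M: np.ndarray,
    svd: SVDResult,
    k: Optional[int] = None,
    divisor: str = "frobenius",
) -> tuple[float, float]:
    """Absolute and relative Frobenius reconstruction error.

    ``divisor`` selects the normalizer of the relative error:
    ``"frobenius"`` (default) divides by ||M||_F; ``"centered_ss"``
    divides by the square root of the total column-centered sum of squares
    (the square root of the variance mass in the data).
    """
    M = np.asarray(M, dtype=np.float64)
    if M.shape != (svd.n_samples, svd.n_features):
        raise MetricError(
            f"shape mismatch: matrix {M.shape} vs decomposition "
            f"{(svd.n_samples, svd.n_features)}"
        )
    absolute = float(np.linalg.norm(M - reconstruct(svd, k), "fro"))
    if divisor == "frobenius":
        denom = float(np.linalg.norm(M, "fro"))
    elif divisor == "centered_ss":
        denom = float(np.sqrt(np.sum((M - M.mean(axis=0)) ** 2)))
    else:
        raise ValueError(f"unknown divisor {divisor!r}")
    if denom == 0.0:
        if absolute == 0.0:
            return 0.0, 0.0
        warnings.warn("zero-norm matrix with nonzero error; relative error is inf",
                      stacklevel=2)
        return absolute, float("inf")
    return absolute, absolute / denom


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    Uses population (1/n) moment estimators:
    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2).
    Equals 1 iff y == x elementwise; penalizes both decorrelation and
    location/scale shift.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise MetricError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise MetricError("CCC needs at least 2 observations")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise MetricError("CCC undefined: both vectors constant and equal")
    return 2.0 * sxy / denom


def align_signs(candidate: SVDResult, reference: SVDResult) -> SVDResult:
    """Resolve sign ambiguity of the candidate against a reference.

    For each component, the candidate's U column (and matching Vt row) is
    negated iff its dot product with the reference U column is negative.
    Idempotent; S is unchanged.
    """
    if candidate.U.shape != reference.U.shape or candidate.Vt.shape != reference.Vt.shape:
        raise MetricError(
            f"shape mismatch: candidate U {candidate.U.shape} / Vt {candidate.Vt.shape} "
            f"vs reference U {reference.U.shape} / Vt {reference.Vt.shape}"
        )
    dots = np.einsum("ij,ij->j", candidate.U, reference.U)
    signs = np.where(dots < 0, -1.0, 1.0)
    return replace(candidate, U=candidate.U * signs, Vt=candidate.Vt * signs[:, None])


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of agreement statistics between a candidate decomposition and
    the exact reference on the same matrix."""

    sse_ratio: float
    ccc_singular_values: float
    ccc_pc: dict[int, float]
    absolute_error: float
    relative_error: float
    k: int
    relative_error_divisor: str = "frobenius"

    def to_dict(self) -> dict:
        return {
            "sse_ratio": self.sse_ratio,
            "ccc_singular_values": self.ccc_singular_values,
            "ccc_pc": {str(i): v for i, v in self.ccc_pc.items()},
            "absolute_error": self.absolute_error,
            "relative_error": self.relative_error,
            "relative_error_divisor": self.relative_error_divisor,
            "k": self.k,
        }

    def save(self, outdir: Union[str, Path]) -> None:
        """Write metrics.json (full precision) and metrics.tsv (table
        precision: 6 decimals for the SSE ratio, 4 for CCC, round half to
        even)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "metrics.json").write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        rows = [("sse_ratio", f"{np.round(self.sse_ratio, 6):.6f}"),
                ("ccc_singular_values", f"{np.round(self.ccc_singular_values, 4):.4f}")]
        rows += [(f"ccc_pc{i}", f"{np.round(v, 4):.4f}") for i, v in sorted(self.ccc_pc.items())]
        rows += [("absolute_error", repr(self.absolute_error)),
                 ("relative_error", repr(self.relative_error)),
                 ("k", str(self.k))]
        (outdir / "metrics.tsv").write_text(
            "metric\tvalue\n" + "".join(f"{a}\t{b}\n" for a, b in rows)
        )


def compare_decompositions(
    candidate: SVDResult,
    reference_exact: SVDResult,
    M: np.ndarray,
    k: int,
    n_pcs_to_compare: int = 2,
    relative_error_divisor: str = "frobenius",
) -> MetricsReport:
    """Full agreement report of a candidate against the exact reference.

    Computes the SSE ratio at rank ``k``, CCC over the first ``k``
    singular values, per-component CCC of the first ``n_pcs_to_compare``
    PC score vectors (U column times singular value, after sign
    alignment), and the candidate's Frobenius reconstruction errors.
    """
    M = np.asarray(M, dtype=np.float64)
    if n_pcs_to_compare > k:
        raise RankError(
            f"insufficient components: n_pcs_to_compare={n_pcs_to_compare} > k={k}"
        )
    ratio = sse_ratio(candidate, reference_exact, M, k)
    ccc_sv = ccc(candidate.S[:k], reference_exact.S[:k])
    from .svd import truncate_svd  # local import to avoid cycle at module load

    cand_k = truncate_svd(candidate, k)
    ref_k = truncate_svd(reference_exact, k)
    aligned = align_signs(cand_k, ref_k)
    ccc_pc = {}
    for i in range(n_pcs_to_compare):
        ccc_pc[i + 1] = ccc(aligned.U[:, i] * aligned.S[i], ref_k.U[:, i] * ref_k.S[i])
    absolute, relative = frobenius_error(M, candidate, k, divisor=relative_error_divisor)
    return MetricsReport(
        sse_ratio=ratio,
        ccc_singular_values=ccc_sv,
        ccc_pc=ccc_pc,
        absolute_error=absolute,
        relative_error=relative,
        k=k,
        relative_error_divisor=relative_error_divisor,
    )
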