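"""Principal-component scores from a truncated SVD.

For a column-centered matrix M with SVD U diag(S) V^T, the PC scores are
U diag(S) (identically M V for an exact decomposition): each sample's
coordinates on the principal axes. Variance-explained fractions are
S_i^2 / sum_j S_j^2 over the components actually computed — a truncated
decomposition cannot see the discarded tail of the spectrum, so these are
shares of the captured variance, not of the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import RankError
from .svd import SVDResult

__all__ = ["ScoreMatrix", "pc_scores"]


@dataclass(frozen=True)
class ScoreMatrix:
    """Samples x components PC scores with component labels and
    captured-variance fractions."""

    scores: np.ndarray
    sample_ids: list[str]
    component_labels: list[str]
    variance_explained: np.ndarray

    def save(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "scores.tsv", "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.component_labels) + "\n")
            for sid, row in zip(self.sample_ids, self.scores):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        with open(outdir / "variance_explained.tsv", "w") as fh:
            fh.write("component\tvariance_explained\n")
            for lab, v in zip(self.component_labels, self.variance_explained):
                fh.write(f"{lab}\t{float(v)!r}\n")


def pc_scores(
    svd: SVDResult,
    k: Optional[int] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> ScoreMatrix:
    """Compute PC scores ``U[:, :k] @ diag(S[:k])`` from a decomposition.

    ``variance_explained`` uses all ``svd.k`` available singular values as
    the denominator regardless of the ``k`` requested here, so truncating
    the score matrix does not inflate the leading components' shares.
    """
    if k is None:
        k = svd.k
    if not 1 <= k <= svd.k:
        raise RankError(f"insufficient components: requested {k}, have {svd.k}")
    scores = svd.U[:, :k] * svd.S[:k]
    total = float(np.sum(svd.S**2))
    if total == 0.0:
        warnings.warn("all singular values are zero; variance_explained undefined, "
                      "reporting zeros", stacklevel=2)
        var_exp = np.zeros(k)
    else:
        var_exp = svd.S[:k] ** 2 / total
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(svd.n_samples)]
    return ScoreMatrix(
        scores=scores,
        sample_ids=list(sample_ids),
        component_labels=[f"PC{i + 1}" for i in range(k)],
        variance_explained=var_exp,
    )
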