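"""End-to-end pipeline: read -> prep -> decompose -> scores.

:class:`RunConfig` collects every knob of the chain; validation aggregates
all problems into a single error before any computation starts, and the
effective (fully materialized) configuration is written to the output
directory as ``meta.json`` alongside the decomposition, so a run can be
reproduced exactly from its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

from .backend import BackendSpec, resolve_backend
from .errors import ConfigError
from .io_prep import prep_matrix, read_matrix
from .scores import pc_scores
from .svd import exact_svd, randomized_svd

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one prep -> SVD -> scores run."""

    input_path: str
    output_dir: str
    input_format: Optional[str] = None  # mtx | delimited | None (infer)
    delimiter: str = ","
    header: bool = True
    row_names_col: Optional[int] = None
    orientation: str = "auto"
    log_base: Optional[Union[int, float, str]] = None
    pseudocount: float = 1.0
    center: bool = True
    scale: bool = True
    zero_variance_policy: str = "drop"
    method: str = "randomized"
    k: int = 50
    oversample: int = 10
    power_iters: int = 2
    seed: int = 0
    backend: str = "reference"
    threads: Union[int, str] = "auto"
    device: str = "cpu"

    def validate(self) -> None:
        """Raise ConfigError listing every problem at once."""
        problems: list[str] = []
        if not Path(self.input_path).exists():
            problems.append(f"input not found: {self.input_path}")
        if self.input_format not in (None, "mtx", "delimited"):
            problems.append(f"unknown input format {self.input_format!r}")
        if self.orientation not in ("auto", "samples_by_features", "features_by_samples"):
            problems.append(f"unknown orientation {self.orientation!r}")
        if self.method not in ("exact", "randomized"):
            problems.append(f"method must be exact or randomized, got {self.method!r}")
        if self.k < 1:
            problems.append(f"k must be >= 1, got {self.k}")
        if self.oversample < 0:
            problems.append(f"oversample must be >= 0, got {self.oversample}")
        if self.power_iters < 0:
            problems.append(f"power_iters must be >= 0, got {self.power_iters}")
        if self.pseudocount < 0:
            problems.append(f"pseudocount must be >= 0, got {self.pseudocount}")
        if self.zero_variance_policy not in ("drop", "keep_zero", "error"):
            problems.append(f"unknown zero_variance_policy {self.zero_variance_policy!r}")
        if self.device not in ("cpu", "gpu"):
            problems.append(f"device must be cpu or gpu, got {self.device!r}")
        if self.threads != "auto" and (not isinstance(self.threads, int) or self.threads < 1):
            problems.append(f"threads must be a positive integer or 'auto', got {self.threads!r}")
        if problems:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))


def run_pipeline(config: RunConfig) -> Path:
    """Run the full chain and write all artifacts to ``config.output_dir``.

    Outputs: ``prep.json`` (transformation provenance), ``U.tsv`` /
    ``S.tsv`` / ``Vt.tsv`` / ``meta.json`` (decomposition), ``scores.tsv``
    and ``variance_explained.tsv``. On any failure after outputs start
    being written, an empty ``RUN.incomplete`` marker is left in the
    directory.

    Returns the output directory path.
    """
    config.validate()
    outdir = Path(config.output_dir)

    logger.info("reading %s", config.input_path)
    raw = read_matrix(
        config.input_path,
        config.input_format,
        delimiter=config.delimiter,
        header=config.header,
        row_names_col=config.row_names_col,
    )
    logger.info("loaded %d x %d matrix (sparse=%s)", *raw.shape, raw.is_sparse)

    prepared = prep_matrix(
        raw,
        orientation=config.orientation,
        log_base=config.log_base,
        pseudocount=config.pseudocount,
        center=config.center,
        scale=config.scale,
        zero_variance_policy=config.zero_variance_policy,
    )
    logger.info("prepared %d samples x %d features", *prepared.shape)

    handle = resolve_backend(
        BackendSpec(name=config.backend, threads=config.threads, device=config.device)
    )
    if config.method == "exact":
        k = min(config.k, min(prepared.shape))
        result = exact_svd(prepared, k=k, backend=handle)
    else:
        result = randomized_svd(
            prepared,
            k=config.k,
            oversample=config.oversample,
            power_iters=config.power_iters,
            seed=config.seed,
            backend=handle,
        )
    logger.info("%s SVD done: k=%d, leading singular value %.6g",
                result.method, result.k, result.S[0])

    score_mat = pc_scores(result, sample_ids=prepared.sample_ids)

    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "RUN.incomplete"
    marker.touch()
    try:
        (outdir / "prep.json").write_text(
            json.dumps(prepared.provenance.to_dict(), indent=2) + "\n"
        )
        result.save(outdir)
        # meta.json gains the full effective config for reproducibility
        meta_path = outdir / "meta.json"
        meta = json.loads(meta_path.read_text())
        meta["config"] = asdict(config)
        meta_path.write_text(json.dumps(meta, indent=2) + "\n")
        score_mat.save(outdir)
    except Exception:
        raise
    else:
        marker.unlink()
    logger.info("outputs written to %s", outdir)
    return outdir
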