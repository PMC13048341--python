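"""Pluggable numeric backends for the SVD core.

The decomposition routines never call numpy directly for their heavy
operations; they go through a :class:`BackendHandle`, which supplies dense
matrix multiplication, thin QR with orthonormal Q, full SVD of (small)
dense matrices, and a seeded Gaussian sampler. This keeps the algorithms
backend-agnostic: a tensor-library backend (e.g. torch, on CPU threads or a
CUDA device) can be registered at runtime and must satisfy the same
contract, including the sampler, so randomized results are reproducible per
(backend, seed) pair.

The ``reference`` backend is pure numpy/LAPACK, always available, and is
the default everywhere.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .errors import BackendNotFoundError, DeviceUnavailableError

__all__ = [
    "BackendSpec",
    "BackendHandle",
    "ReferenceBackend",
    "register_backend",
    "available_backends",
    "resolve_backend",
]


@dataclass(frozen=True)
class BackendSpec:
    """Request for a numeric backend.

    Parameters
    ----------
    name:
        Registered backend identifier (``"reference"`` is always present).
    threads:
        Positive integer thread-count hint, or ``"auto"``. Backends that
        cannot control threading may ignore the hint but must report the
        effective count they used.
    device:
        ``"cpu"`` or ``"gpu"``. A GPU request on a backend that reports no
        GPU support fails at resolution time; there is no silent fallback.
    """

    name: str = "reference"
    threads: Union[int, str] = "auto"
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.threads != "auto":
            if not isinstance(self.threads, (int, np.integer)) or self.threads < 1:
                raise ValueError(
                    f"threads must be a positive integer or 'auto', got {self.threads!r}"
                )
        if self.device not in ("cpu", "gpu"):
            raise ValueError(f"device must be 'cpu' or 'gpu', got {self.device!r}")


class BackendHandle(abc.ABC):
    """Resolved backend exposing the numeric primitives the SVD core needs.

    All array arguments and return values are numpy ``float64`` arrays;
    accelerated backends convert internally and must round-trip through
    float64 so every backend agrees on the Gaussian sampler contract and on
    results to high relative accuracy.
    """

    #: registered identifier of the backend
    name: str = ""

    def __init__(self, spec: BackendSpec) -> None:
        self.spec = spec

    # -- capability report -------------------------------------------------
    @classmethod
    def gpu_available(cls) -> bool:
        return False

    @property
    @abc.abstractmethod
    def effective_threads(self) -> int:
        """Thread count actually in use (>= 1)."""

    @property
    def device(self) -> str:
        return self.spec.device

    # -- primitives --------------------------------------------------------
    @abc.abstractmethod
    def matmul(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Dense matrix product ``a @ b``."""

    @abc.abstractmethod
    def qr(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Thin QR factorization; Q has orthonormal columns."""

    @abc.abstractmethod
    def svd(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Full SVD with thin matrices: returns (U, S, Vt), S descending."""

    def gaussian(self, shape: tuple[int, int], seed: int) -> np.ndarray:
        """Seeded i.i.d. standard-normal matrix.

        Part of the backend contract: every backend must draw from numpy's
        ``default_rng(seed).standard_normal`` stream (converting to its own
        array type afterwards) so that randomized decompositions are
        bit-reproducible across backends for a fixed seed.
        """
        return np.random.default_rng(seed).standard_normal(shape)


class ReferenceBackend(BackendHandle):
    """Pure numpy backend, always available.

    Threading is delegated to whatever BLAS numpy is linked against; the
    hint in the spec is ignored and the effective count is reported as 1
    (the only count this backend can guarantee).
    """

    name = "reference"

    @property
    def effective_threads(self) -> int:
        return 1

    def matmul(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.asarray(a, dtype=np.float64) @ np.asarray(b, dtype=np.float64)

    def qr(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q, r = np.linalg.qr(np.asarray(a, dtype=np.float64), mode="reduced")
        return q, r

    def svd(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        u, s, vt = np.linalg.svd(np.asarray(a, dtype=np.float64), full_matrices=False)
        return u, s, vt


_REGISTRY: dict[str, Callable[[BackendSpec], BackendHandle]] = {}


def register_backend(name: str, factory: Callable[[BackendSpec], BackendHandle]) -> None:
    """Register a backend factory under ``name`` (overwrites any previous)."""
    _REGISTRY[name] = factory


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


register_backend("reference", ReferenceBackend)


def _discover_torch() -> None:
    """Register a torch backend if the optional dependency is importable."""
    if "torch" in _REGISTRY:
        return
    try:
        import torch  # noqa: F401
    except ImportError:
        return

    import torch

    class TorchBackend(BackendHandle):
        name = "torch"

        def __init__(self, spec: BackendSpec) -> None:
            super().__init__(spec)
            if spec.threads != "auto":
                torch.set_num_threads(int(spec.threads))
            self._dev = torch.device("cuda" if spec.device == "gpu" else "cpu")

        @classmethod
        def gpu_available(cls) -> bool:
            return bool(torch.cuda.is_available())

        @property
        def effective_threads(self) -> int:
            return int(torch.get_num_threads())

        def _t(self, a: np.ndarray) -> "torch.Tensor":
            return torch.as_tensor(np.asarray(a, dtype=np.float64), device=self._dev)

        def matmul(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
            return (self._t(a) @ self._t(b)).cpu().numpy()

        def qr(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            q, r = torch.linalg.qr(self._t(a), mode="reduced")
            return q.cpu().numpy(), r.cpu().numpy()

        def svd(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            u, s, vt = torch.linalg.svd(self._t(a), full_matrices=False)
            return u.cpu().numpy(), s.cpu().numpy(), vt.cpu().numpy()

    register_backend("torch", TorchBackend)


def resolve_backend(spec: Union[BackendSpec, str, None] = None) -> BackendHandle:
    """Resolve a :class:`BackendSpec` to a concrete handle.

    Raises
    ------
    BackendNotFoundError
        If ``spec.name`` is not registered (message: "backend not found").
    DeviceUnavailableError
        If ``device='gpu'`` but the backend reports no GPU (message:
        "device unavailable"). There is no silent CPU fallback.
    """
    if spec is None:
        spec = BackendSpec()
    elif isinstance(spec, str):
        spec = BackendSpec(name=spec)

    if spec.name not in _REGISTRY:
        _discover_torch()  # optional plugins are looked up lazily
    if spec.name not in _REGISTRY:
        raise BackendNotFoundError(
            f"backend not found: {spec.name!r} (available: {available_backends()})"
        )
    factory = _REGISTRY[spec.name]
    gpu_ok = getattr(factory, "gpu_available", lambda: False)()
    if spec.device == "gpu" and not gpu_ok:
        raise DeviceUnavailableError(
            f"device unavailable: backend {spec.name!r} reports no GPU support"
        )
    return factory(spec)
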