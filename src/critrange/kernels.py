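"""Finite-range symmetric step kernels D on Z^d.

A step kernel assigns probabilities to nonzero integer offsets in the
sup-norm box of radius L.  All models in this package (voter model, contact
process, oriented percolation, branching random walk) move or infect through
such a kernel.  The kernel must be symmetric (D(-x) = D(x)) with isotropic
coordinate covariance sigma2_D * I; sigma2_D is the per-coordinate variance
that enters every diffusive limit prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "StepKernel",
    "uniform_box_kernel",
    "kernel_variance",
    "characteristic_function",
    "sample_step",
    "kernel_to_json",
    "kernel_from_json",
]

_ISO_TOL = 1e-12


class KernelError(ValueError):
    """Raised when a proposed kernel violates the step-kernel invariants."""


@dataclass(frozen=True)
class StepKernel:
    """Symmetric finite-range step distribution on Z^d.

    Attributes
    ----------
    d : spatial dimension.
    L : sup-norm range; every support offset x has ||x||_inf <= L.
    offsets : (S, d) int array of support offsets.
    probs : (S,) float array of probabilities, summing to one.
    """

    d: int
    L: int
    offsets: np.ndarray
    probs: np.ndarray
    _cum: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.d < 1 or self.L < 1:
            raise KernelError("d and L must be positive integers")
        offsets = np.asarray(self.offsets, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        if offsets.ndim != 2 or offsets.shape[1] != self.d:
            raise KernelError("offsets must be an (S, d) integer array")
        if probs.shape != (offsets.shape[0],):
            raise KernelError("probs must align with offsets")
        if np.any(probs < 0):
            raise KernelError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > _ISO_TOL:
            raise KernelError("probabilities must sum to 1 within 1e-12")
        if np.any(np.all(offsets == 0, axis=1)):
            raise KernelError("D(o) must be 0: the origin may not be in the support")
        if np.max(np.abs(offsets)) > self.L:
            raise KernelError("support offset exceeds the sup-norm range L")
        # symmetry: D(-x) = D(x)
        table = {tuple(o): p for o, p in zip(map(tuple, offsets.tolist()), probs)}
        if len(table) != len(probs):
            raise KernelError("duplicate offsets in support")
        for o, p in table.items():
            q = table.get(tuple(-c for c in o))
            if q is None or abs(q - p) > _ISO_TOL:
                raise KernelError(f"kernel not symmetric at offset {o}")
        # isotropic diagonal covariance
        cov = (offsets[:, :, None] * offsets[:, None, :] * probs[:, None, None]).sum(axis=0)
        diag = np.diag(cov)
        if np.any(np.abs(cov - np.diag(diag)) > _ISO_TOL):
            raise KernelError("coordinate covariance has off-diagonal terms")
        if np.max(np.abs(diag - diag[0])) > _ISO_TOL:
            raise KernelError("coordinate covariance is anisotropic")
        if diag[0] <= 0:
            raise KernelError("per-coordinate variance must be positive")
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "_cum", np.cumsum(probs))

    @property
    def size(self) -> int:
        return self.offsets.shape[0]

    @property
    def sigma2_D(self) -> float:
        """Common per-coordinate variance sigma2_D = sum_x x_1^2 D(x)."""
        return float((self.offsets[:, 0].astype(float) ** 2 * self.probs).sum())

    @property
    def sigma2(self) -> float:
        """Total variance sigma2 = d * sigma2_D."""
        return self.d * self.sigma2_D

    def max_prob(self) -> float:
        return float(self.probs.max())


def uniform_box_kernel(d: int, L: int) -> StepKernel:
    """Kernel uniform on ([-L, L]^d \\ {o}) cap Z^d (the spread-out model)."""
    if d < 1 or L < 1:
        raise KernelError("d and L must be positive integers")
    offsets = np.array(
        [x for x in product(range(-L, L + 1), repeat=d) if any(c != 0 for c in x)],
        dtype=np.int64,
    )
    n = (2 * L + 1) ** d - 1
    probs = np.full(n, 1.0 / n)
    return StepKernel(d=d, L=L, offsets=offsets, probs=probs)


def kernel_variance(kernel: StepKernel) -> float:
    """Per-coordinate variance sigma2_D of a valid kernel."""
    return kernel.sigma2_D


def characteristic_function(kernel: StepKernel, k) -> float | np.ndarray:
    """D-hat(k) = sum_x cos(k . x) D(x), real by symmetry, in [-1, 1].

    ``k`` may be a length-d vector or an (M, d) array of wave vectors.
    """
    k = np.asarray(k, dtype=np.float64)
    single = k.ndim == 1
    if single:
        if k.shape != (kernel.d,):
            raise ValueError(f"k must have length d={kernel.d}")
        k = k[None, :]
    elif k.ndim != 2 or k.shape[1] != kernel.d:
        raise ValueError(f"k must be (M, {kernel.d})")
    vals = np.cos(k @ kernel.offsets.T.astype(np.float64)) @ kernel.probs
    return float(vals[0]) if single else vals


def sample_step(kernel: StepKernel, rng: np.random.Generator, size: int | None = None):
    """Draw offsets from D.  Returns (d,) for size=None, else (size, d)."""
    if size is None:
        idx = int(np.searchsorted(kernel._cum, rng.random(), side="right"))
        idx = min(idx, kernel.size - 1)
        return kernel.offsets[idx].copy()
    idx = np.searchsorted(kernel._cum, rng.random(size), side="right")
    np.clip(idx, 0, kernel.size - 1, out=idx)
    return kernel.offsets[idx]


def kernel_to_json(kernel: StepKernel) -> str:
    entries = [[*map(int, o), float(p)] for o, p in zip(kernel.offsets, kernel.probs)]
    return json.dumps({"d": kernel.d, "L": kernel.L, "entries": entries})


def kernel_from_json(text: str) -> StepKernel:
    obj = json.loads(text)
    entries = obj["entries"]
    offsets = np.array([e[:-1] for e in entries], dtype=np.int64)
    probs = np.array([e[-1] for e in entries], dtype=np.float64)
    return StepKernel(d=int(obj["d"]), L=int(obj["L"]), offsets=offsets, probs=probs)
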