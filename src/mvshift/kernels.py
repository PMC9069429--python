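"""Spherically symmetric kernels for matrix arguments.

A kernel on P×T matrices is taken spherically symmetric,
K(X) = ½·κ(tr(XᵀX)), so it depends on X only through the squared
Frobenius norm.  Two kinds are shipped:

* ``normal`` — the matrix standard normal density,
  K(X) = (2π)^{-d/2} exp(-tr(XᵀX)/2) with d = P·T; differentiable,
  used by all κ′-weighted mean-shift steps.
* ``uniform_ball`` — the uniform density on the unit d-ball,
  K(X) = ν₀^{-1}·1{tr(XᵀX) ≤ 1}; its mean-shift update is the
  in-ball average (it has no usable profile derivative).

Under the K = ½κ convention the normal profile is
κ(u) = 2(2π)^{-d/2} e^{-u/2} and κ′(u) = -(2π)^{-d/2} e^{-u/2} ≤ 0.
Multiplicative constants in κ′ cancel in all mean-shift weights, so the
convention only pins density values, which match the matrix-normal
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["KernelSpec", "normal_kernel", "uniform_ball_kernel", "unit_ball_volume"]


def unit_ball_volume(d: int) -> float:
    """Hypervolume ν₀ = π^{d/2} / Γ(d/2 + 1) of the unit d-ball."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    return float(np.exp(0.5 * d * np.log(np.pi) - gammaln(0.5 * d + 1)))


@dataclass(frozen=True)
class KernelSpec:
    """A spherically symmetric kernel profile in dimension d = P·T."""

    kind: str  # "normal" | "uniform_ball"
    dim: int

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "uniform_ball"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")

    # --- normalizing constants and moments -------------------------------
    @property
    def rk(self) -> float:
        """Roughness R(K) = ∫K²."""
        if self.kind == "normal":
            return float((4 * np.pi) ** (-self.dim / 2))
        return 1.0 / unit_ball_volume(self.dim)

    @property
    def m2(self) -> float:
        """Second moment m₂(K) = ∫ x_{p,t}² K."""
        if self.kind == "normal":
            return 1.0
        return 1.0 / (self.dim + 2)

    @property
    def ball_volume(self) -> float:
        if self.kind != "uniform_ball":
            raise ValueError("ball_volume defined for uniform_ball kernels only")
        return unit_ball_volume(self.dim)

    # --- evaluation -------------------------------------------------------
    def eval_sq(self, sq_norm: np.ndarray | float) -> np.ndarray | float:
        """K as a function of the squared Frobenius norm tr(XᵀX)."""
        u = np.asarray(sq_norm, dtype=float)
        if self.kind == "normal":
            out = (2 * np.pi) ** (-self.dim / 2) * np.exp(-0.5 * u)
        else:
            out = np.where(u <= 1.0, 1.0 / unit_ball_volume(self.dim), 0.0)
        return out if out.ndim else float(out)

    def __call__(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.size != self.dim:
            raise ValueError(f"argument has {x.size} entries, kernel dim is {self.dim}")
        return float(self.eval_sq(float((x * x).sum())))

    def profile(self, u: np.ndarray | float) -> np.ndarray | float:
        """κ(u), where K(X) = ½κ(tr(XᵀX))."""
        return 2.0 * self.eval_sq(u)

    def profile_deriv(self, u: np.ndarray | float) -> np.ndarray | float:
        """κ′(u) ≤ 0 (normal kernel only)."""
        if self.kind != "normal":
            raise ValueError("profile derivative undefined; use knn_uniform step")
        u = np.asarray(u, dtype=float)
        out = -((2 * np.pi) ** (-self.dim / 2)) * np.exp(-0.5 * u)
        return out if out.ndim else float(out)


def normal_kernel(dim: int) -> KernelSpec:
    return KernelSpec("normal", dim)


def uniform_ball_kernel(dim: int) -> KernelSpec:
    return KernelSpec("uniform_ball", dim)


def kernel_by_name(name: str, dim: int) -> KernelSpec:
    """Resolve the CLI/config kernel name ('normal' or 'uniform')."""
    if name in ("normal", "gaussian"):
        return normal_kernel(dim)
    if name in ("uniform", "uniform_ball"):
        return uniform_ball_kernel(dim)
    raise ValueError(f"unknown kernel {name!r}; choose 'normal' or 'uniform'")
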