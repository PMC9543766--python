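"""Kernel functions, admissible compositions, and Gram-matrix utilities.

The regression model in this package is built on Mercer (admissible) kernels:
symmetric positive-semidefinite similarity functions that implicitly define an
inner product in a feature space.  Two base kernels are provided — a Gaussian
radial basis function (local) and an inhomogeneous polynomial (global) — plus
the two mixtures that are the point of the method: a convex sum

    K_sum(x, z)  = beta * K_RB(x, z) + (1 - beta) * K_P(x, z),   beta in (0, 1)

and a product

    K_prod(x, z) = K_RB(x, z) * K_P(x, z).

Both are admissible because the Mercer class is closed under nonnegative
linear combination and under pointwise product (Schur product theorem).

The RBF kernel is evaluated as exp(-gamma * ||x - z||^2) with gamma > 0.  A
positive-exponent variant (``literal_rbf``) is exposed only so tests can
demonstrate that it is *not* positive semidefinite; it is never admissible and
the solver refuses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "GramMatrix",
    "KernelParameterError",
    "DimensionMismatchError",
    "eval_rbf",
    "eval_poly",
    "eval_sum_mixture",
    "eval_product_mixture",
    "eval_kernel",
    "gram_matrix",
    "check_admissible",
    "induced_feature_distance",
]

_KINDS = frozenset(
    {"rbf", "poly", "linear_raw", "sum_mixture", "product_mixture", "scaled",
     "literal_rbf"}
)

#: kernel kinds that pass the Mercer admissibility contract
ADMISSIBLE_KINDS = frozenset(
    {"rbf", "poly", "linear_raw", "sum_mixture", "product_mixture", "scaled"}
)


class KernelParameterError(ValueError):
    """A kernel hyperparameter is outside its admissible range."""


class DimensionMismatchError(ValueError):
    """Point sets passed to a kernel do not share a feature dimension."""


@dataclass(frozen=True)
class KernelSpec:
    """Declarative description of a kernel.

    Parameters
    ----------
    kind
        One of ``rbf``, ``poly``, ``linear_raw``, ``sum_mixture``,
        ``product_mixture``, ``scaled``, or ``literal_rbf`` (test-only,
        inadmissible).
    gamma
        RBF width, > 0.  Required by ``rbf``, ``literal_rbf`` and both
        mixtures.
    sigma
        Polynomial scale, > 0.  Required by ``poly`` and both mixtures.
    p
        Polynomial degree, integer >= 1.
    beta
        Sum-mixture weight on the RBF term, strictly inside (0, 1).
    scale
        Nonnegative multiplier for ``scaled`` kernels.
    children
        Child spec for ``scaled`` (exactly one).
    """

    kind: str
    gamma: Optional[float] = None
    sigma: Optional[float] = None
    p: Optional[int] = None
    beta: Optional[float] = None
    scale: Optional[float] = None
    children: tuple["KernelSpec", ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise KernelParameterError(f"unknown kernel kind {self.kind!r}")
        needs_gamma = self.kind in {"rbf", "literal_rbf", "sum_mixture",
                                    "product_mixture"}
        needs_poly = self.kind in {"poly", "sum_mixture", "product_mixture"}
        if needs_gamma:
            if self.gamma is None or not self.gamma > 0:
                raise KernelParameterError(
                    f"gamma must be positive, got {self.gamma}")
        if needs_poly:
            if self.sigma is None or not self.sigma > 0:
                raise KernelParameterError(
                    f"sigma must be positive, got {self.sigma}")
            if self.p is None or int(self.p) != self.p or self.p < 1:
                raise KernelParameterError(
                    f"degree p must be an integer >= 1, got {self.p}")
            object.__setattr__(self, "p", int(self.p))
        if self.kind == "sum_mixture":
            if self.beta is None or not (0.0 < self.beta < 1.0):
                raise KernelParameterError(
                    f"beta must lie strictly in (0, 1), got {self.beta}")
        if self.kind == "scaled":
            if self.scale is None or self.scale < 0:
                raise KernelParameterError(
                    f"scale must be nonnegative, got {self.scale}")
            if len(self.children) != 1:
                raise KernelParameterError(
                    "scaled kernel requires exactly one child spec")

    @property
    def admissible(self) -> bool:
        if self.kind == "scaled":
            return self.children[0].admissible
        return self.kind in ADMISSIBLE_KINDS

    # -- flat key-value serialization (CLI config block) -------------------

    def to_dict(self) -> dict:
        out: dict = {"kind": self.kind}
        for key in ("gamma", "sigma", "p", "beta", "scale"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.children:
            out["children"] = [c.to_dict() for c in self.children]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        d = dict(d)
        children = tuple(cls.from_dict(c) for c in d.pop("children", ()))
        return cls(children=children, **d)


@dataclass
class GramMatrix:
    """Matrix of pairwise kernel evaluations over one or two point sets."""

    values: np.ndarray
    kernel: KernelSpec
    symmetric: bool


def _as_2d(x: np.ndarray) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    return a


def _check_dims(x: np.ndarray, z: np.ndarray) -> None:
    if x.shape[-1] != z.shape[-1]:
        raise DimensionMismatchError(
            f"points have dimensions {x.shape[-1]} and {z.shape[-1]}")


def eval_rbf(x, z, gamma: float) -> float:
    """Gaussian RBF kernel exp(-gamma * ||x - z||^2); value in (0, 1]."""
    if not gamma > 0:
        raise KernelParameterError(f"gamma must be positive, got {gamma}")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_dims(x, z)
    d2 = float(np.sum((x - z) ** 2))
    return float(np.exp(-gamma * d2))


def eval_poly(x, z, sigma: float, p: int) -> float:
    """Inhomogeneous polynomial kernel (1 + sigma * <x, z>)^p."""
    if not sigma > 0:
        raise KernelParameterError(f"sigma must be positive, got {sigma}")
    if int(p) != p or p < 1:
        raise KernelParameterError(f"degree p must be an integer >= 1, got {p}")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_dims(x, z)
    return float((1.0 + sigma * float(np.dot(x, z))) ** int(p))


def eval_sum_mixture(x, z, gamma: float, sigma: float, p: int,
                     beta: float) -> float:
    """Convex sum mixture beta*RBF + (1-beta)*poly, beta in (0, 1)."""
    if not (0.0 < beta < 1.0):
        raise KernelParameterError(
            f"beta must lie strictly in (0, 1), got {beta}")
    return beta * eval_rbf(x, z, gamma) + (1.0 - beta) * eval_poly(x, z, sigma, p)


def eval_product_mixture(x, z, gamma: float, sigma: float, p: int) -> float:
    """Product mixture RBF * poly."""
    return eval_rbf(x, z, gamma) * eval_poly(x, z, sigma, p)


def eval_kernel(kernel: KernelSpec, x, z) -> float:
    """Evaluate an arbitrary :class:`KernelSpec` at a single pair of points."""
    g = gram_matrix(kernel, _as_2d(np.atleast_1d(np.asarray(x, dtype=float))),
                    _as_2d(np.atleast_1d(np.asarray(z, dtype=float))))
    return float(g.values[0, 0])


def gram_matrix(kernel: KernelSpec, X, Z=None) -> GramMatrix:
    """Build the Gram matrix K[i, j] = kernel(X[i], Z[j]).

    When ``Z`` is omitted the matrix is built on ``X`` alone and flagged
    symmetric.
    """
    X = _as_2d(X)
    symmetric = Z is None
    Z = X if Z is None else _as_2d(Z)
    if X.shape[0] == 0 or Z.shape[0] == 0:
        raise DimensionMismatchError("empty point set")
    _check_dims(X, Z)
    values = _gram_values(kernel, X, Z)
    return GramMatrix(values=values, kernel=kernel, symmetric=symmetric)


def _gram_values(kernel: KernelSpec, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    kind = kernel.kind
    if kind == "rbf":
        return np.exp(-kernel.gamma * cdist(X, Z, "sqeuclidean"))
    if kind == "literal_rbf":
        # intentionally non-Mercer: positive exponent
        return np.exp(kernel.gamma * cdist(X, Z, "sqeuclidean"))
    if kind == "poly":
        return (1.0 + kernel.sigma * (X @ Z.T)) ** kernel.p
    if kind == "linear_raw":
        return X @ Z.T
    if kind == "sum_mixture":
        rbf = np.exp(-kernel.gamma * cdist(X, Z, "sqeuclidean"))
        poly = (1.0 + kernel.sigma * (X @ Z.T)) ** kernel.p
        return kernel.beta * rbf + (1.0 - kernel.beta) * poly
    if kind == "product_mixture":
        rbf = np.exp(-kernel.gamma * cdist(X, Z, "sqeuclidean"))
        poly = (1.0 + kernel.sigma * (X @ Z.T)) ** kernel.p
        return rbf * poly
    if kind == "scaled":
        return kernel.scale * _gram_values(kernel.children[0], X, Z)
    raise KernelParameterError(f"unknown kernel kind {kind!r}")


@dataclass
class AdmissibilityReport:
    """Result of an empirical positive-semidefiniteness check."""

    min_eigenvalue: float
    n: int
    tol: float
    passed: bool


def check_admissible(kernel: KernelSpec, X, tol: float = 1e-8) -> AdmissibilityReport:
    """Empirically check Mercer admissibility on a finite point set.

    Computes the eigenvalues of the symmetric Gram matrix on ``X`` and passes
    iff the minimum eigenvalue is >= ``-tol * n``.  The tolerance scales with
    ``n`` to absorb floating-point eigenvalue noise on larger matrices.
    """
    X = _as_2d(X)
    n = X.shape[0]
    if n < 2:
        raise DimensionMismatchError("admissibility check needs n >= 2 points")
    K = _gram_values(kernel, X, X)
    if not np.allclose(K, K.T, atol=1e-10, rtol=0.0):
        raise RuntimeError("Gram matrix is not symmetric")  # pragma: no cover
    min_eig = float(np.linalg.eigvalsh((K + K.T) / 2.0).min())
    return AdmissibilityReport(min_eigenvalue=min_eig, n=n, tol=tol,
                               passed=min_eig >= -tol * n)


def induced_feature_distance(kernel: KernelSpec, x, z) -> float:
    """Distance between feature-space images of ``x`` and ``z``.

    A Mercer kernel is an inner product in feature space, so the squared
    distance between images is K(x,x) + K(z,z) - 2 K(x,z); tiny negative
    round-off is clamped to zero.
    """
    kxx = eval_kernel(kernel, x, x)
    kzz = eval_kernel(kernel, z, z)
    kxz = eval_kernel(kernel, x, z)
    return float(np.sqrt(max(0.0, kxx + kzz - 2.0 * kxz)))
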