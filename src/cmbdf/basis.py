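"""Hermite polynomials, Hermite-Gaussian kernels and weighting functions.

The m-th derivative of a normalized Gaussian is, up to sign and scale, the
Hermite-Gaussian

    f_m(r) = N(r; 0, sigma) * H_m(r / (sqrt(2) sigma)),

with H_m the physicists' Hermite polynomial.  Derivatives of the atomic
density therefore never need numerical differentiation: raising the
derivative order just raises the Hermite degree,

    d/dr f_m(r) = -(1 / (sqrt(2) sigma)) f_{m+1}(r).

Each body order nu carries two families of weighting functions indexed by an
integer order n >= 0:

* radial (nu = 2, 4):  exp(-alpha (n+1) r)   and   (r + 1)^-(2n+3)
* angular (nu = 3):    cos((2n+1) theta) - cos((2n+1)(theta + pi))
                       and the analogous sine pair,

which for the odd multiplier 2n+1 reduce to 2 cos((2n+1) theta) and
2 sin((2n+1) theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightingSpec",
    "families_for",
    "hermite_poly",
    "hermite_gaussian",
    "weighting_value",
    "DEFAULT_ALPHA",
]

#: Default decay rate (1/angstrom) of the exponential radial weighting family
#: for the two- and four-body functionals.
DEFAULT_ALPHA = 1.5

RADIAL_FAMILIES = ("decay_exp", "decay_power")
ANGULAR_FAMILIES = ("cosine", "sine")


def families_for(nu: int) -> tuple[str, str]:
    """The two weighting-function families (type 0, type 1) for body order nu."""
    if nu == 3:
        return ANGULAR_FAMILIES
    if nu in (2, 4):
        return RADIAL_FAMILIES
    raise ValueError(f"unsupported body order: {nu}")


@dataclass(frozen=True)
class WeightingSpec:
    """One weighting function: body order, family, integer order, decay rate."""

    body_order: int
    family: str
    n: int
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.family not in families_for(self.body_order):
            raise ValueError(
                f"family {self.family!r} is not valid for body order "
                f"{self.body_order} (expected one of "
                f"{families_for(self.body_order)})"
            )
        if self.n < 0:
            raise ValueError(f"weighting order must be >= 0, got {self.n}")
        if self.family in RADIAL_FAMILIES and self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @property
    def is_angular(self) -> bool:
        return self.family in ANGULAR_FAMILIES


def hermite_poly(m: int, u):
    """Physicists' Hermite polynomial H_m(u), by the three-term recurrence.

    Vectorized over ``u``; validated against ``scipy.special.eval_hermite``
    in the test suite.
    """
    if m < 0:
        raise ValueError(f"Hermite degree must be >= 0, got {m}")
    u = np.asarray(u, dtype=float)
    h_prev = np.ones_like(u)
    if m == 0:
        return h_prev if h_prev.ndim else float(h_prev)
    h = 2.0 * u
    for k in range(1, m):
        h, h_prev = 2.0 * u * h - 2.0 * k * h_prev, h
    return h if h.ndim else float(h)


def hermite_gaussian(m: int, r, sigma: float):
    """Hermite-Gaussian f_m(r) = N(r; 0, sigma) H_m(r / (sqrt(2) sigma))."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r = np.asarray(r, dtype=float)
    norm = 1.0 / math.sqrt(2.0 * math.pi * sigma * sigma)
    u = r / (math.sqrt(2.0) * sigma)
    out = norm * np.exp(-(u * u)) * hermite_poly(m, u)
    return out if np.ndim(out) else float(out)


def weighting_value(spec: WeightingSpec, x):
    """Evaluate the weighting function of ``spec`` at ``x`` (vectorized).

    Radial families take a nonnegative distance in angstrom, angular
    families any angle in radians.
    """
    x = np.asarray(x, dtype=float)
    n = spec.n
    if spec.family == "decay_exp":
        out = np.exp(-spec.alpha * (n + 1) * x)
    elif spec.family == "decay_power":
        out = (x + 1.0) ** (-(2 * n + 3))
    elif spec.family == "cosine":
        k = 2 * n + 1
        out = np.cos(k * x) - np.cos(k * (x + math.pi))
    elif spec.family == "sine":
        k = 2 * n + 1
        out = np.sin(k * x) - np.sin(k * (x + math.pi))
    else:  # pragma: no cover - guarded by WeightingSpec
        raise ValueError(f"unknown family {spec.family!r}")
    return out if np.ndim(out) else float(out)
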