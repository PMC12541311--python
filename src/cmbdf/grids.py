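"""Precomputed convolution grids H_{nu,n,m} and fast lookups.

Every feature component is an integral of a weighting function g against a
derivative of the smooth many-body distribution.  Because the distribution
is a sum of Gaussians, each component reduces to a sum of values of the
convolved function

    H_{nu,n,m}(x) = (g_{n,nu} * f_m)(x),

which is system independent: it is evaluated once by the convolution theorem
(discrete Fourier transforms) on a fixed 1-D grid and then only looked up.
Radial body orders (nu = 2, 4) use a zero-padded linear convolution on
[0, x_hi]; the angular order (nu = 3) uses a circular convolution with
period 2*pi.

Grids are stored one derivative order beyond the configured maximum so that
analytic gradients (which raise the Hermite degree by one) never trigger a
rebuild.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import fftconvolve

from .basis import WeightingSpec, families_for, hermite_gaussian, weighting_value

__all__ = [
    "ConvolutionGrid",
    "GridSet",
    "build_radial_grid",
    "build_angular_grid",
    "lookup",
    "save_gridset",
    "load_gridset",
]

#: Default radial grid spacing (angstrom) and angular node count.
DEFAULT_RADIAL_DX = 0.002
DEFAULT_ANGULAR_NODES = 4096

INTERP_MODES = ("cubic", "linear", "nearest")


@dataclass
class ConvolutionGrid:
    """Tabulation of one convolved function H_{nu,n,m} on a 1-D grid.

    Radial grids cover [0, x_hi] with spacing ``dx``; angular grids hold one
    period [0, 2*pi) with ``len(values)`` uniform nodes and are understood
    periodically.
    """

    spec: WeightingSpec
    m: int
    sigma_used: float
    dx: float
    values: np.ndarray
    periodic: bool
    interp_mode: str = "cubic"
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)

    @property
    def body_order(self) -> int:
        return self.spec.body_order

    @property
    def x_hi(self) -> float:
        if self.periodic:
            return 2.0 * math.pi
        return (len(self.values) - 1) * self.dx

    @property
    def nodes(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dx

    def key(self) -> tuple:
        return (
            self.spec.body_order,
            self.spec.family,
            self.spec.n,
            round(self.spec.alpha, 12),
            self.m,
            round(self.sigma_used, 12),
            round(self.dx, 15),
            len(self.values),
        )

    def key_hash(self) -> str:
        return hashlib.sha256(repr(self.key()).encode()).hexdigest()[:16]

    def spline(self) -> CubicSpline:
        if self._spline is None:
            if self.periodic:
                x = np.append(self.nodes, 2.0 * math.pi)
                y = np.append(self.values, self.values[0])
                self._spline = CubicSpline(x, y, bc_type="periodic")
            else:
                self._spline = CubicSpline(self.nodes, self.values)
        return self._spline


def _check_spacing(dx: float, sigma: float) -> None:
    if dx > sigma / 4.0:
        raise ValueError(
            f"grid spacing {dx} is too coarse for kernel width sigma={sigma}: "
            f"need dx <= sigma/4 = {sigma / 4.0:.4g} (sigma/10 recommended)"
        )


def build_radial_grid(
    spec: WeightingSpec,
    m: int,
    sigma: float,
    x_hi: float,
    dx: float = DEFAULT_RADIAL_DX,
    interp_mode: str = "cubic",
) -> ConvolutionGrid:
    """Tabulate H(x) = integral_0^inf g(r) f_m(x - r) dr for x in [0, x_hi].

    The weighting function is sampled on [0, x_hi + pad] and the
    Hermite-Gaussian on [-pad, pad] with pad = 8*sigma, so that the linear
    (zero-padded) discrete convolution equals the half-line integral to
    quadrature accuracy at every requested node.
    """
    if spec.is_angular:
        raise ValueError("build_radial_grid requires a radial weighting family")
    _check_spacing(dx, sigma)
    n_x = int(round(x_hi / dx)) + 1
    pad = int(math.ceil(8.0 * sigma / dx))
    r = np.arange(n_x + pad) * dx
    g = np.asarray(weighting_value(spec, r), dtype=float)
    # trapezoid end weights: the discrete convolution then matches the
    # half-line integral to O(dx^2) instead of O(dx) at the r=0 boundary
    g[0] *= 0.5
    g[-1] *= 0.5
    s = (np.arange(2 * pad + 1) - pad) * dx
    f = np.asarray(hermite_gaussian(m, s, sigma), dtype=float)
    conv = fftconvolve(g, f) * dx
    # full-conv index k corresponds to x = (k - pad) * dx
    values = conv[pad : pad + n_x].copy()
    return ConvolutionGrid(spec, m, sigma, dx, values, False, interp_mode)


def build_angular_grid(
    spec: WeightingSpec,
    m: int,
    sigma_ang: float,
    n_nodes: int = DEFAULT_ANGULAR_NODES,
    interp_mode: str = "cubic",
) -> ConvolutionGrid:
    """Circular (period 2*pi) convolution of an angular weighting with f_m."""
    if not spec.is_angular:
        raise ValueError("build_angular_grid requires an angular weighting family")
    if n_nodes < 1024 or (n_nodes & (n_nodes - 1)) != 0:
        raise ValueError(f"n_nodes must be a power of two >= 1024, got {n_nodes}")
    dtheta = 2.0 * math.pi / n_nodes
    _check_spacing(dtheta, sigma_ang)
    theta = np.arange(n_nodes) * dtheta
    g = np.asarray(weighting_value(spec, theta), dtype=float)
    # periodically wrapped Hermite-Gaussian centered at 0
    f = np.zeros(n_nodes)
    for shift in (-2.0 * math.pi, 0.0, 2.0 * math.pi):
        f += hermite_gaussian(m, theta + shift, sigma_ang)
    values = np.real(np.fft.ifft(np.fft.fft(g) * np.fft.fft(f))) * dtheta
    return ConvolutionGrid(spec, m, sigma_ang, dtheta, values, True, interp_mode)


def lookup(grid: ConvolutionGrid, x, mode: str | None = None):
    """Interpolated value(s) of a stored grid at ``x``.

    Radial grids return 0 beyond their upper edge (decayed tail); angular
    lookups are only meaningful on [0, pi] but any finite angle is wrapped.
    Modes: ``cubic`` (default), ``linear``, ``nearest``.
    """
    mode = mode or grid.interp_mode
    if mode not in INTERP_MODES:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.isnan(x).any():
        raise ValueError("lookup received NaN coordinate(s)")
    if grid.periodic:
        x = np.mod(x, 2.0 * math.pi)
        if mode == "cubic":
            out = grid.spline()(x)
        elif mode == "linear":
            nodes = np.append(grid.nodes, 2.0 * math.pi)
            vals = np.append(grid.values, grid.values[0])
            out = np.interp(x, nodes, vals)
        else:
            idx = np.mod(np.rint(x / grid.dx).astype(int), len(grid.values))
            out = grid.values[idx]
    else:
        if (x < -1e-12).any():
            raise ValueError("radial lookup requires nonnegative distances")
        x = np.clip(x, 0.0, None)
        inside = x <= grid.x_hi
        out = np.zeros_like(x)
        if mode == "cubic":
            out[inside] = grid.spline()(x[inside])
        elif mode == "linear":
            out[inside] = np.interp(x[inside], grid.nodes, grid.values)
        else:
            idx = np.minimum(
                np.rint(x[inside] / grid.dx).astype(int), len(grid.values) - 1
            )
            out[inside] = grid.values[idx]
    return float(out[0]) if scalar else out


class GridSet:
    """All convolution grids needed by a feature/gradient configuration.

    Keys are (nu, type index, weighting order n, derivative order m); grids
    for distinct kernel widths (per-element sigma) are held separately.
    """

    def __init__(self) -> None:
        self._grids: dict[tuple, ConvolutionGrid] = {}
        self.interp_mode = "cubic"

    @staticmethod
    def _key(nu: int, type_idx: int, n: int, m: int, sigma: float) -> tuple:
        return (nu, type_idx, n, m, round(float(sigma), 12))

    def add(self, type_idx: int, grid: ConvolutionGrid) -> None:
        key = self._key(grid.body_order, type_idx, grid.spec.n, grid.m, grid.sigma_used)
        self._grids[key] = grid

    def get(
        self, nu: int, type_idx: int, n: int, m: int, sigma: float
    ) -> ConvolutionGrid:
        key = self._key(nu, type_idx, n, m, sigma)
        try:
            return self._grids[key]
        except KeyError:
            raise KeyError(
                f"no grid for (nu={nu}, type={type_idx}, n={n}, m={m}, "
                f"sigma={sigma}); GridSet holds {len(self._grids)} grids"
            ) from None

    def __len__(self) -> int:
        return len(self._grids)

    def __iter__(self):
        return iter(self._grids.items())

    @classmethod
    def build(cls, cfg) -> "GridSet":
        """Build the complete set for a configuration (see CmbdfConfig).

        Derivative orders run to ``cfg.m_max + 1`` so gradient evaluation,
        which raises the Hermite degree by one, finds its grids.
        """
        gs = cls()
        gs.interp_mode = cfg.interp_mode
        x_hi = cfg.r_cut + 6.0 * max(cfg.sigma_values())
        for nu in range(2, cfg.nu + 1):
            families = families_for(nu)
            alpha = cfg.alpha2 if nu == 2 else cfg.alpha4
            for type_idx, family in enumerate(families):
                for n in range(cfg.n_max):
                    spec = WeightingSpec(nu, family, n, alpha)
                    for m in range(cfg.m_max + 2):
                        if nu == 3:
                            gs.add(
                                type_idx,
                                build_angular_grid(
                                    spec,
                                    m,
                                    cfg.sigma_ang,
                                    cfg.angular_nodes,
                                    cfg.interp_mode,
                                ),
                            )
                        else:
                            for sigma in cfg.kernel_sigmas(nu):
                                gs.add(
                                    type_idx,
                                    build_radial_grid(
                                        spec,
                                        m,
                                        sigma,
                                        x_hi,
                                        cfg.radial_dx,
                                        cfg.interp_mode,
                                    ),
                                )
        return gs


def save_gridset(gs: GridSet, path) -> None:
    """Serialize a GridSet to HDF5 (one dataset per grid, keyed by hash)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["interp_mode"] = gs.interp_mode
        for (nu, type_idx, n, m, sigma), grid in gs:
            ds = fh.create_dataset(grid.key_hash(), data=grid.values)
            ds.attrs.update(
                {
                    "nu": nu,
                    "type_idx": type_idx,
                    "family": grid.spec.family,
                    "n": n,
                    "alpha": grid.spec.alpha,
                    "m": m,
                    "sigma": sigma,
                    "dx": grid.dx,
                    "periodic": grid.periodic,
                }
            )


def load_gridset(path) -> GridSet:
    import h5py

    gs = GridSet()
    with h5py.File(path, "r") as fh:
        gs.interp_mode = str(fh.attrs["interp_mode"])
        for name in fh:
            ds = fh[name]
            a = ds.attrs
            spec = WeightingSpec(
                int(a["nu"]), str(a["family"]), int(a["n"]), float(a["alpha"])
            )
            grid = ConvolutionGrid(
                spec,
                int(a["m"]),
                float(a["sigma"]),
                float(a["dx"]),
                np.asarray(ds[...]),
                bool(a["periodic"]),
                gs.interp_mode,
            )
            gs.add(int(a["type_idx"]), grid)
    return gs
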