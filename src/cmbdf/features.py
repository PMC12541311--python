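"""Invariant functionals P_{nu,n,m} and their assembly into feature vectors.

A configuration is fully determined by three integers -- the many-body order
nu (2: distances, 3: angles, 4: quadruplets), the derivative order m, and
the weighting-function order n -- plus widths and cutoffs.  The per-atom
feature vector concatenates, for each body order from 2 up to nu, both
weighting-function types, all orders n < n_max and all derivative orders
m <= m_max, giving the fixed length

    2 * (nu - 1) * (m_max + 1) * n_max

independent of composition, neighbor count and cutoff.  The default
(nu=3, m=4, n=2) yields 40 components per atom; nu=4 yields 60.

Each component is a weighted sum of grid lookups:

    P_2nm[i] = s_m(sigma)      sum_j     A_2(Z_j)                H_2nm(R_ij)
    P_3nm[i] = s_m(sigma_ang)  sum_{j<k} A_3 (R_ij R_ik R_jk)^-2 H_3nm(theta_ijk)
    P_4nm[i] = s_m(sig_ijkl)  sum_{j<k<l} A_4 zeta_ijkl f_ijkl   H_4nm(R_ijkl)

where s_m is the derivative-order prefactor.  The default convention
s_m = (sqrt(2) sigma)^-m makes P exactly equal to the defining integral of
the weighting function against the m-th derivative of the smooth many-body
distribution (this is what the quadrature oracle computes); alternative
conventions rescale each m-block only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import elements
from .basis import DEFAULT_ALPHA
from .geometry import AtomicEnvironment, Molecule, build_environment
from .grids import (
    DEFAULT_ANGULAR_NODES,
    DEFAULT_RADIAL_DX,
    GridSet,
    lookup,
)

__all__ = [
    "CmbdfConfig",
    "FeatureMatrix",
    "feature_index_map",
    "m_prefactor",
    "two_body_features",
    "three_body_features",
    "four_body_features",
    "atomic_representation",
    "representation",
    "molecular_representation",
]


@dataclass
class CmbdfConfig:
    """Everything that determines a cMBDF representation.

    Parameters
    ----------
    nu
        Many-body order, 2-4 (2 is supported for diagnostics; published
        variants use 3 and 4).
    m_max
        Highest derivative order included (m = 0..m_max).
    n_max
        Number of weighting-function orders per type (n = 0..n_max-1).
    sigma
        Radial Gaussian width in angstrom; a mapping Z -> sigma enables
        element-specific basis functions (the four-body block then falls
        back to direct quadrature, since its effective width varies).
    sigma_ang
        Angular Gaussian width in radians.
    r_cut
        Hard neighbor cutoff in angstrom.
    alpha2, alpha4
        Exponential decay rates (1/angstrom) of the radial weighting family.
    prefactor
        Derivative-order scaling convention: "derivative" ((sqrt2 sigma)^-m,
        equal to the defining integral), "sqrt2sigma" or "literal".
    zeta_mode
        "gaussian" keeps the Gaussian-product spread penalty on quadruplets;
        "unit" renormalizes it away.
    """

    nu: int = 3
    m_max: int = 4
    n_max: int = 2
    sigma: float | Mapping[int, float] = elements.DEFAULT_SIGMA
    sigma_ang: float = 0.2
    r_cut: float = 8.0
    alpha2: float = DEFAULT_ALPHA
    alpha4: float = DEFAULT_ALPHA
    radial_dx: float = DEFAULT_RADIAL_DX
    angular_nodes: int = DEFAULT_ANGULAR_NODES
    interp_mode: str = "cubic"
    prefactor: str = "derivative"
    zeta_mode: str = "gaussian"
    ordered_counting: bool = False
    element_list: Sequence[int] = field(default_factory=tuple)
    scaling_form: Callable[[int, int], float] | None = None

    def __post_init__(self) -> None:
        if self.nu not in (2, 3, 4):
            raise ValueError(f"nu must be 2, 3 or 4, got {self.nu}")
        if self.m_max < 0 or self.n_max < 1:
            raise ValueError("need m_max >= 0 and n_max >= 1")
        if self.sigma_ang <= 0 or self.r_cut <= 0:
            raise ValueError("sigma_ang and r_cut must be positive")
        if self.prefactor not in ("derivative", "sqrt2sigma", "literal"):
            raise ValueError(f"unknown prefactor convention {self.prefactor!r}")
        if self.zeta_mode not in ("gaussian", "unit"):
            raise ValueError(f"unknown zeta mode {self.zeta_mode!r}")
        if min(self.sigma_values()) <= 0:
            raise ValueError("sigma must be positive")

    # -- widths ----------------------------------------------------------
    def sigma_for(self, Z: int) -> float:
        if isinstance(self.sigma, Mapping):
            try:
                return float(self.sigma[int(Z)])
            except KeyError:
                raise KeyError(f"no sigma configured for element Z={Z}") from None
        return float(self.sigma)

    def sigma_values(self) -> tuple[float, ...]:
        if isinstance(self.sigma, Mapping):
            return tuple(sorted({float(v) for v in self.sigma.values()}))
        return (float(self.sigma),)

    @property
    def uniform_sigma(self) -> bool:
        return len(self.sigma_values()) == 1

    def kernel_sigmas(self, nu: int) -> tuple[float, ...]:
        """Kernel widths the GridSet must tabulate for body order ``nu``."""
        if nu == 3:
            return (self.sigma_ang,)
        if nu == 4:
            if not self.uniform_sigma:
                return ()  # four-body handled by quadrature fallback
            return (self.sigma_values()[0] / math.sqrt(6.0),)
        return self.sigma_values()

    # -- layout ----------------------------------------------------------
    @property
    def feature_length(self) -> int:
        return 2 * (self.nu - 1) * (self.m_max + 1) * self.n_max

    def build_grids(self) -> GridSet:
        return GridSet.build(self)


def m_prefactor(m: int, sigma: float, convention: str = "derivative") -> float:
    """Derivative-order scaling s_m applied to every H lookup."""
    if convention == "derivative":
        return (math.sqrt(2.0) * sigma) ** (-m)
    if convention == "sqrt2sigma":
        return (math.sqrt(2.0) * sigma) ** m
    if convention == "literal":
        return (2.0 * sigma) ** m
    raise ValueError(f"unknown prefactor convention {convention!r}")


def feature_index_map(cfg: CmbdfConfig) -> list[tuple[int, int, int, int]]:
    """Ordered (nu, type, n, m) tuple for every feature position."""
    out = []
    for nu in range(2, cfg.nu + 1):
        for type_idx in range(2):
            for n in range(cfg.n_max):
                for m in range(cfg.m_max + 1):
                    out.append((nu, type_idx, n, m))
    return out


@dataclass
class FeatureMatrix:
    """Per-atom feature vectors of one molecule (rows follow atom order)."""

    Zs: np.ndarray
    values: np.ndarray  # (n_atoms, feature_length)

    @property
    def n_atoms(self) -> int:
        return len(self.Zs)


def _block(cfg: CmbdfConfig, fill) -> np.ndarray:
    """Evaluate one (type, n, m)-indexed block via ``fill(type, n, m)``."""
    out = np.zeros((2, cfg.n_max, cfg.m_max + 1))
    for t in range(2):
        for n in range(cfg.n_max):
            for m in range(cfg.m_max + 1):
                out[t, n, m] = fill(t, n, m)
    return out


def two_body_features(
    env: AtomicEnvironment, cfg: CmbdfConfig, grids: GridSet
) -> np.ndarray:
    """Pair block: sum over neighbors of A_2 s_m H_2nm(R_ij)."""

    def fill(t: int, n: int, m: int) -> float:
        total = 0.0
        for sigma in np.unique(env.sigma_j) if env.n_neighbors else []:
            mask = env.sigma_j == sigma
            grid = grids.get(2, t, n, m, sigma)
            s = m_prefactor(m, sigma, cfg.prefactor)
            total += s * float(np.dot(env.w2[mask], lookup(grid, env.r_ij[mask])))
        return total

    return _block(cfg, fill)


def three_body_features(
    env: AtomicEnvironment, cfg: CmbdfConfig, grids: GridSet
) -> np.ndarray:
    """Triplet block: ATM-damped angular functionals H_3nm(theta_ijk)."""

    def fill(t: int, n: int, m: int) -> float:
        if len(env.theta) == 0:
            return 0.0
        grid = grids.get(3, t, n, m, cfg.sigma_ang)
        s = m_prefactor(m, cfg.sigma_ang, cfg.prefactor)
        return s * float(np.dot(env.w3 * env.f3, lookup(grid, env.theta)))

    return _block(cfg, fill)


def four_body_features(
    env: AtomicEnvironment, cfg: CmbdfConfig, grids: GridSet
) -> np.ndarray:
    """Quadruplet block: Gaussian-product-reduced radial functionals.

    With a uniform basis width all quadruplets share the effective width
    sigma/sqrt(6) and a single grid serves every lookup; with per-element
    widths each quadruplet's convolution is integrated directly.
    """

    if cfg.uniform_sigma:

        def fill(t: int, n: int, m: int) -> float:
            if len(env.r_eff) == 0:
                return 0.0
            sigma_eff = cfg.kernel_sigmas(4)[0]
            grid = grids.get(4, t, n, m, sigma_eff)
            s = m_prefactor(m, sigma_eff, cfg.prefactor)
            w = env.w4 * env.zeta * env.f4
            return s * float(np.dot(w, lookup(grid, env.r_eff)))

    else:
        from .oracle import convolved_value  # quadrature fallback
        from .basis import WeightingSpec, families_for

        def fill(t: int, n: int, m: int) -> float:
            total = 0.0
            spec = WeightingSpec(4, families_for(4)[t], n, cfg.alpha4)
            for q in range(len(env.r_eff)):
                s = m_prefactor(m, env.sigma_eff[q], cfg.prefactor)
                h = convolved_value(spec, m, env.sigma_eff[q], env.r_eff[q])
                total += s * env.w4[q] * env.zeta[q] * env.f4[q] * h
            return total

    return _block(cfg, fill)


_BLOCK_FUNCS = {2: two_body_features, 3: three_body_features, 4: four_body_features}


def atomic_representation(
    mol: Molecule, i: int, cfg: CmbdfConfig, grids: GridSet
) -> np.ndarray:
    """Feature vector of atom ``i``: body orders ascending, then type, n, m."""
    env = build_environment(mol, i, cfg)
    parts = [_BLOCK_FUNCS[nu](env, cfg, grids).ravel() for nu in range(2, cfg.nu + 1)]
    return np.concatenate(parts)


def representation(mol: Molecule, cfg: CmbdfConfig, grids: GridSet) -> FeatureMatrix:
    rows = [atomic_representation(mol, i, cfg, grids) for i in range(mol.n_atoms)]
    return FeatureMatrix(Zs=mol.Zs.copy(), values=np.array(rows))


def molecular_representation(
    mol: Molecule, cfg: CmbdfConfig, grids: GridSet, mode: str = "sum"
) -> np.ndarray:
    """Global vector: plain sum of atomic vectors, or per-element bagged sums.

    In ``element_bag`` mode the configured element list fixes the bag order;
    elements absent from the molecule contribute zero blocks.
    """
    fm = representation(mol, cfg, grids)
    if mode == "sum":
        return fm.values.sum(axis=0)
    if mode == "element_bag":
        if not cfg.element_list:
            raise ValueError("element_bag mode requires cfg.element_list")
        missing = set(map(int, fm.Zs)) - set(map(int, cfg.element_list))
        if missing:
            raise ValueError(
                f"molecule contains elements {sorted(missing)} absent from "
                f"the configured element list"
            )
        bags = []
        for Z in cfg.element_list:
            mask = fm.Zs == Z
            bags.append(
                fm.values[mask].sum(axis=0)
                if mask.any()
                else np.zeros(cfg.feature_length)
            )
        return np.concatenate(bags)
    raise ValueError(f"unknown global mode {mode!r}")
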