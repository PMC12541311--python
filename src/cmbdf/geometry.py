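"""Molecular geometry: neighbor lists, internal coordinates, environments.

An atomic environment collects, for one center atom i, everything the
functionals need:

* neighbors j within the hard cutoff, with exact distances R_ij;
* unordered triplets (j < k) with the angle theta_ijk at i and the
  Axilrod-Teller-Muto damping 1 / (R_ij R_ik R_jk)^2;
* unordered quadruplets (j < k < l) with the Gaussian-product reduction of
  the six pair Gaussians to a single effective Gaussian: center R_ijkl,
  width sigma_ijkl, spread penalty zeta, and the product of the six inverse
  square distances.

Open boundary conditions only; the O(N^2) neighbor search is adequate at
molecular scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import elements

__all__ = [
    "Molecule",
    "AtomicEnvironment",
    "neighbor_list",
    "angle",
    "quadruplet_params",
    "gaussian_product_reduce",
    "build_environment",
]

#: Two atoms closer than this (angstrom) indicate a corrupt geometry.
MIN_SANE_DISTANCE = 0.1

QUAD_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class Molecule:
    """Atomic numbers plus Cartesian coordinates in angstrom."""

    Zs: np.ndarray
    coords: np.ndarray
    label: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.Zs = np.asarray(self.Zs, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.Zs.ndim != 1 or len(self.Zs) < 1:
            raise ValueError("a molecule needs at least one atom")
        if self.coords.shape != (len(self.Zs), 3):
            raise ValueError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.Zs)} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if len(self.Zs) > 1:
            d = np.linalg.norm(
                self.coords[:, None, :] - self.coords[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            dmin = float(d.min())
            if dmin < MIN_SANE_DISTANCE:
                raise ValueError(
                    f"atoms closer than {MIN_SANE_DISTANCE} A (min distance "
                    f"{dmin:.3g} A)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.Zs)


@dataclass
class AtomicEnvironment:
    """Internal coordinates of the neighborhood of one center atom."""

    center: int
    # neighbors
    j_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    r_ij: np.ndarray = field(default_factory=lambda: np.empty(0))
    w2: np.ndarray = field(default_factory=lambda: np.empty(0))  # A_2(Z_j)
    sigma_j: np.ndarray = field(default_factory=lambda: np.empty(0))
    # triplets (j < k, both neighbors)
    trip_jk: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    f3: np.ndarray = field(default_factory=lambda: np.empty(0))  # ATM damping
    w3: np.ndarray = field(default_factory=lambda: np.empty(0))  # A_3(Z_j, Z_k)
    trip_dists: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    # quadruplets (j < k < l, all neighbors)
    quad_jkl: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    r_eff: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma_eff: np.ndarray = field(default_factory=lambda: np.empty(0))
    zeta: np.ndarray = field(default_factory=lambda: np.empty(0))
    f4: np.ndarray = field(default_factory=lambda: np.empty(0))
    w4: np.ndarray = field(default_factory=lambda: np.empty(0))
    quad_dists: np.ndarray = field(default_factory=lambda: np.empty((0, 6)))

    @property
    def n_neighbors(self) -> int:
        return len(self.j_idx)


def neighbor_list(mol: Molecule, i: int, r_cut: float):
    """Indices and exact distances of atoms within ``r_cut`` of atom ``i``.

    Hard cutoff, no switching function; the center itself is excluded.
    """
    if not 0 <= i < mol.n_atoms:
        raise IndexError(f"atom index {i} out of range for {mol.n_atoms} atoms")
    d = np.linalg.norm(mol.coords - mol.coords[i], axis=1)
    mask = (d <= r_cut) & (np.arange(mol.n_atoms) != i)
    return np.flatnonzero(mask), d[mask]


def angle(Ri, Rj, Rk) -> float:
    """Angle theta_ijk at vertex i between bonds i->j and i->k, in [0, pi]."""
    u = np.asarray(Rj, dtype=float) - np.asarray(Ri, dtype=float)
    v = np.asarray(Rk, dtype=float) - np.asarray(Ri, dtype=float)
    nu_, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu_ == 0.0 or nv == 0.0:
        raise ValueError("zero-length bond vector in angle computation")
    c = np.clip(np.dot(u, v) / (nu_ * nv), -1.0, 1.0)
    return float(math.acos(c))


def gaussian_product_reduce(centers, sigmas):
    """Collapse a product of 1-D Gaussians into one effective Gaussian.

    Returns (center, sigma, zeta) where zeta is the spread-penalty
    exponential accumulated by successive Gaussian products (constant
    normalization factors dropped).  Precisions add; the center is the
    precision-weighted mean.
    """
    centers = np.asarray(centers, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    prec = 1.0 / (sigmas * sigmas)
    p_tot = prec.sum()
    mu = float((prec * centers).sum() / p_tot)
    # exponent: -1/2 [sum p_a c_a^2 - p_tot mu^2]
    expo = 0.5 * (float((prec * centers * centers).sum()) - p_tot * mu * mu)
    return mu, float(1.0 / math.sqrt(p_tot)), math.exp(-expo)


def quadruplet_params(dists, sigma):
    """Effective (R_ijkl, sigma_ijkl, zeta, f_ijkl) of a four-atom cluster.

    ``dists`` are the six unique interatomic distances; ``sigma`` is either
    a scalar width or one width per distance.  With uniform sigma the
    effective width is sigma/sqrt(6) and the center the arithmetic mean.
    """
    dists = np.asarray(dists, dtype=float)
    if dists.shape != (6,):
        raise ValueError(f"expected six distances, got shape {dists.shape}")
    if (dists <= 0).any():
        raise ValueError("nonpositive interatomic distance")
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (6,))
    if (sig <= 0).any():
        raise ValueError("nonpositive sigma")
    mu, sigma_eff, zeta = gaussian_product_reduce(dists, sig)
    f = float(np.prod(1.0 / (dists * dists)))
    return mu, sigma_eff, zeta, f


def build_environment(mol: Molecule, i: int, cfg) -> AtomicEnvironment:
    """Assemble the AtomicEnvironment of atom ``i`` under configuration ``cfg``.

    Triplets/quadruplets are enumerated once per unordered neighbor set
    unless ``cfg.ordered_counting`` (a pure scale factor) is set.
    """
    env = AtomicEnvironment(center=i)
    idx, dists = neighbor_list(mol, i, cfg.r_cut)
    env.j_idx, env.r_ij = idx, dists
    if len(idx) == 0:
        return env
    env.w2 = np.array([elements.scaling_factor(Z, cfg.scaling_form) for Z in mol.Zs[idx]])
    env.sigma_j = np.array([cfg.sigma_for(Z) for Z in mol.Zs[idx]])
    mult = 2.0 if cfg.ordered_counting else 1.0

    if cfg.nu >= 3 and len(idx) >= 2:
        rows = []
        for a, b in combinations(range(len(idx)), 2):
            j, k = idx[a], idx[b]
            r_jk = float(np.linalg.norm(mol.coords[j] - mol.coords[k]))
            th = angle(mol.coords[i], mol.coords[j], mol.coords[k])
            f = 1.0 / (env.r_ij[a] * env.r_ij[b] * r_jk) ** 2
            w = elements.many_body_scaling([mol.Zs[j], mol.Zs[k]], 3, cfg.scaling_form)
            rows.append((a, b, th, f, w, env.r_ij[a], env.r_ij[b], r_jk))
        arr = np.array(rows)
        env.trip_jk = arr[:, :2].astype(int)
        env.theta = arr[:, 2]
        env.f3 = arr[:, 3] * mult
        env.w3 = arr[:, 4]
        env.trip_dists = arr[:, 5:8]

    if cfg.nu >= 4 and len(idx) >= 3:
        mult4 = 6.0 if cfg.ordered_counting else 1.0
        rows = []
        for a, b, c in combinations(range(len(idx)), 3):
            atoms = (i, idx[a], idx[b], idx[c])
            d6 = np.array(
                [
                    np.linalg.norm(mol.coords[atoms[p]] - mol.coords[atoms[q]])
                    for p, q in QUAD_PAIRS
                ]
            )
            # width of each pair Gaussian follows the non-central atom of
            # the pair (the basis function it came from)
            sig6 = np.array([cfg.sigma_for(mol.Zs[atoms[q]]) for _, q in QUAD_PAIRS])
            mu, sigma_eff, zeta, f = quadruplet_params(d6, sig6)
            if cfg.zeta_mode == "unit":
                zeta = 1.0
            w = elements.many_body_scaling(
                [mol.Zs[idx[a]], mol.Zs[idx[b]], mol.Zs[idx[c]]], 4, cfg.scaling_form
            )
            rows.append((a, b, c, mu, sigma_eff, zeta, f * mult4, w, *d6))
        arr = np.array(rows)
        env.quad_jkl = arr[:, :3].astype(int)
        env.r_eff = arr[:, 3]
        env.sigma_eff = arr[:, 4]
        env.zeta = arr[:, 5]
        env.f4 = arr[:, 6]
        env.w4 = arr[:, 7]
        env.quad_dists = arr[:, 8:14]
    return env
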