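"""Analytic nuclear gradients of the cMBDF functionals.

Differentiating a grid lookup never needs a new convolution: the derivative
of the convolved function raises the Hermite degree by one,

    d/dx H_{nu,n,m}(x) = -(1 / (sqrt(2) sigma)) H_{nu,n,m+1}(x),

so every gradient is assembled from the (m+1)-grids already held by the
GridSet, chained with the gradients of the internal coordinates

    grad_a R_ij     = (delta_aj - delta_ai) (R_j - R_i) / R_ij
    grad_a theta_ijk  (arccos chain rule; zeroed with a logged warning for
                       near-collinear triplets where sin(theta) -> 0)

and product-rule terms on the Axilrod-Teller-Muto and quadruplet damping
factors.  The result tensor holds dP[i, q] / dR[a, c] for every center atom
i, feature q, atom a and Cartesian component c; rows vanish whenever i and
a are farther apart than the cutoff, and summing over a gives exactly zero
(translation invariance).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .features import CmbdfConfig, m_prefactor
from .geometry import QUAD_PAIRS, Molecule, build_environment
from .grids import GridSet, lookup

__all__ = ["distance_gradient", "angle_gradient", "representation_gradients"]

logger = logging.getLogger(__name__)

#: sin(theta) below which the angle gradient is clamped to zero.
COLLINEAR_SIN_TOL = 1e-6


def distance_gradient(mol: Molecule, i: int, j: int, a: int) -> np.ndarray:
    """Gradient of R_ij with respect to the position of atom ``a``."""
    if i == j:
        raise ValueError("distance gradient needs two distinct atoms")
    rij = mol.coords[j] - mol.coords[i]
    d = float(np.linalg.norm(rij))
    if d == 0.0:
        raise ValueError(f"atoms {i} and {j} are coincident")
    if a == j:
        return rij / d
    if a == i:
        return -rij / d
    return np.zeros(3)


def _angle_gradients(Ri, Rj, Rk):
    """Gradients of theta_ijk w.r.t. R_i, R_j, R_k (3 vectors).

    Returns zeros for (near-)collinear triplets, where the arccos derivative
    is singular.
    """
    u = Rj - Ri
    v = Rk - Ri
    nu_ = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    uh, vh = u / nu_, v / nv
    c = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    s = math.sqrt(max(0.0, 1.0 - c * c))
    if s < COLLINEAR_SIN_TOL:
        logger.warning(
            "near-collinear triplet (sin theta = %.2g): angle gradient clamped to 0", s
        )
        z = np.zeros(3)
        return z, z.copy(), z.copy()
    gj = (c * uh - vh) / (nu_ * s)
    gk = (c * vh - uh) / (nv * s)
    gi = -(gj + gk)
    return gi, gj, gk


def angle_gradient(mol: Molecule, i: int, j: int, k: int, a: int) -> np.ndarray:
    """Gradient of theta_ijk (vertex i) with respect to atom ``a``."""
    gi, gj, gk = _angle_gradients(mol.coords[i], mol.coords[j], mol.coords[k])
    if a == i:
        return gi
    if a == j:
        return gj
    if a == k:
        return gk
    return np.zeros(3)


def representation_gradients(
    mol: Molecule, cfg: CmbdfConfig, grids: GridSet
) -> np.ndarray:
    """Full gradient tensor, shape (n_atoms, n_features, n_atoms, 3)."""
    if not cfg.uniform_sigma:
        raise NotImplementedError(
            "analytic gradients require a uniform basis width sigma"
        )
    nA = mol.n_atoms
    L = cfg.feature_length
    out = np.zeros((nA, L, nA, 3))
    block_len = 2 * cfg.n_max * (cfg.m_max + 1)

    def pos(nu, t, n, m):
        return (nu - 2) * block_len + (t * cfg.n_max + n) * (cfg.m_max + 1) + m

    sigma = cfg.sigma_values()[0]
    sqrt2 = math.sqrt(2.0)

    for i in range(nA):
        env = build_environment(mol, i, cfg)
        if env.n_neighbors == 0:
            continue

        # ---- two-body ------------------------------------------------
        uvec = (mol.coords[env.j_idx] - mol.coords[i]) / env.r_ij[:, None]
        for t in range(2):
            for n in range(cfg.n_max):
                for m in range(cfg.m_max + 1):
                    grid1 = grids.get(2, t, n, m + 1, sigma)
                    coef = (
                        m_prefactor(m, sigma, cfg.prefactor)
                        * (-1.0 / (sqrt2 * sigma))
                        * env.w2
                        * lookup(grid1, env.r_ij)
                    )
                    vecs = coef[:, None] * uvec
                    p = pos(2, t, n, m)
                    np.add.at(out[i, p], env.j_idx, vecs)
                    out[i, p, i] -= vecs.sum(axis=0)

        # ---- three-body ----------------------------------------------
        if cfg.nu >= 3 and len(env.theta) > 0:
            c1a = -1.0 / (sqrt2 * cfg.sigma_ang)
            hvals = {}
            for t in range(2):
                for n in range(cfg.n_max):
                    for m in range(cfg.m_max + 2):
                        hvals[(t, n, m)] = lookup(
                            grids.get(3, t, n, m, cfg.sigma_ang), env.theta
                        )
            for tr in range(len(env.theta)):
                a_loc, b_loc = env.trip_jk[tr]
                j, k = env.j_idx[a_loc], env.j_idx[b_loc]
                rij, rik, rjk = env.trip_dists[tr]
                gi_t, gj_t, gk_t = _angle_gradients(
                    mol.coords[i], mol.coords[j], mol.coords[k]
                )
                u_ij = (mol.coords[j] - mol.coords[i]) / rij
                u_ik = (mol.coords[k] - mol.coords[i]) / rik
                u_kj = (mol.coords[j] - mol.coords[k]) / rjk
                f = env.f3[tr]
                gf = {
                    j: -2.0 * f * (u_ij / rij + u_kj / rjk),
                    k: -2.0 * f * (u_ik / rik - u_kj / rjk),
                    i: 2.0 * f * (u_ij / rij + u_ik / rik),
                }
                gth = {i: gi_t, j: gj_t, k: gk_t}
                w = env.w3[tr]
                for t in range(2):
                    for n in range(cfg.n_max):
                        for m in range(cfg.m_max + 1):
                            s = m_prefactor(m, cfg.sigma_ang, cfg.prefactor)
                            H = hvals[(t, n, m)][tr]
                            Hp = c1a * hvals[(t, n, m + 1)][tr]
                            p = pos(3, t, n, m)
                            for atom, gfa in gf.items():
                                out[i, p, atom] += s * w * (
                                    H * gfa + f * Hp * gth[atom]
                                )

        # ---- four-body -----------------------------------------------
        if cfg.nu >= 4 and len(env.r_eff) > 0:
            sigma_eff = cfg.kernel_sigmas(4)[0]
            c14 = -1.0 / (sqrt2 * sigma_eff)
            h4 = {}
            for t in range(2):
                for n in range(cfg.n_max):
                    for m in range(cfg.m_max + 2):
                        h4[(t, n, m)] = lookup(
                            grids.get(4, t, n, m, sigma_eff), env.r_eff
                        )
            for q in range(len(env.r_eff)):
                a_loc, b_loc, c_loc = env.quad_jkl[q]
                atoms = (
                    i,
                    int(env.j_idx[a_loc]),
                    int(env.j_idx[b_loc]),
                    int(env.j_idx[c_loc]),
                )
                d6 = env.quad_dists[q]
                rbar = env.r_eff[q]
                zeta = env.zeta[q]
                f = env.f4[q]
                w = env.w4[q]
                # per-atom gradients of the six distances
                grad_d = np.zeros((4, 6, 3))
                for pr, (p_loc, q_loc) in enumerate(QUAD_PAIRS):
                    vec = (
                        mol.coords[atoms[p_loc]] - mol.coords[atoms[q_loc]]
                    ) / d6[pr]
                    grad_d[p_loc, pr] = vec
                    grad_d[q_loc, pr] = -vec
                grad_rbar = grad_d.mean(axis=1)  # (4, 3)
                grad_f = -2.0 * f * (grad_d / d6[None, :, None]).sum(axis=1)
                if cfg.zeta_mode == "unit":
                    grad_zeta = np.zeros((4, 3))
                else:
                    dev = (d6 - rbar) / (sigma * sigma)  # (6,)
                    grad_zeta = -zeta * (dev[None, :, None] * grad_d).sum(axis=1)
                for t in range(2):
                    for n in range(cfg.n_max):
                        for m in range(cfg.m_max + 1):
                            s = m_prefactor(m, sigma_eff, cfg.prefactor)
                            H = h4[(t, n, m)][q]
                            Hp = c14 * h4[(t, n, m + 1)][q]
                            p = pos(4, t, n, m)
                            for a_idx, atom in enumerate(atoms):
                                out[i, p, atom] += s * w * (
                                    H
                                    * (
                                        zeta * grad_f[a_idx]
                                        + f * grad_zeta[a_idx]
                                    )
                                    + zeta * f * Hp * grad_rbar[a_idx]
                                )
    return out
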