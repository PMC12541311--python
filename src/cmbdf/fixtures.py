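"""Deterministic synthetic molecules and toy labels.

Random "molecules" are rejection-sampled point clouds in a cubic box with a
minimum interatomic distance, drawing elements from a configurable pool.
They exercise every geometric and combinatorial code path (varying atom
counts, 10 distinct elements, short and long distances) without any
external dataset.  The toy label is a sum of pairwise Morse terms

    E = sum_{j<k} D_jk [ (1 - exp(-a_jk (r_jk - re_jk)))^2 - 1 ],

smooth, permutation invariant and extensive, so that a 2/3-body
representation can visibly learn it.  No attempt is made to mimic real
quantum-chemical energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import elements
from .geometry import Molecule

__all__ = [
    "FixtureSpec",
    "MorseParams",
    "random_molecule",
    "random_molecules",
    "toy_energy",
    "write_xyz",
    "DEFAULT_ELEMENT_POOL",
]

#: Ten-element pool (H, C, N, O, F, Si, P, S, Cl, Br) spanning three periods.
DEFAULT_ELEMENT_POOL = (1, 6, 7, 8, 9, 14, 15, 16, 17, 35)


@dataclass(frozen=True)
class MorseParams:
    """Morse well depth D, stiffness a (1/A) and equilibrium distance re (A)
    per unordered element pair, keyed by sorted (Z1, Z2)."""

    table: dict

    def get(self, z1: int, z2: int) -> tuple[float, float, float]:
        key = (min(z1, z2), max(z1, z2))
        try:
            return self.table[key]
        except KeyError:
            raise KeyError(f"no Morse parameters for element pair {key}") from None

    @classmethod
    def default_for(cls, pool: Sequence[int]) -> "MorseParams":
        """Deterministic toy parameters derived from period/group only."""
        table = {}
        pool = sorted(set(int(z) for z in pool))
        for i, z1 in enumerate(pool):
            for z2 in pool[i:]:
                p1, g1 = elements.period_group(z1)
                p2, g2 = elements.period_group(z2)
                depth = float(np.sqrt((1.0 + 0.15 * g1) * (1.0 + 0.15 * g2)))
                re = (0.35 + 0.22 * p1) + (0.35 + 0.22 * p2)
                table[(z1, z2)] = (depth, 1.7, re)
        return cls(table)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible synthetic molecule set."""

    n_molecules: int = 50
    atoms_min: int = 2
    atoms_max: int = 20
    element_pool: Sequence[int] = DEFAULT_ELEMENT_POOL
    min_distance: float = 1.0
    box: float = 6.0
    seed: int = 0
    max_attempts: int = 500
    morse: MorseParams | None = None

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if not self.element_pool:
            raise ValueError("element pool must be non-empty")
        if self.atoms_min < 1 or self.atoms_max < self.atoms_min:
            raise ValueError("invalid atom-count range")

    def morse_params(self) -> MorseParams:
        return self.morse or MorseParams.default_for(self.element_pool)


def random_molecule(spec: FixtureSpec, rng: np.random.Generator) -> Molecule:
    """One rejection-sampled molecule; deterministic given the rng state."""
    n = int(rng.integers(spec.atoms_min, spec.atoms_max + 1))
    Zs = rng.choice(np.asarray(spec.element_pool, dtype=int), size=n)
    coords = np.empty((n, 3))
    for i in range(n):
        for attempt in range(spec.max_attempts):
            cand = rng.uniform(0.0, spec.box, size=3)
            if i == 0 or (
                np.linalg.norm(coords[:i] - cand, axis=1) >= spec.min_distance
            ).all():
                coords[i] = cand
                break
        else:
            raise RuntimeError(
                f"could not place atom {i} after {spec.max_attempts} attempts; "
                f"increase the box size (currently {spec.box} A)"
            )
    mol = Molecule(Zs=Zs, coords=coords)
    mol.label = toy_energy(mol, spec.morse_params())
    return mol


def random_molecules(spec: FixtureSpec) -> list[Molecule]:
    """The full fixture set from one named, seeded generator stream."""
    rng = np.random.default_rng(spec.seed)
    return [random_molecule(spec, rng) for _ in range(spec.n_molecules)]


def toy_energy(mol: Molecule, params: MorseParams) -> float:
    """Sum of pairwise Morse terms over all unordered atom pairs."""
    e = 0.0
    for j in range(mol.n_atoms):
        for k in range(j + 1, mol.n_atoms):
            depth, a, re = params.get(int(mol.Zs[j]), int(mol.Zs[k]))
            r = float(np.linalg.norm(mol.coords[j] - mol.coords[k]))
            x = 1.0 - np.exp(-a * (r - re))
            e += depth * (x * x - 1.0)
    return float(e)


def write_xyz(mols: Sequence[Molecule], path) -> None:
    """Multi-block XYZ; the comment line carries the scalar label if set."""
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{mol.n_atoms}\n")
            fh.write("" if mol.label is None else f"{mol.label:.10f}")
            fh.write("\n")
            for Z, (x, y, z) in zip(mol.Zs, mol.coords):
                fh.write(
                    f"{elements.z_to_symbol(int(Z))} {x:.10f} {y:.10f} {z:.10f}\n"
                )
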