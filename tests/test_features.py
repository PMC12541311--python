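import math

import numpy as np
import pytest

from cmbdf import elements
from cmbdf.features import (
    CmbdfConfig,
    atomic_representation,
    feature_index_map,
    m_prefactor,
    molecular_representation,
    representation,
)
from cmbdf.fixtures import FixtureSpec, random_molecules
from cmbdf.geometry import Molecule, build_environment
from cmbdf.grids import GridSet, lookup
from cmbdf.oracle import quadrature_functional


def rotation_matrix(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestLayout:
    @pytest.mark.parametrize(
        "nu, m_max, n_max, expected",
        [(3, 4, 2, 40), (4, 4, 2, 60), (2, 4, 2, 20), (3, 2, 3, 36)],
    )
    def test_dimension_law(self, nu, m_max, n_max, expected):
        cfg = CmbdfConfig(nu=nu, m_max=m_max, n_max=n_max)
        assert cfg.feature_length == expected
        assert len(feature_index_map(cfg)) == expected

    def test_index_map_order(self, cfg3):
        idx = feature_index_map(cfg3)
        assert idx[0] == (2, 0, 0, 0)
        assert idx[cfg3.m_max] == (2, 0, 0, cfg3.m_max)
        assert idx[-1] == (3, 1, cfg3.n_max - 1, cfg3.m_max)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CmbdfConfig(nu=5)
        with pytest.raises(ValueError):
            CmbdfConfig(n_max=0)
        with pytest.raises(ValueError):
            CmbdfConfig(prefactor="wrong")


class TestClosedForms:
    def test_isolated_atom_is_zero_vector(self, cfg3, grids3):
        mol = Molecule(Zs=[8], coords=[[0.0, 0.0, 0.0]])
        vec = atomic_representation(mol, 0, cfg3, grids3)
        assert vec.shape == (40,)
        assert np.all(vec == 0.0)

    def test_single_neighbor_pair_term(self, cfg3, grids3):
        r = 1.1
        mol = Molecule(Zs=[6, 8], coords=[[0, 0, 0], [r, 0, 0]])
        vec = atomic_representation(mol, 0, cfg3, grids3)
        a_o = elements.scaling_factor(8)
        for q, (nu, t, n, m) in enumerate(feature_index_map(cfg3)):
            if nu != 2:
                continue
            grid = grids3.get(2, t, n, m, 0.6)
            expected = a_o * m_prefactor(m, 0.6) * lookup(grid, r)
            assert vec[q] == pytest.approx(expected, rel=1e-12)

    def test_three_body_needs_two_neighbors(self, cfg3, grids3):
        mol = Molecule(Zs=[6, 8], coords=[[0, 0, 0], [1.1, 0, 0]])
        vec = atomic_representation(mol, 0, cfg3, grids3)
        three_body = vec[20:]
        assert np.all(three_body == 0.0)

    def test_single_triplet_closed_form(self, cfg3, grids3):
        mol = Molecule(
            Zs=[6, 1, 1], coords=[[0, 0, 0], [1.0, 0, 0], [0, 1.2, 0]]
        )
        env = build_environment(mol, 0, cfg3)
        vec = atomic_representation(mol, 0, cfg3, grids3)
        rjk = math.hypot(1.0, 1.2)
        f = 1.0 / (1.0 * 1.2 * rjk) ** 2
        a3 = elements.scaling_factor(1)
        for q, (nu, t, n, m) in enumerate(feature_index_map(cfg3)):
            if nu != 3:
                continue
            grid = grids3.get(3, t, n, m, cfg3.sigma_ang)
            expected = (
                a3 * f * m_prefactor(m, cfg3.sigma_ang) * lookup(grid, math.pi / 2)
            )
            assert vec[q] == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_four_body_needs_three_neighbors(self, cfg4, grids4):
        mol = Molecule(Zs=[6, 1, 1], coords=[[0, 0, 0], [1.0, 0, 0], [0, 1.2, 0]])
        vec = atomic_representation(mol, 0, cfg4, grids4)
        assert np.all(vec[40:] == 0.0)


class TestOracleEquivalence:
    def test_grid_path_matches_quadrature(self, cfg4, grids4):
        mols = random_molecules(
            FixtureSpec(n_molecules=3, atoms_min=5, atoms_max=6, box=5.0, seed=21)
        )
        for mol in mols:
            env = build_environment(mol, 0, cfg4)
            vec = atomic_representation(mol, 0, cfg4, grids4)
            for q, (nu, t, n, m) in enumerate(feature_index_map(cfg4)):
                ref = quadrature_functional(env, nu, t, n, m, cfg4)
                assert vec[q] == pytest.approx(ref, rel=1e-3, abs=1e-10)


class TestInvariances:
    def test_translation(self, cfg3, grids3, rng):
        mols = random_molecules(
            FixtureSpec(n_molecules=3, atoms_min=3, atoms_max=8, box=5.0, seed=4)
        )
        for mol in mols:
            v = representation(mol, cfg3, grids3).values
            shifted = Molecule(mol.Zs, mol.coords + rng.normal(size=3) * 5)
            v2 = representation(shifted, cfg3, grids3).values
            np.testing.assert_allclose(v2, v, rtol=1e-12, atol=1e-12)

    def test_rotation(self, cfg4, grids4, rng):
        mols = random_molecules(
            FixtureSpec(n_molecules=3, atoms_min=3, atoms_max=8, box=5.0, seed=5)
        )
        for mol in mols:
            v = representation(mol, cfg4, grids4).values
            rotated = Molecule(mol.Zs, mol.coords @ rotation_matrix(rng).T)
            v2 = representation(rotated, cfg4, grids4).values
            scale = max(np.abs(v).max(), 1.0)
            assert np.abs(v2 - v).max() <= 1e-10 * scale

    def test_permutation(self, cfg3, grids3, rng):
        mol = random_molecules(
            FixtureSpec(n_molecules=1, atoms_min=7, atoms_max=7, box=5.0, seed=6)
        )[0]
        v = representation(mol, cfg3, grids3).values
        perm = rng.permutation(mol.n_atoms)
        v2 = representation(
            Molecule(mol.Zs[perm], mol.coords[perm]), cfg3, grids3
        ).values
        np.testing.assert_allclose(v2, v[perm], rtol=1e-12, atol=1e-13)

    def test_size_invariance_across_compositions(self, cfg3, grids3):
        mols = random_molecules(
            FixtureSpec(n_molecules=8, atoms_min=2, atoms_max=12, box=6.0, seed=7)
        )
        mols.append(Molecule(Zs=[1], coords=[[0, 0, 0]]))
        lengths = {representation(m, cfg3, grids3).values.shape[1] for m in mols}
        assert lengths == {40}

    def test_locality_beyond_cutoff_is_exact(self, cfg3, grids3):
        near = np.array([[0, 0, 0], [1.2, 0, 0], [0, 1.4, 0.3]])
        far = np.array([[30.0, 0, 0]])
        mol_a = Molecule([6, 8, 1, 17], np.vstack([near, far]))
        mol_b = Molecule([6, 8, 1, 17], np.vstack([near, far + 0.7]))
        for i in range(3):
            va = atomic_representation(mol_a, i, cfg3, grids3)
            vb = atomic_representation(mol_b, i, cfg3, grids3)
            assert np.array_equal(va, vb)


class TestGlobalRepresentation:
    def test_sum_mode_equals_column_sums(self, cfg3, grids3):
        mol = random_molecules(
            FixtureSpec(n_molecules=1, atoms_min=5, atoms_max=5, box=5.0, seed=8)
        )[0]
        fm = representation(mol, cfg3, grids3)
        np.testing.assert_allclose(
            molecular_representation(mol, cfg3, grids3, "sum"),
            fm.values.sum(axis=0),
        )

    def test_one_atom_molecule_sums_to_zero(self, cfg3, grids3):
        mol = Molecule(Zs=[6], coords=[[0, 0, 0]])
        assert np.all(molecular_representation(mol, cfg3, grids3, "sum") == 0.0)

    def test_element_bag_layout_and_errors(self, grids3):
        cfg = CmbdfConfig(element_list=(1, 6, 8))
        mol = Molecule(Zs=[6, 1], coords=[[0, 0, 0], [1.1, 0, 0]])
        bag = molecular_representation(mol, cfg, grids3, "element_bag")
        assert bag.shape == (3 * 40,)
        assert np.all(bag[2 * 40 :] == 0.0)  # no oxygen present
        bad = Molecule(Zs=[7, 1], coords=[[0, 0, 0], [1.1, 0, 0]])
        with pytest.raises(ValueError, match="absent"):
            molecular_representation(bad, cfg, grids3, "element_bag")

    def test_sum_mode_invariant_under_reindexing(self, cfg3, grids3, rng):
        mol = random_molecules(
            FixtureSpec(n_molecules=1, atoms_min=6, atoms_max=6, box=5.0, seed=9)
        )[0]
        perm = rng.permutation(mol.n_atoms)
        g1 = molecular_representation(mol, cfg3, grids3, "sum")
        g2 = molecular_representation(
            Molecule(mol.Zs[perm], mol.coords[perm]), cfg3, grids3, "sum"
        )
        np.testing.assert_allclose(g2, g1, rtol=1e-12, atol=1e-12)


class TestPerElementSigma:
    def test_pair_block_matches_oracle_with_element_widths(self):
        sigma = {1: 0.5, 8: 0.7}
        cfg = CmbdfConfig(nu=2, m_max=2, n_max=1, sigma=sigma)
        grids = cfg.build_grids()
        mol = Molecule(Zs=[8, 1, 1], coords=[[0, 0, 0], [0.96, 0, 0], [-0.3, 0.93, 0]])
        env = build_environment(mol, 0, cfg)
        vec = atomic_representation(mol, 0, cfg, grids)
        for q, (nu, t, n, m) in enumerate(feature_index_map(cfg)):
            ref = quadrature_functional(env, nu, t, n, m, cfg)
            assert vec[q] == pytest.approx(ref, rel=1e-3, abs=1e-10)
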