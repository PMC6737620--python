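import math

import numpy as np
import pytest

import oracles
from conftest import permute_record
from hbstrength.descriptors import (
    DescriptorInapplicableError,
    DescriptorSpec,
    charge_shell,
    combine_blocks,
    compute_block,
    descriptor_matrix,
    empirical_charges,
    mass_shell,
    sorted_shell,
    spatial_cacf,
    spatial_rdf,
    topo_cacf,
    topological_shells,
)
from hbstrength.molio import MoleculeRecord

ATOMIC_WEIGHTS = {"C": 12.011, "O": 15.999, "H": 1.008, "N": 14.007}


def chain(charges, coords=None):
    n = len(charges)
    return MoleculeRecord(
        atoms=[("C", 0, 0)] * n,
        bonds=[((i, i + 1), 1) for i in range(n - 1)],
        atom_charges=list(charges),
        coords3d=coords,
    )


class TestShells:
    def test_linear_chain(self):
        mol = chain([0.0, 0.0, 0.0])
        assert topological_shells(mol, 0, 2) == [[1], [2]]

    def test_trailing_empty_shells(self):
        mol = chain([0.0, 0.0])
        assert topological_shells(mol, 0, 4) == [[1], [], [], []]

    def test_benzene_first_shell_includes_hydrogen(self):
        mol = MoleculeRecord.from_smiles("c1ccccc1")
        shells = topological_shells(mol, 0, 1)
        symbols = sorted(mol.atoms[i][0] for i in shells[0])
        assert symbols == ["C", "C", "H"]


class TestChargeShell:
    def test_single_atom_shells(self):
        mol = chain([0.2, -0.1, 0.3])
        np.testing.assert_allclose(
            charge_shell(mol, 0, DescriptorSpec("CS", n_shells=2)), [-0.1, 0.3]
        )

    def test_mean_over_shell(self):
        mol = MoleculeRecord(
            atoms=[("C", 0, 0)] * 3,
            bonds=[((0, 1), 1), ((0, 2), 1)],
            atom_charges=[0.0, 0.1, -0.3],
        )
        np.testing.assert_allclose(
            charge_shell(mol, 0, DescriptorSpec("CS", n_shells=1)), [-0.1]
        )

    def test_empty_shell_strict_error(self):
        mol = chain([0.2, -0.1, 0.3])
        with pytest.raises(DescriptorInapplicableError):
            charge_shell(mol, 0, DescriptorSpec("CS", n_shells=3))

    def test_empty_shell_zero_fill(self):
        mol = chain([0.2, -0.1, 0.3])
        out = charge_shell(mol, 0, DescriptorSpec("CS", n_shells=3, zero_fill=True))
        np.testing.assert_allclose(out, [-0.1, 0.3, 0.0])


class TestSortedShell:
    def test_padding(self):
        mol = chain([0.0, -0.1])
        out = sorted_shell(mol, 0, DescriptorSpec("sorted_shell", n_shells=1, shell_width=2))
        np.testing.assert_allclose(out, [-0.1, 0.0])

    def test_oxygen_outranks_hydrogen(self):
        mol = MoleculeRecord(
            atoms=[("C", 0, 0), ("H", 0, 0), ("O", 0, 1)],
            bonds=[((0, 1), 1), ((0, 2), 1)],
            atom_charges=[0.0, 0.1, -0.4],
        )
        out = sorted_shell(mol, 0, DescriptorSpec("sorted_shell", n_shells=1, shell_width=2))
        np.testing.assert_allclose(out, [-0.4, 0.1])

    def test_recursive_priority_breaks_element_ties(self):
        # center bonded to two carbons; one carries an O, the other only H
        mol = MoleculeRecord(
            atoms=[("C", 0, 3), ("C", 0, 2), ("C", 0, 3), ("O", 0, 1)],
            bonds=[((0, 1), 1), ((0, 2), 1), ((1, 3), 1)],
            atom_charges=[0.0, 0.2, -0.2, -0.4],
        )
        out = sorted_shell(mol, 0, DescriptorSpec("sorted_shell", n_shells=1, shell_width=2))
        np.testing.assert_allclose(out, [0.2, -0.2])  # O-bearing carbon first

    def test_permutation_invariance(self, charged_graphs):
        rng = np.random.default_rng(1)
        spec = DescriptorSpec("sorted_shell", n_shells=3, shell_width=3)
        for mol in charged_graphs[:15]:
            perm = list(rng.permutation(mol.num_atoms()))
            permuted = permute_record(mol, perm)
            np.testing.assert_allclose(
                sorted_shell(mol, 0, spec), sorted_shell(permuted, perm[0], spec)
            )


class TestMassShell:
    def test_values(self):
        mol = MoleculeRecord(
            atoms=[("C", 0, 0), ("C", 0, 0), ("O", 0, 0)],
            bonds=[((0, 1), 1), ((0, 2), 1)],
        )
        np.testing.assert_allclose(
            mass_shell(mol, 0, DescriptorSpec("MS", n_shells=2)), [28.010, 0.0]
        )

    def test_methane(self):
        mol = MoleculeRecord.from_smiles("C")
        np.testing.assert_allclose(
            mass_shell(mol, 0, DescriptorSpec("MS", n_shells=1)), [4 * 1.008]
        )


class TestSpatial:
    def test_rdf_single_neighbor_on_grid_point(self):
        mol = chain([0.0, -0.1], coords=[(0, 0, 0), (1.0, 0, 0)])
        spec = DescriptorSpec("CRDF", r_min=1.0, r_max=2.0, r_step=1.0, beta=4.0)
        out = spatial_rdf(mol, 0, spec)
        assert out[0] == pytest.approx(-0.1, abs=1e-3)

    def test_rdf_zero_charges(self):
        mol = chain([0.0, 0.0, 0.0], coords=[(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        out = spatial_rdf(mol, 0, DescriptorSpec("CRDF"))
        np.testing.assert_allclose(out, 0.0)

    def test_cacf_sign_split(self):
        mol = chain([0.2, -0.1], coords=[(0, 0, 0), (1.0, 0, 0)])
        spec = DescriptorSpec("CACF", r_min=1.0, r_max=2.0, r_step=1.0, beta=4.0)
        out = spatial_cacf(mol, 0, spec)
        glen = len(spec.grid())
        np.testing.assert_allclose(out[:glen], 0.0)
        assert out[glen] == pytest.approx(-0.02, abs=1e-3)

    def test_cacf_zero_center(self):
        mol = chain([0.0, -0.1, 0.2], coords=[(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        np.testing.assert_allclose(spatial_cacf(mol, 0, DescriptorSpec("CACF")), 0.0)

    def test_missing_coordinates_error(self):
        mol = chain([0.1, -0.1])
        with pytest.raises(ValueError, match="coordinates"):
            spatial_rdf(mol, 0, DescriptorSpec("CRDF"))

    def test_beta_limit_recovers_charge(self):
        """With beta -> inf, a grid point exactly at the neighbor distance
        picks out that neighbor's charge."""
        mol = chain([0.0, -0.35], coords=[(0, 0, 0), (1.5, 0, 0)])
        spec = DescriptorSpec("CRDF", r_min=1.0, r_max=2.0, r_step=0.5, beta=1e6)
        out = spatial_rdf(mol, 0, spec)
        assert out[1] == pytest.approx(-0.35, abs=1e-6)
        np.testing.assert_allclose(out[[0, 2]], 0.0, atol=1e-6)


class TestAgainstOracles:
    """Every family equals its direct-summation brute-force oracle."""

    def test_topological_families(self, charged_graphs):
        for mol in charged_graphs:
            K = 4
            cs = oracles.charge_shell_oracle(mol, 0, K)
            if cs is not None:
                np.testing.assert_allclose(
                    charge_shell(mol, 0, DescriptorSpec("CS", n_shells=K)), cs,
                    atol=1e-12,
                )
            np.testing.assert_allclose(
                mass_shell(mol, 0, DescriptorSpec("MS", n_shells=K)),
                oracles.mass_shell_oracle(mol, 0, K, {"C": 12.011}),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                topo_cacf(mol, 0, DescriptorSpec("GACF", n_shells=K)),
                oracles.gacf_oracle(mol, 0, K),
                atol=1e-12,
            )

    def test_spatial_families(self, charged_graphs):
        spec = DescriptorSpec("CRDF", r_min=1.0, r_max=4.0, r_step=0.75, beta=2.5)
        cspec = DescriptorSpec("CACF", r_min=1.0, r_max=4.0, r_step=0.75, beta=2.5)
        for mol in charged_graphs:
            grid = list(spec.grid())
            np.testing.assert_allclose(
                spatial_rdf(mol, 0, spec),
                oracles.crdf_oracle(mol, 0, grid, 2.5),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                spatial_cacf(mol, 0, cspec),
                oracles.cacf_oracle(mol, 0, grid, 2.5),
                atol=1e-12,
            )


class TestInvariances:
    def test_rigid_motion(self, charged_graphs):
        """Spatial blocks depend only on interatomic distances."""
        rng = np.random.default_rng(9)
        spec_r = DescriptorSpec("CRDF")
        spec_c = DescriptorSpec("CACF")
        for mol in charged_graphs[:10]:
            # random rotation via QR, random translation
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            t = rng.normal(0, 5, 3)
            moved = MoleculeRecord(
                atoms=mol.atoms,
                bonds=mol.bonds,
                coords3d=[tuple(Q @ np.array(c) + t) for c in mol.coords3d],
                atom_charges=mol.atom_charges,
            )
            for spec, fn in ((spec_r, spatial_rdf), (spec_c, spatial_cacf)):
                np.testing.assert_allclose(
                    fn(mol, 0, spec), fn(moved, 0, spec), atol=1e-9
                )

    def test_permutation(self, charged_graphs):
        rng = np.random.default_rng(11)
        specs = [
            DescriptorSpec("CS", n_shells=2, zero_fill=True),
            DescriptorSpec("MS", n_shells=3),
            DescriptorSpec("GACF", n_shells=3),
            DescriptorSpec("CRDF"),
            DescriptorSpec("CACF"),
        ]
        for mol in charged_graphs[:10]:
            perm = list(rng.permutation(mol.num_atoms()))
            permuted = permute_record(mol, perm)
            for spec in specs:
                np.testing.assert_allclose(
                    compute_block(mol, 2, spec),
                    compute_block(permuted, perm[2], spec),
                    atol=1e-12,
                )


class TestCombine:
    def test_concatenation_and_layout(self):
        mol = chain([0.2, -0.1, 0.3])
        specs = [DescriptorSpec("CS", n_shells=2), DescriptorSpec("MS", n_shells=2)]
        vec = combine_blocks(mol, 0, specs)
        np.testing.assert_allclose(vec.values, [-0.1, 0.3, 12.011, 12.011])
        assert vec.block_layout == [("CS", 0, 2), ("MS", 2, 2)]
        np.testing.assert_allclose(vec.block(0), [-0.1, 0.3])
        np.testing.assert_allclose(vec.block(1), [12.011, 12.011])

    def test_empty_specs_error(self):
        mol = chain([0.0, 0.0])
        with pytest.raises(ValueError):
            combine_blocks(mol, 0, [])

    def test_strict_failure_propagates(self):
        mol = chain([0.2, -0.1, 0.3])
        specs = [DescriptorSpec("MS", n_shells=4), DescriptorSpec("CS", n_shells=4)]
        with pytest.raises(DescriptorInapplicableError):
            combine_blocks(mol, 0, specs)

    def test_dimensionality_is_function_of_specs_only(self, charged_graphs):
        specs = [
            DescriptorSpec("MS", n_shells=3),
            DescriptorSpec("GACF", n_shells=2),
            DescriptorSpec("CRDF", r_min=1, r_max=3, r_step=0.5),
        ]
        expected = sum(s.block_length() for s in specs)
        for mol in charged_graphs[:5]:
            assert len(combine_blocks(mol, 0, specs).values) == expected

    def test_matrix_drops_inapplicable_rows(self):
        short = chain([0.1, -0.1])
        long = chain([0.1, -0.1, 0.2, 0.3])
        specs = [DescriptorSpec("CS", n_shells=3)]
        frame, dropped = descriptor_matrix(
            [(long, 0), (short, 0)], specs, strict=False
        )
        assert dropped == [1]
        assert list(frame.index) == [0]
        with pytest.raises(DescriptorInapplicableError):
            descriptor_matrix([(short, 0)], specs, strict=True)


def test_empirical_charges_conserve_charge(toy_molecules):
    for mol in toy_molecules[:20]:
        assert abs(empirical_charges(mol).sum()) < 1e-9


def test_spec_validation():
    with pytest.raises(ValueError):
        DescriptorSpec("CS", n_shells=0)
    with pytest.raises(ValueError):
        DescriptorSpec("CRDF", r_min=5.0, r_max=1.0)
    with pytest.raises(ValueError):
        DescriptorSpec("nope")
    assert len(DescriptorSpec("CRDF").grid()) == 15  # 1.0 .. 8.0 by 0.5
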