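import numpy as np
import pytest

from gridqsar.fields import (
    DescriptorBlock,
    GridSpec,
    ProbeSpec,
    assemble_descriptor_matrix,
    build_grid,
    column_filter,
    comfa_electrostatic,
    comfa_steric,
    comsia_field,
)
from tests.conftest import make_molecule


def single_atom(element="C", xyz=(0.0, 0.0, 0.0), charge=0.0):
    return make_molecule([element], [xyz], charges=[charge])


class TestBuildGrid:
    def test_single_atom_margin_four(self):
        grid = build_grid([single_atom()], spacing=2.0, margin=4.0)
        assert grid.dims == (5, 5, 5)
        assert grid.origin == (-4.0, -4.0, -4.0)

    def test_zero_margin_single_atom(self):
        grid = build_grid([single_atom(xyz=(1.0, 2.0, 3.0))], spacing=2.0, margin=0.0)
        assert grid.dims == (1, 1, 1)
        assert grid.origin == (1.0, 2.0, 3.0)

    def test_invariant_to_molecule_order(self):
        mols = [single_atom(xyz=(0, 0, 0)), single_atom(xyz=(3, 1, -2)), single_atom(xyz=(-1, 4, 2))]
        assert build_grid(mols) == build_grid(mols[::-1])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_grid([])


class TestComfaSteric:
    def test_far_field_decays(self):
        grid = GridSpec(origin=(100.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        vals = comfa_steric(single_atom(), grid)
        assert abs(vals[0]) < 1e-6

    def test_point_at_atom_center_clamped_to_cap(self):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        vals = comfa_steric(single_atom(), grid)
        assert vals[0] == pytest.approx(30.0)

    def test_lj_minimum_matches_closed_form(self):
        mol = single_atom("C")
        probe = ProbeSpec()
        rmin = mol.vdw_radius[0] + probe.vdw_radius
        grid = GridSpec(origin=(rmin, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        expected = -np.sqrt(mol.lj_epsilon[0] * probe.lj_epsilon)
        assert comfa_steric(mol, grid)[0] == pytest.approx(expected, rel=1e-9)

    def test_values_within_cap(self, planted_dataset):
        grid = planted_dataset["grid"]
        for mol in planted_dataset["molecules"][:5]:
            vals = comfa_steric(mol, grid)
            assert vals.min() >= -30.0 and vals.max() <= 30.0


class TestComfaElectrostatic:
    def test_zero_charges_give_zero_field(self):
        grid = GridSpec(origin=(-2.0, -2.0, -2.0), spacing=2.0, dims=(3, 3, 3))
        assert (comfa_electrostatic(single_atom(charge=0.0), grid) == 0).all()

    def test_opposite_charges_cancel_at_midpoint(self):
        mol = make_molecule(
            ["C", "C"], [(-1.0, 0.0, 0.0), (1.0, 0.0, 0.0)], charges=[0.5, -0.5]
        )
        grid = GridSpec(origin=(0.0, 0.0, 2.0), spacing=1.0, dims=(1, 1, 1))
        assert comfa_electrostatic(mol, grid)[0] == pytest.approx(0.0, abs=1e-12)

    def test_distance_dielectric_closed_form(self):
        mol = single_atom(charge=0.5)
        grid = GridSpec(origin=(4.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        expected = 332.0636 * 0.5 / 16.0
        assert comfa_electrostatic(mol, grid)[0] == pytest.approx(expected, abs=1e-3)


class TestComsiaField:
    def test_zero_distance_unit_weight(self):
        mol = make_molecule(["C"], [(0.0, 0.0, 0.0)])
        mol.hydrophobic_weight[:] = 1.0
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        assert comsia_field(mol, grid, "H")[0] == pytest.approx(-1.0)

    def test_gaussian_attenuation_at_unit_distance(self):
        mol = make_molecule(["C"], [(0.0, 0.0, 0.0)])
        mol.hydrophobic_weight[:] = 1.0
        grid = GridSpec(origin=(1.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        assert comsia_field(mol, grid, "H", alpha=0.3)[0] == pytest.approx(
            -np.exp(-0.3), rel=1e-12
        )

    def test_no_donors_gives_zero_donor_field(self):
        mol = make_molecule(["C", "O"], [(0, 0, 0), (1.5, 0, 0)])
        grid = GridSpec(origin=(-1.0, 0.0, 0.0), spacing=1.0, dims=(4, 1, 1))
        assert (comsia_field(mol, grid, "D") == 0).all()

    def test_unknown_kind_rejected(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(1, 1, 1))
        with pytest.raises(ValueError):
            comsia_field(single_atom(), grid, "X")

    def test_nonpositive_when_weights_nonnegative(self):
        mol = make_molecule(["C", "S"], [(0, 0, 0), (2, 0, 0)])
        grid = GridSpec(origin=(-2.0, -2.0, 0.0), spacing=1.0, dims=(5, 5, 1))
        assert (comsia_field(mol, grid, "S") <= 0).all()


class TestAssembly:
    def test_comfa_shape_and_ordering(self):
        mols = [single_atom(xyz=(0, 0, 0)), single_atom(xyz=(1, 0, 0))]
        grid = GridSpec(origin=(-1.0, -1.0, -1.0), spacing=2.0, dims=(2, 2, 2))
        block = assemble_descriptor_matrix(mols, grid, kinds=("S", "E"), scheme="comfa")
        assert block.matrix.shape == (2, 16)
        assert list(block.column_meta["kind"][:8]) == ["S"] * 8
        assert list(block.column_meta["point"][:8]) == list(range(8))

    def test_comsia_four_kinds_tagged(self):
        mols = [single_atom()]
        grid = GridSpec(origin=(-2.0, 0.0, 0.0), spacing=1.0, dims=(10, 1, 1))
        block = assemble_descriptor_matrix(
            mols, grid, kinds=("S", "E", "H", "D"), scheme="comsia"
        )
        assert block.matrix.shape == (1, 40)
        assert block.column_meta["kind"].value_counts().to_dict() == {
            "S": 10, "E": 10, "H": 10, "D": 10
        }

    def test_duplicate_molecules_give_identical_rows(self):
        mol = single_atom(charge=0.3)
        grid = GridSpec(origin=(-2.0, -2.0, -2.0), spacing=2.0, dims=(3, 3, 3))
        block = assemble_descriptor_matrix([mol, mol], grid, kinds=("S", "E"), scheme="comfa")
        np.testing.assert_array_equal(block.matrix[0], block.matrix[1])

    def test_comfa_rejects_similarity_kinds(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(1, 1, 1))
        with pytest.raises(ValueError):
            assemble_descriptor_matrix([single_atom()], grid, kinds=("S", "H"), scheme="comfa")

    def test_atom_order_invariance(self):
        coords = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (0.0, 1.5, 0.0)]
        charges = [0.2, -0.5, 0.3]
        mol_a = make_molecule(["C", "N", "O"], coords, charges)
        mol_b = make_molecule(["O", "C", "N"], [coords[2], coords[0], coords[1]], [0.3, 0.2, -0.5])
        grid = GridSpec(origin=(-3.0, -3.0, -3.0), spacing=2.0, dims=(4, 4, 4))
        for scheme, kinds in (("comfa", ("S", "E")), ("comsia", ("S", "E", "H"))):
            a = assemble_descriptor_matrix([mol_a], grid, kinds=kinds, scheme=scheme)
            b = assemble_descriptor_matrix([mol_b], grid, kinds=kinds, scheme=scheme)
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_translation_invariance(self):
        mol = make_molecule(["C", "N"], [(0, 0, 0), (1.5, 0.5, -0.5)], [0.25, -0.25])
        shift = np.array([7.3, -2.1, 4.4])
        grid = GridSpec(origin=(-3.0, -3.0, -3.0), spacing=2.0, dims=(4, 4, 4))
        grid_shifted = GridSpec(
            origin=tuple(np.array(grid.origin) + shift), spacing=2.0, dims=(4, 4, 4)
        )
        mol_shifted = mol.translated(shift)
        for fn in (comfa_steric, comfa_electrostatic):
            np.testing.assert_allclose(
                fn(mol, grid), fn(mol_shifted, grid_shifted), atol=1e-9
            )
        np.testing.assert_allclose(
            comsia_field(mol, grid, "E"),
            comsia_field(mol_shifted, grid_shifted, "E"),
            atol=1e-9,
        )

    def test_additivity_over_atoms(self):
        frag_a = make_molecule(["C"], [(0.0, 0.0, 0.0)], [0.3])
        frag_b = make_molecule(["N"], [(4.0, 0.0, 0.0)], [-0.3])
        both = make_molecule(["C", "N"], [(0, 0, 0), (4.0, 0.0, 0.0)], [0.3, -0.3])
        grid = GridSpec(origin=(-2.0, -2.0, -2.0), spacing=2.0, dims=(5, 3, 3))
        # uncapped comparison: use a cap large enough not to clip
        s = comfa_steric(frag_a, grid, cap=1e9) + comfa_steric(frag_b, grid, cap=1e9)
        np.testing.assert_allclose(s, comfa_steric(both, grid, cap=1e9), rtol=1e-9)
        e = comfa_electrostatic(frag_a, grid, cap=1e9) + comfa_electrostatic(frag_b, grid, cap=1e9)
        np.testing.assert_allclose(e, comfa_electrostatic(both, grid, cap=1e9), rtol=1e-9)
        h = comsia_field(frag_a, grid, "H") + comsia_field(frag_b, grid, "H")
        np.testing.assert_allclose(h, comsia_field(both, grid, "H"), rtol=1e-9)


class TestColumnFilter:
    @staticmethod
    def _block(matrix, kinds=None):
        import pandas as pd

        matrix = np.asarray(matrix, dtype=float)
        n_cols = matrix.shape[1]
        meta = pd.DataFrame(
            {"kind": kinds or ["S"] * n_cols, "point": list(range(n_cols))}
        )
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(n_cols, 1, 1))
        return DescriptorBlock(
            matrix=matrix, column_meta=meta, grid=grid, scheme="comfa",
            molecule_ids=[f"m{i}" for i in range(matrix.shape[0])],
        )

    def test_constant_column_dropped(self):
        block = self._block([[1.0, 5.0], [1.0, -5.0], [1.0, 0.0]])
        out = column_filter(block, min_sigma=2.0)
        assert list(out.kept_mask) == [False, True]

    def test_column_at_sd_2_5_kept_at_threshold_2(self):
        col = np.array([-2.5, 0.0, 2.5, -2.5, 2.5])
        col = col / col.std(ddof=1) * 2.5
        block = self._block(col[:, None])
        out = column_filter(block, min_sigma=2.0)
        assert out.kept_mask[0]

    def test_zero_threshold_keeps_varying_columns(self):
        block = self._block([[1.0, 2.0], [1.5, -2.0]])
        out = column_filter(block, min_sigma=0.0)
        assert out.kept_mask.all()

    def test_all_dropped_raises_with_advice(self):
        block = self._block([[0.1], [0.2]])
        with pytest.raises(ValueError, match="lower the threshold"):
            column_filter(block, min_sigma=2.0)

    def test_cap_touched_columns_excluded(self):
        mat = np.array([[30.0, 5.0], [-10.0, -5.0], [0.0, 0.0]])
        out = column_filter(self._block(mat), min_sigma=2.0)
        assert list(out.kept_mask) == [False, True]
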