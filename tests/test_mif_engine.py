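"""Molecular interaction fields: radial/angular terms, grids, isovolumes, cube I/O."""

import numpy as np
import pytest

from dynhb.calibration import MapStore, fit_linear_map
from dynhb.core_chem import ACCEPTOR, mol_from_smiles
from dynhb.errors import InputError, ParameterError
from dynhb.mif_engine import (GridSpec, HBGeometry, build_grid, compute_mif,
                              export_cube, hb_angular, hb_radial, isovolume,
                              load_probes, read_cube, resolve_demin)
from dynhb.registry import static_emin


class TestHBRadial:
    def test_minimum_exactly_at_rmin(self):
        assert hb_radial(1.6, -5.5, 1.6) == pytest.approx(-5.5, abs=1e-12)

    def test_double_rmin_closed_form(self):
        # 3/16 - 2/64 = 0.15625
        assert hb_radial(3.2, -5.5, 1.6) == pytest.approx(-5.5 * 0.15625)
        assert hb_radial(3.2, -5.5, 1.6) == pytest.approx(-0.859375)

    def test_long_range_decay(self):
        assert abs(hb_radial(16.0, -5.5, 1.6)) < 0.01 * 5.5

    def test_short_range_repulsion_capped(self):
        assert hb_radial(0.2, -5.5, 1.6) == pytest.approx(5.0)

    def test_rmin_is_the_global_minimum(self):
        r = np.linspace(0.5, 10.0, 2000)
        er = hb_radial(r, -5.5, 1.6)
        assert er.min() >= -5.5 - 1e-9
        assert abs(r[np.argmin(er)] - 1.6) < 0.01

    @pytest.mark.parametrize("emin, rmin", [(+1.0, 1.6), (-5.5, -1.0)])
    def test_non_physical_parameters_rejected(self, emin, rmin):
        with pytest.raises(ParameterError):
            hb_radial(1.6, emin, rmin)


class TestHBAngular:
    @pytest.mark.parametrize("t, expected", [
        (0.0, 1.0),       # head-on: strongest possible hydrogen bond
        (60.0, 0.25),     # cos^2 60
        (90.0, 0.0),
        (135.0, 0.0),     # beyond 90 degrees: cut off
    ])
    def test_values(self, t, expected):
        assert hb_angular(HBGeometry(r=2.8, t=t)) == pytest.approx(expected, abs=1e-12)

    def test_range_and_monotone_falloff(self):
        ts = np.linspace(0, 180, 91)
        vals = [hb_angular(HBGeometry(r=2.8, t=t)) for t in ts]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestGrid:
    def test_single_atom_box(self):
        mol = mol_from_smiles("[Ne]")
        spec = build_grid(mol, spacing=0.5, padding=4.0)
        assert spec.dims == (17, 17, 17)

    def test_padding_monotonicity(self):
        mol = mol_from_smiles("c1ccncc1")
        small = build_grid(mol, padding=3.0)
        large = build_grid(mol, padding=6.0)
        assert all(b > a for a, b in zip(small.dims, large.dims))

    def test_translation_equivariance(self, fixture_set):
        byname, _ = fixture_set
        mol = byname["furan"]
        spec = build_grid(mol)
        import copy
        shifted = copy.deepcopy(mol)
        conf = shifted.rdmol.GetConformer()
        for i in range(shifted.rdmol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (p.x + 5.0, p.y - 2.0, p.z + 1.0))
        from dynhb.core_chem import Molecule
        shifted = Molecule.from_rdkit(shifted.rdmol, name="shifted")
        spec2 = build_grid(shifted)
        assert spec2.dims == spec.dims
        np.testing.assert_allclose(np.array(spec2.origin) - np.array(spec.origin),
                                   [5.0, -2.0, 1.0], atol=1e-9)

    def test_bad_parameters_rejected(self):
        with pytest.raises(InputError):
            GridSpec((0, 0, 0), -0.5, (3, 3, 3))
        with pytest.raises(InputError):
            GridSpec((0, 0, 0), 0.5, (0, 3, 3))


@pytest.fixture(scope="module")
def probes():
    return load_probes()


class TestComputeMIF:
    def test_no_complementary_atoms_means_zero_hb(self, fixture_set,
                                                  typed_fixtures, probes):
        byname, _ = fixture_set
        mol = byname["benzene"]
        grid = compute_mif(mol, typed_fixtures["benzene"], "static",
                           probes["N1"], build_grid(mol))
        assert np.all(grid.components["E_HB"] == 0.0)

    def test_single_acceptor_well_depth_and_position(self, fixture_set,
                                                     typed_fixtures, probes):
        """Donor probe against pyridine's lone acceptor: the HB component
        minimum sits within 5% of dEmin, near Rmin along the lone-pair axis."""
        byname, _ = fixture_set
        mol = byname["pyridine"]
        typing = typed_fixtures["pyridine"]
        spec = build_grid(mol, spacing=0.25)
        grid = compute_mif(mol, typing, "static", probes["N1"], spec)
        hb = grid.components["E_HB"]
        demin = static_emin("N:=")
        assert hb.min() == pytest.approx(demin, rel=0.05)
        n_idx = next(a.atom_index for a in typing if a.at_code == "N:=")
        n_pos = np.array(mol.atoms[n_idx].coords)
        min_pt = spec.points()[np.argmin(hb)]
        rmin = 1.6 + probes["N1"].rmin_contrib
        assert np.linalg.norm(min_pt - n_pos) == pytest.approx(rmin, abs=0.3)

    def test_field_scales_with_well_depth_on_attractive_branch(
            self, fixture_set, typed_fixtures, probes):
        byname, _ = fixture_set
        mol = byname["pyridine"]
        typing = typed_fixtures["pyridine"]
        spec = build_grid(mol)
        n_idx = next(a.atom_index for a in typing if a.at_code == "N:=")
        shallow = compute_mif(mol, typing, {n_idx: -4.0}, probes["N1"], spec)
        deep = compute_mif(mol, typing, {n_idx: -8.0}, probes["N1"], spec)
        attractive = shallow.components["E_HB"] < 0
        assert np.all(deep.components["E_HB"][attractive]
                      <= shallow.components["E_HB"][attractive])

    def test_static_and_dynamic_agree_when_demin_is_static(
            self, fixture_set, typed_fixtures, probes):
        byname, _ = fixture_set
        mol = byname["pyridine"]
        typing = typed_fixtures["pyridine"]
        spec = build_grid(mol)
        explicit = {a.atom_index: static_emin(a.at_code)
                    for a in typing if ACCEPTOR in a.roles}
        g_static = compute_mif(mol, typing, "static", probes["N1"], spec)
        g_dynamic = compute_mif(mol, typing, explicit, probes["N1"], spec)
        assert np.array_equal(g_static.total, g_dynamic.total)

    def test_total_is_sum_of_components(self, fixture_set, typed_fixtures,
                                        probes):
        byname, charge_sets = fixture_set
        mol = byname["aminopyridine"]
        grid = compute_mif(mol, typed_fixtures["aminopyridine"], "static",
                           probes["N1"], build_grid(mol),
                           charges=charge_sets["aminopyridine"])
        np.testing.assert_array_equal(
            grid.total, sum(grid.components.values()))
        assert np.all(np.isfinite(grid.total))
        assert grid.total.max() <= 5.0 + 1e-9

    def test_rigid_motion_leaves_isovolume_unchanged(self, typed_fixtures,
                                                     probes):
        from rdkit.Chem import rdMolTransforms
        from dynhb.core_chem import Molecule, assign_atom_types
        mol = mol_from_smiles("c1ccncc1", name="pyr")
        g1 = compute_mif(mol, assign_atom_types(mol), "static", probes["N1"],
                         build_grid(mol))
        c1 = isovolume(g1, -3.0)
        theta = np.radians(33.0)
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0, 2.0],
            [np.sin(theta), np.cos(theta), 0, -1.0],
            [0, 0, 1, 4.0],
            [0, 0, 0, 1.0]])
        rdMolTransforms.TransformConformer(mol.rdmol.GetConformer(), rot)
        moved = Molecule.from_rdkit(mol.rdmol, name="moved")
        g2 = compute_mif(moved, assign_atom_types(moved), "static",
                         probes["N1"], build_grid(moved))
        c2 = isovolume(g2, -3.0)
        # grid discretization shifts a few boundary points, not the volume scale
        assert c2[0] == pytest.approx(c1[0], rel=0.1)

    def test_dynamic_path_resolves_demin_through_maps(self, fixture_set,
                                                      typed_fixtures,
                                                      fixture_eps):
        byname, _ = fixture_set
        typing = typed_fixtures["pyridine"]
        eps = fixture_eps["pyridine"]
        lm = fit_linear_map(np.linspace(-0.1, 0.1, 50), "N:=", ACCEPTOR, -5.5)
        maps = MapStore([lm])
        demin = resolve_demin(typing, ACCEPTOR, (maps, eps))
        n_idx = next(a.atom_index for a in typing if a.at_code == "N:=")
        assert set(demin) == {n_idx}
        assert -8.25 <= demin[n_idx] <= -2.75


class TestIsovolume:
    def test_threshold_below_minimum_is_empty(self, fixture_set,
                                              typed_fixtures, probes):
        byname, _ = fixture_set
        mol = byname["pyridine"]
        grid = compute_mif(mol, typed_fixtures["pyridine"], "static",
                           probes["N1"], build_grid(mol))
        count, volume = isovolume(grid, grid.total.min() - 1.0)
        assert (count, volume) == (0, 0.0)

    def test_nesting_in_threshold(self, fixture_set, typed_fixtures, probes):
        byname, _ = fixture_set
        mol = byname["pyridine"]
        grid = compute_mif(mol, typed_fixtures["pyridine"], "static",
                           probes["N1"], build_grid(mol))
        counts = [isovolume(grid, t)[0] for t in (-5.0, -4.0, -3.0, -2.0)]
        assert counts == sorted(counts)

    def test_matches_brute_force_scan_of_analytic_well(self):
        """Isovolume of a synthetic single-well field equals an independent
        point-by-point scan of the same closed form."""
        spec = GridSpec((-4.0, -4.0, -4.0), 0.4, (21, 21, 21))
        pts = spec.points()
        r = np.linalg.norm(pts, axis=1)
        r[r < 0.05] = 0.05
        values = hb_radial(r, -5.5, 1.6)
        from dynhb.mif_engine import MIFGrid
        grid = MIFGrid(spec, values, {"E_HB": values})
        count, volume = isovolume(grid, -4.0)
        brute = sum(1 for v in values if v <= -4.0)
        assert count == brute
        assert volume == pytest.approx(brute * 0.4 ** 3)


class TestCubeExport:
    def test_roundtrip(self, tmp_path, fixture_set, typed_fixtures, probes):
        byname, _ = fixture_set
        mol = byname["furan"]
        grid = compute_mif(mol, typed_fixtures["furan"], "static",
                           probes["N1"], build_grid(mol, spacing=1.0))
        path = tmp_path / "furan.cube"
        export_cube(grid, mol, path)
        spec, values = read_cube(path)
        assert spec.dims == grid.spec.dims
        assert np.abs(values - grid.total).max() < 1e-4
        np.testing.assert_allclose(spec.origin, grid.spec.origin, atol=1e-5)

    def test_single_point_grid(self, tmp_path):
        mol = mol_from_smiles("[Ne]")
        from dynhb.mif_engine import MIFGrid
        spec = GridSpec((0.0, 0.0, 0.0), 0.5, (1, 1, 1))
        grid = MIFGrid(spec, np.array([-1.25]), {})
        path = tmp_path / "one.cube"
        export_cube(grid, mol, path)
        spec2, values = read_cube(path)
        assert spec2.dims == (1, 1, 1)
        assert values[0] == pytest.approx(-1.25, abs=1e-5)

    def test_cube_header_layout(self, tmp_path):
        """Third-party readers rely on the published layout: natoms+origin,
        three axis records, then one line per atom before the data block."""
        mol = mol_from_smiles("O")
        from dynhb.mif_engine import MIFGrid
        spec = GridSpec((0.0, 0.0, 0.0), 0.5, (2, 2, 2))
        grid = MIFGrid(spec, np.arange(8.0), {})
        path = tmp_path / "w.cube"
        export_cube(grid, mol, path)
        lines = path.read_text().splitlines()
        assert int(lines[2].split()[0]) == mol.n_atoms
        assert [int(lines[3 + k].split()[0]) for k in range(3)] == [2, 2, 2]
        atom_line = lines[6].split()
        assert int(atom_line[0]) == 8  # oxygen atomic number
        data = [float(v) for line in lines[6 + mol.n_atoms:] for v in line.split()]
        assert data == list(np.arange(8.0))
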