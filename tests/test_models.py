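"""Templates, PQR I/O, exposure, grids and effective charges."""

import math

import numpy as np
import pytest

from crowdbd.constants import COULOMB, kt
from crowdbd.models import (AtomRecord, PotentialGrid, RigidBodyTemplate,
                            PQRParseError, fit_effective_charges,
                            generate_screened_coulomb_grid, load_template,
                            read_dx_grid, read_pqr, save_template,
                            select_exposed_atoms,
                            stokes_einstein_coefficients, write_dx_grid,
                            write_pqr)


def _template(atoms):
    return RigidBodyTemplate(name="t", atoms=atoms)


# ----------------------------------------------------------------- PQR I/O

class TestPQR:
    def test_single_atom_identity(self, tmp_path):
        p = tmp_path / "one.pqr"
        p.write_text("ATOM 1 C MOL 1 0.0 0.0 0.0 1.0 1.5\n")
        t = read_pqr(p)
        assert t.n_atoms == 1
        assert t.atoms[0].charge == 1.0
        assert t.atoms[0].radius == 1.5
        np.testing.assert_allclose(t.atoms[0].position, 0.0)

    def test_hetatm_included(self, tmp_path):
        p = tmp_path / "het.pqr"
        p.write_text("ATOM 1 C MOL 1 0 0 0 0.0 1.5\n"
                     "HETATM 2 O LIG 2 3 0 0 -0.5 1.4\n")
        t = read_pqr(p)
        assert t.n_atoms == 2
        assert t.atoms[1].charge == -0.5

    def test_roundtrip_3_decimals(self, tmp_path):
        rng = np.random.default_rng(0)
        atoms = [AtomRecord(f"C{i}", rng.uniform(-10, 10, 3),
                            radius=rng.uniform(1, 3),
                            charge=rng.uniform(-1, 1)) for i in range(20)]
        t = _template(atoms)
        # recentre so the read-back (which recentres) is comparable
        centre = t.positions.mean(axis=0)
        for a in t.atoms:
            a.position = a.position - centre
        t.invalidate_cache()
        p = tmp_path / "rt.pqr"
        write_pqr(t, p)
        back = read_pqr(p)
        np.testing.assert_allclose(back.positions, t.positions, atol=2e-3)
        np.testing.assert_allclose(back.charges, t.charges, atol=1e-3)
        np.testing.assert_allclose(back.radii, t.radii, atol=1e-3)

    def test_agrees_with_mdanalysis_reader(self, tmp_path):
        """Independent cross-check of the PQR dialect against MDAnalysis."""
        mda = pytest.importorskip("MDAnalysis")
        rng = np.random.default_rng(1)
        atoms = [AtomRecord("C", rng.uniform(-5, 5, 3), radius=1.7,
                            charge=round(rng.uniform(-1, 1), 4))
                 for _ in range(10)]
        t = _template(atoms)
        p = tmp_path / "x.pqr"
        write_pqr(t, p)
        ours = read_pqr(p)
        u = mda.Universe(str(p))
        np.testing.assert_allclose(
            ours.positions,
            u.atoms.positions - u.atoms.positions.mean(axis=0), atol=2e-3)
        np.testing.assert_allclose(ours.charges, u.atoms.charges, atol=1e-4)
        np.testing.assert_allclose(ours.radii, u.atoms.radii, atol=1e-4)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 C MOL 1 0 0 0 0.0 1.5\n"
                     "ATOM 2 C MOL 1 nan_is fine 0 xx 1.5\n")
        with pytest.raises(PQRParseError, match=":2:"):
            read_pqr(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pqr"
        p.write_text("")
        with pytest.raises(PQRParseError, match="no ATOM"):
            read_pqr(p)


# ---------------------------------------------------------------- exposure

def _brute_force_sasa_exposed(template, probe=4.0, n=10000):
    """Dense-sampling oracle: exposed iff any of n surface points free."""
    pos, rad = template.positions, template.radii + probe
    from crowdbd.models import _fibonacci_sphere
    sphere = _fibonacci_sphere(n)
    out = []
    for i in range(len(pos)):
        pts = pos[i] + rad[i] * sphere
        free = np.ones(n, bool)
        for j in range(len(pos)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - pos[j], axis=1) >= rad[j]
        out.append(bool(free.any()))
    return np.array(out)


class TestExposure:
    def test_single_atom_exposed(self):
        t = _template([AtomRecord("C", (0, 0, 0), 2.0, 0.0)])
        select_exposed_atoms(t)
        assert t.atoms[0].exposed

    def test_far_pair_both_exposed(self):
        t = _template([AtomRecord("C", (0, 0, 0), 2.0, 0.0),
                       AtomRecord("C", (30, 0, 0), 2.0, 0.0)])
        select_exposed_atoms(t, probe_radius=4.0)
        assert all(a.exposed for a in t.atoms)

    def test_fcc13_centre_buried_and_matches_oracle(self):
        """Central atom of a close-packed 13-sphere cluster is buried;
        every exposure decision agrees with a dense-point oracle."""
        r = 6.0
        d = 2 * r
        dirs = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0],
                         [1, 0, 1], [1, 0, -1], [-1, 0, 1], [-1, 0, -1],
                         [0, 1, 1], [0, 1, -1], [0, -1, 1], [0, -1, -1]],
                        float) / math.sqrt(2)
        atoms = [AtomRecord("C0", (0, 0, 0), r, 0.0)]
        atoms += [AtomRecord(f"C{i+1}", d * v, r, 0.0)
                  for i, v in enumerate(dirs)]
        t = _template(atoms)
        select_exposed_atoms(t, probe_radius=4.0)
        assert not t.atoms[0].exposed
        assert all(a.exposed for a in t.atoms[1:])
        oracle = _brute_force_sasa_exposed(t)
        np.testing.assert_array_equal(t.exposed_mask, oracle)

    def test_random_cluster_matches_oracle(self):
        rng = np.random.default_rng(5)
        atoms = [AtomRecord("C", rng.uniform(-8, 8, 3),
                            rng.uniform(1.5, 3.0), 0.0) for _ in range(18)]
        t = _template(atoms)
        select_exposed_atoms(t)
        np.testing.assert_array_equal(t.exposed_mask,
                                      _brute_force_sasa_exposed(t))

    def test_hydrogens_never_exposed(self):
        t = _template([AtomRecord("H1", (0, 0, 0), 1.0, 0.0),
                       AtomRecord("C", (30, 0, 0), 2.0, 0.0)])
        select_exposed_atoms(t)
        assert not t.atoms[0].exposed

    def test_zero_atoms_errors(self):
        with pytest.raises(ValueError):
            select_exposed_atoms(_template([]))


# ---------------------------------------------------- Stokes-Einstein

class TestStokesEinstein:
    def test_scaling_laws(self):
        dt1, dr1 = stokes_einstein_coefficients(10.0)
        dt2, dr2 = stokes_einstein_coefficients(20.0)
        assert dt2 == pytest.approx(dt1 / 2)
        assert dr2 == pytest.approx(dr1 / 8)

    def test_si_oracle(self):
        """Direct SI evaluation of kT/(6 pi eta R), independently
        converted to Å²/ps."""
        dt, dr = stokes_einstein_coefficients(20.0, 298.15, 0.89)
        kb, t = 1.380649e-23, 298.15
        d_si = kb * t / (6 * math.pi * 0.89e-3 * 20e-10)  # m²/s
        assert dt == pytest.approx(d_si * 1e20 / 1e12, rel=1e-12)
        dr_si = kb * t / (8 * math.pi * 0.89e-3 * (20e-10) ** 3)  # 1/s
        assert dr == pytest.approx(dr_si / 1e12, rel=1e-12)

    def test_viscous_limit_and_errors(self):
        dt, dr = stokes_einstein_coefficients(10.0, viscosity=1e9)
        assert dt < 1e-10 and dr < 1e-10
        for bad in [(0, 298, 1), (10, -1, 1), (10, 298, 0)]:
            with pytest.raises(ValueError):
                stokes_einstein_coefficients(*bad)


# ------------------------------------------------------------------- grids

class TestGrids:
    def test_zero_charge_grid_is_zero(self):
        t = _template([AtomRecord("C", (0, 0, 0), 2.0, 0.0)])
        g = generate_screened_coulomb_grid(t, spacing=4.0, margin=10.0)
        assert np.all(g.values == 0.0)

    def test_unscreened_single_charge_matches_coulomb(self):
        t = _template([AtomRecord("N", (0, 0, 0), 1.5, 1.0)])
        g = generate_screened_coulomb_grid(t, spacing=2.0, margin=16.0,
                                           ionic_strength=0.0,
                                           solvent_dielectric=78.0)
        n = np.array(g.dims)
        idx = [(0, 0, 0), (0, n[1] // 2, n[2] // 2),
               (n[0] - 1, n[1] - 1, n[2] - 1)]
        for i, j, k in idx:
            node = g.origin + g.spacing * np.array([i, j, k])
            r = max(np.linalg.norm(node), 1.5)
            assert g.values[i, j, k] == pytest.approx(
                COULOMB / (78.0 * r), rel=1e-12)

    def test_monotone_decay_along_ray(self):
        t = _template([AtomRecord("N", (0, 0, 0), 1.5, 1.0)])
        g = generate_screened_coulomb_grid(t, spacing=2.0, margin=16.0,
                                           ionic_strength=0.15)
        i0, j0, k0 = (np.array(g.dims) - 1) // 2
        line = g.values[i0:, j0, k0]
        assert np.all(np.diff(np.abs(line)) <= 1e-12)

    def test_spacing_validation(self):
        t = _template([AtomRecord("N", (0, 0, 0), 1.5, 1.0)])
        with pytest.raises(ValueError):
            generate_screened_coulomb_grid(t, spacing=-1.0)

    def test_interpolation_of_linear_field_exact(self):
        """Trilinear interpolation reproduces a linear field exactly."""
        ax = np.arange(5) * 2.0 - 4.0
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = 0.5 * X - 1.25 * Y + 2.0 * Z + 3.0
        g = PotentialGrid(origin=(-4, -4, -4), spacing=2.0, values=vals)
        rng = np.random.default_rng(2)
        pts = rng.uniform(-4, 4, size=(50, 3))
        v, grad, inside = g.interpolate(pts, gradient=True)
        assert inside.all()
        expected = 0.5 * pts[:, 0] - 1.25 * pts[:, 1] + 2.0 * pts[:, 2] + 3.0
        np.testing.assert_allclose(v, expected, atol=1e-12)
        np.testing.assert_allclose(grad, np.tile([0.5, -1.25, 2.0], (50, 1)),
                                   atol=1e-12)

    def test_outside_points_are_zero(self):
        g = PotentialGrid(origin=(0, 0, 0), spacing=1.0,
                          values=np.ones((3, 3, 3)))
        v = g.interpolate(np.array([[10.0, 0, 0]]))
        assert v[0] == 0.0


class TestDX:
    def test_small_grid_of_ones(self, tmp_path):
        g = PotentialGrid(origin=(0, 0, 0), spacing=1.0,
                          values=np.ones((2, 2, 2)))
        p = tmp_path / "ones.dx"
        write_dx_grid(g, p)
        back = read_dx_grid(p)
        assert back.values.shape == (2, 2, 2)
        np.testing.assert_array_equal(back.values, 1.0)

    def test_roundtrip_random(self, tmp_path):
        rng = np.random.default_rng(3)
        g = PotentialGrid(origin=(-3.0, 1.0, 2.5), spacing=1.5,
                          values=rng.normal(size=(4, 5, 6)))
        p = tmp_path / "rand.dx"
        write_dx_grid(g, p)
        back = read_dx_grid(p)
        np.testing.assert_allclose(back.origin, g.origin)
        assert back.spacing == pytest.approx(g.spacing)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-12)

    def test_wrong_header_errors(self, tmp_path):
        p = tmp_path / "junk.dx"
        p.write_text("object 1 class banana\n")
        with pytest.raises(ValueError):
            read_dx_grid(p)


# ------------------------------------------------------- effective charges

class TestEffectiveCharges:
    def test_single_point_charge_recovered(self):
        t = _template([AtomRecord("N", (0, 0, 0), 1.5, 0.8)])
        g = generate_screened_coulomb_grid(t, spacing=2.0, margin=18.0,
                                           ionic_strength=0.15)
        ec = fit_effective_charges(t, g, shell_inner=3.0, shell_outer=12.0)
        assert len(ec) == 1
        assert ec.magnitudes[0] == pytest.approx(0.8, rel=0.01)
        assert ec.residual < 0.05

    def test_zero_grid_zero_charges(self):
        t = _template([AtomRecord("N", (0, 0, 0), 1.5, 0.0)])
        g = generate_screened_coulomb_grid(t, spacing=4.0, margin=12.0)
        ec = fit_effective_charges(t, g)
        np.testing.assert_allclose(ec.magnitudes, 0.0)

    def test_linearity_in_grid(self):
        rng = np.random.default_rng(4)
        atoms = [AtomRecord("N", rng.uniform(-3, 3, 3), 1.5,
                            rng.uniform(-1, 1)) for _ in range(4)]
        t = _template(atoms)
        g = generate_screened_coulomb_grid(t, spacing=2.0, margin=16.0)
        g2 = PotentialGrid(origin=g.origin, spacing=g.spacing,
                           values=2.0 * g.values)
        ec1 = fit_effective_charges(t, g)
        ec2 = fit_effective_charges(t, g2)
        np.testing.assert_allclose(ec2.magnitudes, 2.0 * ec1.magnitudes,
                                   rtol=1e-8)

    def test_fixture_molecule_residual_small(self):
        """Effective-charge field reproduces the source grid in the fit
        shell to <= 5% relative RMS on a multi-bead fixture."""
        from crowdbd.fixtures import make_bead_protein
        t = make_bead_protein(6, 4.0, "globule",
                              charges=[1, -1, 0.5, -0.5, 0.25, -0.25])
        ec = fit_effective_charges(t, t.fine_grid)
        assert ec.residual <= 0.05


# --------------------------------------------------------- serialization

def test_template_archive_roundtrip(tmp_path):
    from crowdbd.fixtures import make_bead_protein
    t = make_bead_protein(5, 4.0, "chain", charges=[1, 0, -1, 0, 0.5])
    p = tmp_path / "t.json"
    save_template(t, p)
    back = load_template(p)
    np.testing.assert_allclose(back.positions, t.positions)
    np.testing.assert_allclose(back.charges, t.charges)
    np.testing.assert_array_equal(back.exposed_mask, t.exposed_mask)
    assert back.d0_trans == pytest.approx(t.d0_trans)
    np.testing.assert_allclose(back.fine_grid.values, t.fine_grid.values)
    np.testing.assert_allclose(back.effective_charges.magnitudes,
                               t.effective_charges.magnitudes)
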