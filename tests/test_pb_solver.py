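"""Finite-difference PB solver: grid setup, charge spreading, analytic
electrostatics oracles (Coulomb, Born, Kirkwood)."""

import numpy as np
import pytest

from bindmodes.pb_solver import (
    KE, PBConfig, _boundary_potential, assign_dielectric, build_grid,
    grid_geometry, polar_solvation, solve, spread_charges,
)
from bindmodes.structure_io import Atom, Structure


def _atoms(coords, names=None):
    coords = np.atleast_2d(coords)
    return Structure.from_atoms([
        Atom(i + 1, (names or ["CA"] * len(coords))[i], "ALA", i + 1, "A", c)
        for i, c in enumerate(coords)])


def born_energy(q, R, eps_in, eps_out):
    return -KE * q * q / (2.0 * R) * (1.0 / eps_in - 1.0 / eps_out)


class TestGridGeometry:
    def test_single_atom_at_origin(self):
        g, acent = grid_geometry(_atoms([0, 0, 0]), PBConfig())
        np.testing.assert_allclose(acent, 0.0)
        assert g == 33  # floor for a degenerate solute

    def test_two_atom_formula_with_floor(self):
        # half-extent 5 Å at scale 2 -> formula gives 20 -> odd 21 -> floor 33
        g, acent = grid_geometry(_atoms([[-5, 0, 0], [5, 0, 0]]), PBConfig())
        np.testing.assert_allclose(acent, 0.0)
        assert g == 33

    def test_formula_dominates_for_large_solute(self):
        s = _atoms([[-30, 0, 0], [30, 0, 0]])
        g, _ = grid_geometry(s, PBConfig())
        # scale*2*extent = 120 -> odd 121; margin rule may round up a little
        assert g >= 121 and g % 2 == 1
        # every atom at least margin away from the box faces
        grid = build_grid(s, PBConfig())
        half_box = grid.spacing * (grid.gsize - 1) / 2
        assert half_box >= 30 + PBConfig().margin - grid.spacing

    def test_translation_covariance(self):
        s = _atoms([[-5, 0, 0], [5, 0, 0], [0, 3, 1]])
        t = np.array([7.3, -2.1, 0.9])
        g1, a1 = grid_geometry(s, PBConfig())
        g2, a2 = grid_geometry(s.with_coords(s.coords + t), PBConfig())
        assert g1 == g2
        np.testing.assert_allclose(a2 - a1, t, atol=1e-12)

    def test_gsize_always_odd(self):
        for extent in (3.0, 8.7, 13.2, 21.9):
            g, _ = grid_geometry(_atoms([[-extent, 0, 0], [extent, 0, 0]]), PBConfig())
            assert g % 2 == 1


class TestSpreadCharges:
    def test_charge_on_node_stays_there(self):
        s = _atoms([0, 0, 0])
        grid = build_grid(s, PBConfig())
        q = spread_charges(s, np.array([1.0]), grid)
        c = (grid.gsize - 1) // 2
        assert q[c, c, c] == pytest.approx(1.0)
        assert q.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cell_center_eighth_shares(self):
        s = _atoms([0, 0, 0])
        grid = build_grid(s, PBConfig())
        h = grid.spacing
        s2 = s.with_coords(s.coords + h / 2.0)
        # keep the same grid (explicit acent) so the atom sits mid-cell
        q = spread_charges(s2, np.array([1.0]), grid)
        nz = q[q > 0]
        assert len(nz) == 8
        np.testing.assert_allclose(nz, 0.125)

    def test_conservation_random_positions(self, rng):
        coords = rng.uniform(-4, 4, (20, 3))
        charges = rng.uniform(-1, 1, 20)
        s = _atoms(coords)
        grid = build_grid(s, PBConfig())
        q = spread_charges(s, charges, grid)
        assert q.sum() == pytest.approx(charges.sum(), abs=1e-10)

    def test_atom_outside_grid_rejected(self):
        s = _atoms([0, 0, 0])
        grid = build_grid(s, PBConfig())
        far = s.with_coords(np.array([[100.0, 0, 0]]))
        with pytest.raises(ValueError, match="outside"):
            spread_charges(far, np.array([1.0]), grid)


class TestDielectric:
    def test_uniform_when_eps_equal(self):
        s = _atoms([0, 0, 0])
        grid = build_grid(s, PBConfig())
        for m in assign_dielectric(s, np.array([2.0]), grid, 4.0, 4.0):
            assert np.all(m == 4.0)

    def test_edge_inside_sphere_gets_eps_in(self):
        s = _atoms([0, 0, 0])
        grid = build_grid(s, PBConfig())
        ex, _, _ = assign_dielectric(s, np.array([2.0]), grid, 4.0, 80.0)
        c = (grid.gsize - 1) // 2
        assert ex[c, c, c] == 4.0       # edge midpoint 0.25 Å from the centre
        assert ex[0, 0, 0] == 80.0      # far corner

    def test_interior_fraction_grows_with_radius(self):
        s = _atoms([0, 0, 0])
        grid = build_grid(s, PBConfig(), pad=8.0)
        fracs = []
        for r in (1.0, 2.0, 3.0, 4.0):
            ex, ey, ez = assign_dielectric(s, np.array([r]), grid, 4.0, 80.0)
            fracs.append(sum(float((m == 4.0).mean()) for m in (ex, ey, ez)))
        assert all(b > a for a, b in zip(fracs, fracs[1:]))


class TestSolve:
    def test_zero_charge_zero_potential(self):
        s = _atoms([0, 0, 0])
        cfg = PBConfig()
        grid = build_grid(s, cfg)
        q = np.zeros((grid.gsize,) * 3)
        eps = assign_dielectric(s, np.array([2.0]), grid, 4.0, 80.0)
        res = solve(grid, q, eps, cfg)
        assert np.all(res.phi == 0.0)
        assert res.converged

    def test_uniform_medium_matches_coulomb(self):
        s = _atoms([0, 0, 0])
        cfg = PBConfig(eps_in=2.0, eps_out=2.0, nlit=2000, relaxation="auto", gsize=41)
        grid = build_grid(s, cfg, pad=10.0)
        q = spread_charges(s, np.array([1.0]), grid)
        eps = assign_dielectric(s, np.array([2.0]), grid, 2.0, 2.0)
        bnd = _boundary_potential(grid, s.coords, np.array([1.0]), 2.0, 0.0, cfg.coulomb_kt)
        res = solve(grid, q, eps, cfg, boundary=bnd)
        c = (grid.gsize - 1) // 2
        for r_nodes in (10, 14, 18):
            r = r_nodes * grid.spacing
            analytic = cfg.coulomb_kt / (2.0 * r)
            assert res.phi[c + r_nodes, c, c] == pytest.approx(analytic, rel=0.05)

    def test_tighter_convergence_approaches_fixed_point(self):
        # halving the convergence tolerance never drifts the solution away
        # from the fully converged discrete fixed point
        s = _atoms([0, 0, 0])
        def _solve(conv):
            cfg = PBConfig(eps_in=2.0, eps_out=2.0, convergence=conv, nlit=20000,
                           relaxation="auto", gsize=33)
            grid = build_grid(s, cfg, pad=8.0)
            q = spread_charges(s, np.array([1.0]), grid)
            eps = assign_dielectric(s, np.array([2.0]), grid, 2.0, 2.0)
            bnd = _boundary_potential(grid, s.coords, np.array([1.0]), 2.0, 0.0, cfg.coulomb_kt)
            return solve(grid, q, eps, cfg, boundary=bnd).phi
        reference = _solve(1e-9)
        errs = [float(np.max(np.abs(_solve(conv) - reference)))
                for conv in (0.1, 0.05, 0.025)]
        assert errs[1] <= errs[0] + 1e-12 and errs[2] <= errs[1] + 1e-12

    def test_nonconvergence_flagged_not_fatal(self):
        s = _atoms([0, 0, 0])
        cfg = PBConfig(nlit=2, convergence=1e-9)
        grid = build_grid(s, cfg)
        q = spread_charges(s, np.array([1.0]), grid)
        eps = assign_dielectric(s, np.array([2.0]), grid, 1.0, 80.0)
        res = solve(grid, q, eps, cfg)
        assert not res.converged and res.iterations == 2


class TestPolarSolvation:
    def test_zero_charges(self):
        s = _atoms([[0, 0, 0], [3, 0, 0]])
        assert polar_solvation(s, (np.zeros(2), np.full(2, 2.0)), PBConfig()) == 0.0

    def test_born_ion(self):
        s = _atoms([0, 0, 0])
        cfg = PBConfig(scale=2, eps_in=1.0, eps_out=80.0, nlit=2000, relaxation="auto")
        e = polar_solvation(s, (np.array([1.0]), np.array([2.0])), cfg)
        assert e == pytest.approx(born_energy(1.0, 2.0, 1.0, 80.0), rel=0.05)

    def test_reference_equals_solvated_when_eps_match(self):
        s = _atoms([0, 0, 0])
        cfg = PBConfig(eps_in=4.0, eps_out=4.0, nlit=300)
        assert polar_solvation(s, (np.array([1.0]), np.array([2.0])), cfg) == 0.0

    def test_quadratic_in_charge(self):
        s = _atoms([0, 0, 0])
        cfg = PBConfig(scale=2, eps_in=1.0, eps_out=80.0, nlit=1000, relaxation="auto")
        e_pos = polar_solvation(s, (np.array([1.0]), np.array([2.0])), cfg)
        e_neg = polar_solvation(s, (np.array([-1.0]), np.array([2.0])), cfg)
        assert e_pos == e_neg

    def test_translation_invariance(self):
        # moving the solute by a non-integer multiple of the spacing moves
        # the (solute-centred) grid with it: drift stays below 1%
        charges, radii = np.array([1.0, -0.5]), np.array([2.0, 1.6])
        s1 = _atoms([[0, 0, 0], [2.5, 0.3, -0.4]])
        cfg = PBConfig(scale=2, eps_in=2.0, eps_out=80.0, nlit=1500, relaxation="auto")
        e1 = polar_solvation(s1, (charges, radii), cfg)
        s2 = s1.with_coords(s1.coords + np.array([0.137, -0.219, 0.083]))
        e2 = polar_solvation(s2, (charges, radii), cfg)
        assert abs(e2 - e1) < 0.01 * abs(e1)

    def test_kirkwood_two_charges(self):
        """Two charges in a low-dielectric sphere vs the analytic Kirkwood
        multipole expansion."""
        R, eps_in, eps_out = 4.0, 2.0, 80.0
        r1 = np.array([0.0, 0.0, 1.5])
        r2 = np.array([0.0, 0.0, -1.5])
        q = np.array([1.0, 1.0, 0.0])
        # third "atom" carries the cavity sphere, charges sit inside it
        s = _atoms([r1, r2, [0, 0, 0]])
        radii = np.array([0.5, 0.5, R])
        cfg = PBConfig(scale=4, eps_in=eps_in, eps_out=eps_out, nlit=3000,
                       relaxation="auto")
        num = polar_solvation(s, (q, radii), cfg)

        # independent oracle: Kirkwood series with Legendre polynomials
        from numpy.polynomial.legendre import legval
        def kirkwood(qs, rs, cos_tbl):
            total = 0.0
            for i in range(len(qs)):
                for j in range(len(qs)):
                    ri, rj = np.linalg.norm(rs[i]), np.linalg.norm(rs[j])
                    cos_t = cos_tbl[i][j]
                    for l in range(0, 60):
                        pl = legval(cos_t, [0] * l + [1])
                        coef = ((l + 1) * (eps_in - eps_out) /
                                (eps_in * (eps_out * (l + 1) + l * eps_in)))
                        total += qs[i] * qs[j] * coef * (ri * rj) ** l / R ** (2 * l + 1) * pl
            return KE / 2.0 * total
        cos_tbl = [[1.0, -1.0], [-1.0, 1.0]]
        ana = kirkwood(q[:2], [r1, r2], cos_tbl)
        assert num == pytest.approx(ana, rel=0.10)


class TestConfigValidation:
    def test_positive_parameters_enforced(self):
        with pytest.raises(ValueError):
            PBConfig(scale=0)
        with pytest.raises(ValueError):
            PBConfig(convergence=-1)
        with pytest.raises(ValueError):
            PBConfig(eps_in=0.5)
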