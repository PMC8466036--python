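"""nci_promolecular: field analytics, RDG closed forms, lambda2 signs, outputs."""

from __future__ import annotations

import numpy as np
import pytest

from oxastack.grids import BOHR_PER_ANGSTROM
from oxastack.nci_promolecular import (
    PROMOLECULAR_MODEL,
    RDG_PREFACTOR,
    AtomicDensityModel,
    compute_nci,
    default_grid,
    nci_outputs,
    promolecular_field,
    rdg,
    signed_lambda2,
    symmetric_eigenvalues_3x3,
)
from oxastack.structure_io import AtomSite, read_cube
from oxastack.synthetic_data import PairSpec, make_ideal_ring, place_pair
from conftest import rigid_motion, sites_from


def single_atom(element="C"):
    return [AtomSite(label=f"{element}1", element=element, cart=[0.0, 0.0, 0.0])]


class TestModelTable:
    def test_all_required_elements_present(self):
        for el in ("H", "C", "N", "O", "S"):
            assert el in PROMOLECULAR_MODEL

    def test_shells_positive_and_densities_decay(self):
        r = np.linspace(0.1, 15, 200)
        for el, terms in PROMOLECULAR_MODEL.shells.items():
            assert all(c > 0 and z > 0 for c, z in terms)
            rho = PROMOLECULAR_MODEL.atom_density(el, r)
            assert np.all(np.diff(rho) < 0)

    def test_electron_count_order_of_magnitude(self):
        """8 pi sum(c z^3) integrates each fit; it must land near the
        element's electron count (these are shape fits, not normalized)."""
        from oxastack._elements import atomic_number
        for el, terms in PROMOLECULAR_MODEL.shells.items():
            n_el = 8 * np.pi * sum(c * z ** 3 for c, z in terms)
            assert 0.5 * atomic_number(el) < n_el < 1.5 * atomic_number(el), el

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AtomicDensityModel({"H": ((-1.0, 0.5),)})


class TestField:
    def test_single_atom_density_equals_shell_sum(self):
        rho, _, _ = promolecular_field(single_atom("C"), np.array([[1.0, 0, 0]]))
        r_bohr = 1.0 * BOHR_PER_ANGSTROM
        expected = sum(c * np.exp(-r_bohr / z)
                       for c, z in PROMOLECULAR_MODEL.shells["C"])
        assert rho[0] == pytest.approx(expected, rel=1e-12)

    def test_two_atom_additivity(self):
        atoms = [AtomSite(label="C1", element="C", cart=[0, 0, 0]),
                 AtomSite(label="N1", element="N", cart=[2.0, 0, 0])]
        pts = np.random.default_rng(0).uniform(-2, 4, (20, 3))
        rho_both, g_both, h_both = promolecular_field(atoms, pts)
        rho_sum = np.zeros(20)
        g_sum = np.zeros((20, 3))
        h_sum = np.zeros((20, 3, 3))
        for a in atoms:
            r, g, h = promolecular_field([a], pts)
            rho_sum += r
            g_sum += g
            h_sum += h
        # additive by construction; only summation-order ulps may differ
        np.testing.assert_allclose(rho_both, rho_sum, rtol=1e-14)
        np.testing.assert_allclose(g_both, g_sum, rtol=1e-12, atol=1e-18)
        np.testing.assert_allclose(h_both, h_sum, rtol=1e-12, atol=1e-18)

    def test_density_vanishes_far_away(self):
        rho, _, _ = promolecular_field(single_atom("S"), np.array([[20.0, 0, 0]]))
        assert rho[0] < 1e-12

    def test_unsupported_element_named(self):
        atoms = [AtomSite(label="FE1", element="Fe", cart=[0, 0, 0])]
        with pytest.raises(ValueError, match="Fe"):
            promolecular_field(atoms, np.zeros((1, 3)))

    def test_analytic_derivatives_match_finite_differences(self):
        """Gradient and Hessian from the shell formulas agree with central
        differences to < 1e-5 relative error on random points."""
        atoms = [AtomSite(label="C1", element="C", cart=[0, 0, 0]),
                 AtomSite(label="O1", element="O", cart=[2.5, 0.3, -0.2])]
        pts = np.random.default_rng(1).uniform(-1.5, 4.0, (40, 3))
        rho0, g0, h0 = promolecular_field(atoms, pts)
        eps = 1e-4
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = eps
            rp, gp, _ = promolecular_field(atoms, pts + dp)
            rm, gm, _ = promolecular_field(atoms, pts - dp)
            g_fd = (rp - rm) / (2 * eps * BOHR_PER_ANGSTROM)
            h_fd = (gp - gm) / (2 * eps * BOHR_PER_ANGSTROM)
            assert np.max(np.abs(g_fd - g0[:, k])) < 1e-5 * np.max(np.abs(g0))
            assert np.max(np.abs(h_fd - h0[:, :, k])) < 1e-5 * np.max(np.abs(h0))

    def test_rotational_invariance(self):
        struct = place_pair(PairSpec(kind_a="phenyl", kind_b="pyridine", h=3.4))
        pts = np.random.default_rng(5).uniform(-3, 6, (30, 3))
        rho0, g0, h0 = promolecular_field(struct.sites, pts)
        rot, trans = rigid_motion(np.random.default_rng(6))
        moved = [AtomSite(label=s.label, element=s.element,
                          cart=rot @ s.cart + trans) for s in struct.sites]
        rho1, g1, h1 = promolecular_field(moved, pts @ rot.T + trans)
        np.testing.assert_allclose(rho1, rho0, atol=1e-9)
        s0, s1 = rdg(rho0, g0), rdg(rho1, g1)
        np.testing.assert_allclose(s1, s0, atol=1e-9)
        np.testing.assert_allclose(signed_lambda2(rho1, h1),
                                   signed_lambda2(rho0, h0), atol=1e-9)


class TestRDG:
    def test_single_shell_closed_form(self):
        """For rho = c exp(-r/zeta): s(r) = rho^(-1/3) / (2 (3 pi^2)^(1/3) zeta)."""
        model = AtomicDensityModel({"H": ((0.2815, 0.5288),)})
        r = np.linspace(0.5, 5.0, 50)
        pts = np.stack([r, np.zeros_like(r), np.zeros_like(r)], axis=1)
        rho, grad, _ = promolecular_field(single_atom("H"), pts, model)
        s = rdg(rho, grad)
        s_closed = rho ** (-1.0 / 3.0) / (RDG_PREFACTOR * 0.5288)
        np.testing.assert_allclose(s, s_closed, rtol=1e-6)

    def test_midpoint_of_homonuclear_pair_is_stationary(self):
        atoms = [AtomSite(label="C1", element="C", cart=[0, 0, 0]),
                 AtomSite(label="C2", element="C", cart=[3.0, 0, 0])]
        rho, grad, _ = promolecular_field(atoms, np.array([[1.5, 0, 0]]))
        assert rdg(rho, grad)[0] <= 1e-8

    def test_rdg_nonnegative_and_floored(self):
        rho = np.array([0.0, 1e-40, 0.5])
        grad = np.array([[1e-3, 0, 0]] * 3)
        s = rdg(rho, grad)
        assert np.all(s >= 0) and np.all(np.isfinite(s))


class TestSignedLambda2:
    def test_closed_form_eigenvalues_match_lapack(self):
        rng = np.random.default_rng(2)
        h = rng.normal(size=(300, 3, 3))
        h = h + h.transpose(0, 2, 1)
        np.testing.assert_allclose(symmetric_eigenvalues_3x3(h),
                                   np.linalg.eigvalsh(h), atol=1e-10)

    def test_degenerate_isotropic_matrix(self):
        h = np.eye(3)[None] * 2.0
        lam = symmetric_eigenvalues_3x3(h)
        np.testing.assert_allclose(lam[0], [2.0, 2.0, 2.0])

    def test_off_nucleus_single_atom_negative(self):
        """Tangential curvature of a spherical exponential is -rho/(zeta r) < 0,
        so lambda2 < 0 and the signed density is negative off-nucleus."""
        rho, _, h = promolecular_field(single_atom("C"),
                                       np.array([[1.2, 0.4, -0.3]]))
        signed = signed_lambda2(rho, h)
        assert signed[0] == pytest.approx(-rho[0])

    def test_pair_midpoint_is_3m1_saddle(self):
        """At the midpoint of a homonuclear pair the two tangential
        curvatures are negative and the axial one positive (lambda1 =
        lambda2 < 0 < lambda3); cross-checked with a numeric Hessian."""
        atoms = [AtomSite(label="C1", element="C", cart=[0, 0, 0]),
                 AtomSite(label="C2", element="C", cart=[6.0, 0, 0])]
        pt = np.array([[3.0, 0, 0]])
        rho, _, h = promolecular_field(atoms, pt)
        lam = symmetric_eigenvalues_3x3(h)[0]
        assert lam[0] < 0 and lam[1] < 0 and lam[2] > 0
        assert lam[0] == pytest.approx(lam[1], rel=1e-5)  # exactly degenerate pair
        # numeric-Hessian oracle on the density itself
        eps = 1e-3
        rho_c, _, _ = promolecular_field(atoms, pt)
        num = []
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = eps
            rp, _, _ = promolecular_field(atoms, pt + dp)
            rm, _, _ = promolecular_field(atoms, pt - dp)
            num.append((rp[0] - 2 * rho_c[0] + rm[0])
                       / (eps * BOHR_PER_ANGSTROM) ** 2)
        assert num[0] > 0 and num[1] < 0 and num[2] < 0
        assert signed_lambda2(rho, h)[0] < 0

    def test_ring_center_is_repulsive(self):
        """Inside an aromatic ring the in-plane curvatures are positive:
        lambda2 > 0, the classic steric signal."""
        coords, elems, labels = make_ideal_ring("phenyl")
        atoms = sites_from(coords, elems, labels)
        rho, _, h = promolecular_field(atoms, np.array([[0.0, 0.0, 0.0]]))
        assert signed_lambda2(rho, h)[0] > 0

    def test_signed_magnitude_is_rho(self):
        struct = place_pair(PairSpec(h=3.4))
        pts = np.random.default_rng(9).uniform(-3, 6, (50, 3))
        rho, _, h = promolecular_field(struct.sites, pts)
        signed = signed_lambda2(rho, h)
        np.testing.assert_allclose(np.abs(signed), rho, atol=1e-30)


class TestOutputs:
    def test_zero_cutoff_empty_scatter(self):
        struct = place_pair(PairSpec(h=3.4))
        res = compute_nci(struct.sites, spacing=0.5, rho_cutoff=0.0)
        assert len(res.scatter) == 0

    def test_stacked_dimer_has_dispersive_region(self):
        """Between two stacked rings there must be scatter points with small
        |sign(lambda2) rho| and small RDG - the green dispersive signature."""
        struct = place_pair(PairSpec(kind_a="phenyl", kind_b="phenyl", h=3.4))
        res = compute_nci(struct.sites, spacing=0.25)
        sc = res.scatter
        region = sc[(sc.signed_rho.abs() < 0.01) & (sc.rdg < 1.0)]
        assert len(region) > 0

    def test_cube_round_trip_through_outputs(self, tmp_path):
        struct = place_pair(PairSpec(h=3.4))
        res = compute_nci(struct.sites, spacing=0.5)
        paths = nci_outputs(res, tmp_path / "nci", atoms=struct.sites)
        grid, atoms = read_cube(paths["rho"])
        assert grid.dims == res.rho.dims
        np.testing.assert_allclose(grid.values, res.rho.values,
                                   rtol=1e-4, atol=1e-12)
        assert len(atoms) == len(struct.sites)
        assert paths["scatter"].exists()

    def test_default_grid_covers_atoms(self):
        struct = place_pair(PairSpec(h=3.4))
        grid = default_grid(struct.sites, margin=3.0, spacing=0.3)
        pts = grid.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        cart = struct.cart
        assert np.all(lo <= cart.min(axis=0)) and np.all(hi >= cart.max(axis=0))
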