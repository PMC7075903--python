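"""Hessian assembly, normal modes, mode statistics and moduli extraction."""

import numpy as np
import pytest

from activesheet.modes import (
    assemble_hessian,
    dynamical_matrix,
    eigenmodes,
    estimate_moduli,
    mode_energies,
    mode_fourier_weights,
    mode_velocity_correlation,
)
from activesheet.observables import commensurate_qgrid
from activesheet.softdisk import SoftDiskConfig, energy_and_forces
from activesheet.synthfields import make_fixture_packing


def finite_difference_hessian(config, h=1e-5):
    n = config.n
    hess = np.zeros((2 * n, 2 * n))

    def force_vec(p):
        _, f = energy_and_forces(SoftDiskConfig(p, config.radii, config.box,
                                                stiffness=config.stiffness))
        return f.ravel()

    for j in range(n):
        for b in range(2):
            p = config.positions.copy()
            p[j, b] += h
            fp = force_vec(p)
            p[j, b] -= 2 * h
            fm = force_vec(p)
            hess[:, 2 * j + b] = -(fp - fm) / (2 * h)
    return 0.5 * (hess + hess.T)


class TestHessian:
    def test_two_disk_contact_block_closed_form(self, two_disk):
        # contact along x: off-diagonal block diag(-k, |f|/r) with
        # |f| = 0.1, r = 1.9
        hess = assemble_hessian(two_disk, equilibrium_tol=np.inf).toarray()
        np.testing.assert_allclose(
            hess[0:2, 2:4], np.diag([-1.0, 0.1 / 1.9]), atol=1e-12
        )
        evals = np.linalg.eigvalsh(hess)
        # two translations, one positive (normal) and one negative
        # (transverse pre-stress: an isolated compressed contact is unstable
        # to rotation)
        assert np.sum(np.abs(evals) < 1e-12) == 2
        assert evals[-1] == pytest.approx(2.0)
        assert evals[0] == pytest.approx(-2 * 0.1 / 1.9)

    def test_block_rows_sum_to_zero(self, small_packing):
        hess = assemble_hessian(small_packing).toarray()
        n = small_packing.n
        rows = hess.reshape(n, 2, n, 2).sum(axis=2)
        np.testing.assert_allclose(rows, 0.0, atol=1e-12)

    def test_matches_finite_difference_second_derivatives(self, small_packing):
        hess = assemble_hessian(small_packing).toarray()
        fd = finite_difference_hessian(small_packing)
        scale = np.abs(fd).max()
        np.testing.assert_allclose(hess, fd, atol=1e-5 * scale)

    def test_nonequilibrium_input_warns(self, two_disk):
        with pytest.warns(UserWarning, match="equilibrium"):
            assemble_hessian(two_disk)

    def test_printed_form_drops_inverse_distance(self, two_disk):
        hess = assemble_hessian(two_disk, printed_form=True,
                                equilibrium_tol=np.inf).toarray()
        np.testing.assert_allclose(hess[0:2, 2:4], np.diag([-1.0, 0.1]), atol=1e-12)


class TestEigenmodes:
    def test_orthonormality_and_ascending_order(self, small_packing):
        modes = eigenmodes(assemble_hessian(small_packing))
        gram = modes.eigenvectors.T @ modes.eigenvectors
        np.testing.assert_allclose(gram, np.eye(2 * small_packing.n), atol=1e-10)
        assert np.all(np.diff(modes.eigenvalues) >= -1e-12)

    def test_exactly_two_zero_modes_for_jammed_packing(self, small_packing):
        modes = eigenmodes(assemble_hessian(small_packing))
        near_zero = np.abs(modes.eigenvalues) < 1e-8
        assert near_zero.sum() == 2
        assert np.all(modes.eigenvalues[~near_zero] > 0)

    def test_uniform_translation_is_annihilated(self, small_packing):
        hess = assemble_hessian(small_packing)
        t = np.tile([1.0, 0.0], small_packing.n)
        np.testing.assert_allclose(hess.matrix @ t, 0.0, atol=1e-12)


class TestModeStatistics:
    def test_mode_energy_at_unit_reduced_stiffness(self):
        # lambda tau / zeta = 1  ->  E = zeta v0^2 tau / 8
        modes = eigenmodes(assemble_hessian(make_fixture_packing("random-64")))
        lam = modes.eigenvalues[100]
        tau = 1.0 / lam
        e = mode_energies(modes, v0=2.0, tau=tau, zeta=1.0)
        assert e[100] == pytest.approx(4.0 * tau / 8.0)

    def test_small_persistence_recovers_equipartition(self, small_packing):
        modes = eigenmodes(assemble_hessian(small_packing))
        v0, tau = 1.0, 1e-7
        e = mode_energies(modes, v0, tau)
        t_eff = 0.5 * v0**2 * tau
        np.testing.assert_allclose(e, t_eff / 2, rtol=1e-5)

    def test_large_persistence_weights_soft_modes(self, small_packing):
        modes = eigenmodes(assemble_hessian(small_packing))
        v0, tau = 1.0, 1e9
        e = mode_energies(modes, v0, tau)
        lam = np.clip(modes.eigenvalues, 1e-12, None)
        nonzero = modes.eigenvalues > 1e-8
        np.testing.assert_allclose(
            e[nonzero], v0**2 / (4 * lam[nonzero]), rtol=1e-6
        )

    def test_mode_weight_completeness_on_any_packing(self, small_packing):
        # sum_nu |xi_nu(q)|^2 = 2/N exactly, independent of q
        modes = eigenmodes(assemble_hessian(small_packing))
        qv = commensurate_qgrid(small_packing.box, 1.0)[:5]
        weights = mode_fourier_weights(modes, qv).sum(axis=1)
        np.testing.assert_allclose(weights, 2.0 / small_packing.n, rtol=1e-10)

    def test_thermal_limit_spectrum_is_flat(self, small_packing):
        modes = eigenmodes(assemble_hessian(small_packing))
        corr = mode_velocity_correlation(modes, v0=1.0, tau=1e-9, q_max=2.0)
        np.testing.assert_allclose(
            corr.values, 1.0 / small_packing.n, rtol=1e-5
        )


def hexagonal_disks(n_side=36, overlap=0.04):
    """Monodisperse triangular lattice at small uniform overlap."""
    d = 2.0 * (1.0 - overlap / 2)
    pts = []
    for r in range(n_side):
        for c in range(n_side):
            pts.append([(c + 0.5 * (r % 2)) * d, r * d * np.sqrt(3) / 2])
    box = np.array([n_side * d, n_side * d * np.sqrt(3) / 2])
    return SoftDiskConfig(np.array(pts), np.ones(n_side * n_side), box)


class TestModuli:
    def test_hexagonal_lattice_matches_stress_strain_oracle(self):
        # independent oracle: second strain derivative of the energy under
        # affine deformation (exact for the single-site lattice, where the
        # nonaffine correction vanishes by symmetry); D(q) branch slopes are
        # per-particle stiffnesses, so modulus = slope * N / A
        cfg = hexagonal_disks()
        area = float(np.prod(cfg.box))

        def deformed_energy(f_mat):
            return energy_and_forces(
                SoftDiskConfig(cfg.positions @ f_mat.T, cfg.radii,
                               cfg.box * np.diag(f_mat))
            )[0]

        eps = 1e-5
        e0 = deformed_energy(np.eye(2))
        d2_bulk = (
            deformed_energy((1 + eps) * np.eye(2))
            - 2 * e0
            + deformed_energy((1 - eps) * np.eye(2))
        ) / eps**2
        d_bulk = (
            deformed_energy((1 + eps) * np.eye(2))
            - deformed_energy((1 - eps) * np.eye(2))
        ) / (2 * eps)
        bulk_direct = (d2_bulk - d_bulk) / (4 * area)
        d2_shear = (
            deformed_energy(np.diag([1 + eps, 1 - eps]))
            - 2 * e0
            + deformed_energy(np.diag([1 - eps, 1 + eps]))
        ) / eps**2
        pressure = -d_bulk / (2 * area)
        shear_direct = d2_shear / (4 * area) - pressure / 2

        est = estimate_moduli(cfg, q_max_fit=0.25)  # quadratic-dispersion range
        per_area = cfg.n / area
        assert est.bulk * per_area == pytest.approx(bulk_direct, rel=0.02)
        assert est.shear * per_area == pytest.approx(shear_direct, rel=0.02)

    def test_branch_structure_of_jammed_packing(self, small_packing):
        est = estimate_moduli(small_packing, q_max_fit=1.5)
        assert est.bulk > 0 and est.shear > 0
        # longitudinal branch is everywhere stiffer than transverse
        assert np.all(est.lambda_l > est.lambda_t)
        # both branches grow from zero with q
        assert est.lambda_l[0] < est.lambda_l[-1]
        assert est.lambda_t[0] < est.lambda_t[-1]

    def test_dynamical_matrix_is_hermitian(self, small_packing):
        hess = assemble_hessian(small_packing)
        qv = commensurate_qgrid(small_packing.box, 1.0)[:7]
        dmats = dynamical_matrix(hess, qv)
        np.testing.assert_allclose(
            dmats, np.conj(np.swapaxes(dmats, 1, 2)), atol=1e-10
        )

    def test_too_small_box_signals_insufficient_resolution(self):
        cfg = SoftDiskConfig(np.array([[1.0, 1.0], [2.9, 1.0]]), np.ones(2),
                             np.array([4.0, 4.0]))
        with pytest.raises(ValueError, match="few"):
            estimate_moduli(cfg, q_max_fit=1.5)
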