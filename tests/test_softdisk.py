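"""Soft-disk model: packing generation, contact mechanics, active dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from activesheet.errors import (
    DegenerateContactError,
    NonConvergenceError,
    UnstableStepWarning,
)
from activesheet.softdisk import (
    ActiveDriveState,
    DivisionParams,
    SoftDiskConfig,
    divide_and_extrude,
    energy_and_forces,
    generate_packing,
    max_residual_force,
    relax_to_minimum,
    run_trajectory,
    step_active,
)

from conftest import finite_difference_forces


class TestGeneratePacking:
    def test_monodisperse_box_solves_packing_fraction(self):
        # sum(pi sigma^2) / L^2 = phi  =>  L = sigma sqrt(4 pi) for N=4, phi=1
        cfg = generate_packing(4, 1.0, 0.0, seed=1, relax=False)
        assert cfg.box_length == pytest.approx(np.sqrt(4 * np.pi))
        assert cfg.packing_fraction == pytest.approx(1.0)

    def test_polydisperse_radii_uniform_30pct(self):
        cfg = generate_packing(500, 1.0, 0.3, seed=2, relax=False)
        assert cfg.radii.min() >= 0.7 and cfg.radii.max() <= 1.3
        assert cfg.packing_fraction == pytest.approx(1.0)

    def test_relaxed_packing_is_mechanically_stable(self):
        cfg = generate_packing(400, 1.0, 0.3, seed=5)
        assert max_residual_force(cfg) < 1e-8

    def test_two_disks_at_confluence_reach_force_balance(self):
        # phi = 1 with N = 2 cannot avoid overlap; with explicit image sums
        # (box smaller than twice the cutoff) a finite-energy force-balanced
        # minimum still exists and is found
        cfg = generate_packing(2, 1.0, 0.0, seed=1)
        e, _ = energy_and_forces(cfg)
        assert np.isfinite(e)
        assert max_residual_force(cfg) < 1e-8

    @pytest.mark.parametrize(
        "kwargs", [{"n_particles": 1}, {"n_particles": 10, "packing_fraction": -1},
                   {"n_particles": 10, "polydispersity": 1.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_packing(**kwargs)


class TestEnergyForces:
    def test_disjoint_disks_are_force_free(self):
        cfg = SoftDiskConfig(np.array([[2.0, 2.0], [7.0, 7.0]]), np.ones(2), 10.0)
        e, f = energy_and_forces(cfg)
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_pair_overlap_energy_and_force(self, two_disk):
        # overlap delta = 0.1: pair energy k delta^2/2 = 0.005, |F| = k delta
        e, f = energy_and_forces(two_disk)
        assert e == pytest.approx(0.005)
        assert np.linalg.norm(f[0]) == pytest.approx(0.1)
        np.testing.assert_allclose(f[0], -f[1], atol=1e-14)
        assert f[0][0] < 0  # repulsion pushes disk 0 away from disk 1

    def test_forces_match_finite_differences(self, rng):
        cfg = generate_packing(20, 1.0, 0.3, seed=8, relax=False)
        _, f = energy_and_forces(cfg)

        def efun(p):
            return energy_and_forces(
                SoftDiskConfig(p, cfg.radii, cfg.box)
            )[0]

        fd = finite_difference_forces(efun, cfg.positions)
        np.testing.assert_allclose(f, fd, rtol=1e-6, atol=1e-7)

    def test_attractive_tail_forces_match_finite_differences(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 8, (20, 2))
        cfg = SoftDiskConfig(pos, np.ones(20), 8.0, attraction_eps=0.15)
        _, f = energy_and_forces(cfg)

        def efun(p):
            return energy_and_forces(
                SoftDiskConfig(p, cfg.radii, cfg.box, attraction_eps=0.15)
            )[0]

        fd = finite_difference_forces(efun, cfg.positions)
        np.testing.assert_allclose(f, fd, rtol=1e-5, atol=1e-7)

    def test_numba_and_numpy_kernels_agree(self, monkeypatch):
        import activesheet.softdisk as sd

        cfg = generate_packing(50, 1.0, 0.3, seed=13, relax=False)
        e_fast, f_fast = energy_and_forces(cfg)
        monkeypatch.setattr(sd, "_HAVE_NUMBA", False)
        e_ref, f_ref = energy_and_forces(cfg)
        assert e_fast == pytest.approx(e_ref, rel=1e-12)
        np.testing.assert_allclose(f_fast, f_ref, atol=1e-12)

    def test_coincident_centers_signal_degenerate_contact(self):
        cfg = SoftDiskConfig(np.array([[5.0, 5.0], [5.0, 5.0]]), np.ones(2), 10.0)
        with pytest.raises(DegenerateContactError):
            energy_and_forces(cfg)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_internal_forces_sum_to_zero(self, seed):
        cfg = generate_packing(30, 1.0, 0.3, seed=seed, relax=False)
        _, f = energy_and_forces(cfg)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)


class TestRelaxation:
    def test_minimized_config_is_fixed_point(self, small_packing):
        again = relax_to_minimum(small_packing)
        np.testing.assert_allclose(again.positions, small_packing.positions, atol=1e-6)

    def test_free_overlapping_pair_separates_completely(self):
        cfg = SoftDiskConfig(np.array([[10.0, 10.0], [11.5, 10.0]]), np.ones(2), 30.0)
        out = relax_to_minimum(cfg)
        e, _ = energy_and_forces(out)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_energy_never_increases_through_relaxation(self):
        cfg = generate_packing(100, 1.0, 0.3, seed=6, relax=False)
        e0, _ = energy_and_forces(cfg)
        out = relax_to_minimum(cfg)
        e1, _ = energy_and_forces(out)
        assert e1 <= e0

    def test_nonconvergence_reports_residual(self):
        cfg = generate_packing(100, 1.0, 0.3, seed=7, relax=False)
        with pytest.raises(NonConvergenceError) as exc:
            relax_to_minimum(cfg, tolerance=1e-8, max_iter=3)
        assert exc.value.residual > 0


class TestActiveDynamics:
    def test_force_free_particle_moves_along_polarity(self):
        cfg = SoftDiskConfig(np.array([[5.0, 5.0], [20.0, 20.0]]), np.ones(2), 40.0)
        drive = ActiveDriveState(np.array([0.0, np.pi / 2]), speed=1.0, persistence=1e12)
        rng = np.random.default_rng(0)
        new, _, vel = step_active(cfg, drive, dt=0.01, rng=rng)
        np.testing.assert_allclose(vel[0], [1.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(new.positions[0], [5.01, 5.0], atol=1e-9)

    def test_passive_system_at_minimum_is_static(self, small_packing):
        drive = ActiveDriveState(np.zeros(64), speed=0.0, persistence=1.0)
        traj = run_trajectory(small_packing, drive, dt=0.01, n_steps=100,
                              save_every=50, seed=1)
        drift = np.abs(traj.positions[-1] - traj.positions[0]).max()
        assert drift < 1e-7

    def test_orientation_autocorrelation_decays_with_persistence_time(self):
        # dilute free particles: <n(t).n(0)> = exp(-t/tau)
        n, tau = 400, 1.0
        cfg = SoftDiskConfig(
            np.random.default_rng(2).uniform(0, 400, (n, 2)), np.ones(n) * 0.01, 400.0
        )
        drive = ActiveDriveState(np.zeros(n), speed=1.0, persistence=tau)
        traj = run_trajectory(cfg, drive, dt=0.01, n_steps=3000, save_every=25, seed=3)
        nhat = np.stack([np.cos(traj.angles), np.sin(traj.angles)], axis=-1)
        lags = np.arange(traj.n_frames // 2)
        corr = np.array(
            [
                np.mean(np.einsum("fni,fni->fn", nhat[: traj.n_frames - m],
                                  nhat[m : traj.n_frames]))
                for m in lags
            ]
        )
        t = traj.times[lags] - traj.times[0]
        np.testing.assert_allclose(corr, np.exp(-t / tau), atol=0.05)

    def test_frame_counting_and_seed_determinism(self, small_packing):
        drive = ActiveDriveState(np.zeros(64), speed=0.05, persistence=1.0)
        t1 = run_trajectory(small_packing, drive, dt=0.01, n_steps=100,
                            save_every=50, seed=9)
        assert t1.n_frames == 2
        t2 = run_trajectory(small_packing, drive, dt=0.01, n_steps=100,
                            save_every=50, seed=9)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.velocities, t2.velocities)

    def test_oversized_step_warns_unstable(self, two_disk):
        drive = ActiveDriveState(np.zeros(2), speed=0.0, persistence=1.0)
        with pytest.warns(UnstableStepWarning):
            step_active(two_disk, drive, dt=100.0, rng=np.random.default_rng(0))


class TestDivision:
    def test_infinite_cycle_time_changes_nothing(self, small_packing):
        drive = ActiveDriveState(np.zeros(64), speed=0.1, persistence=1.0)
        cfg, _ = divide_and_extrude(
            small_packing, drive, dt=0.01, cycle_time=1e15, target_n=64,
            rng=np.random.default_rng(0),
        )
        np.testing.assert_array_equal(cfg.positions, small_packing.positions)

    def test_steady_state_holds_cell_number(self, small_packing):
        drive = ActiveDriveState(np.zeros(64), speed=0.05, persistence=1.0)
        division = DivisionParams(cycle_time=50.0, target_n=64)
        traj = run_trajectory(small_packing, drive, dt=0.01, n_steps=10_000,
                              save_every=1000, seed=11, division=division)
        assert traj.positions.shape[1] == 64  # constant N, within 5% trivially

    def test_division_spectra_similar_to_quiescent(self, small_packing):
        # slow divisions leave the velocity spectrum statistically unchanged
        from activesheet.observables import measure_vq

        drive = ActiveDriveState(np.zeros(64), speed=0.05, persistence=2.0)
        kwargs = dict(dt=0.01, n_steps=20_000, save_every=200, seed=13)
        quiet = run_trajectory(small_packing, drive, **kwargs)
        dividing = run_trajectory(
            small_packing, drive,
            division=DivisionParams(cycle_time=2000.0, target_n=64), **kwargs,
        )
        s1 = measure_vq(quiet.after(20.0), q_max=2.0)
        s2 = measure_vq(dividing.after(20.0), q_max=2.0)
        ratio = s2.values / s1.values
        assert np.median(np.abs(ratio - 1)) < 0.35
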