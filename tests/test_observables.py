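"""Estimators validated against synthetic fixtures with known statistics."""

import warnings

import numpy as np
import pytest

import polychannel as pc
from polychannel import fixtures as fix
from polychannel.observables import _unwrap_chain_z


class TestDriftVelocity:
    def test_exact_on_noiseless_ballistic(self):
        traj = fix.ballistic_trajectory(v=(0, 0, 0.05), n_frames=50, noise_sd=0.0)
        v, _ = pc.com_drift_velocity(traj)
        assert v == pytest.approx(0.05, abs=1e-12)

    def test_noisy_ballistic_within_error(self):
        traj = fix.ballistic_trajectory(
            v=(0, 0, 0.05), n_frames=400, noise_sd=0.3, seed=9, n_particles=4
        )
        v, err = pc.com_drift_velocity(traj)
        assert err > 0
        assert abs(v - 0.05) < 4 * err

    def test_time_reversal_negates(self):
        traj = fix.ballistic_trajectory(v=(0, 0, 0.02), n_frames=30, noise_sd=0.0)
        rev = fix.ballistic_trajectory(v=(0, 0, -0.02), n_frames=30, noise_sd=0.0)
        assert pc.com_drift_velocity(traj)[0] == pytest.approx(
            -pc.com_drift_velocity(rev)[0], abs=1e-12
        )

    def test_too_few_frames_raises(self):
        traj = fix.ballistic_trajectory(v=(0, 0, 0.05), n_frames=5)
        traj.times = traj.times[:1]
        traj.positions = traj.positions[:1]
        traj.offsets = traj.offsets[:1]
        traj.velocities = traj.velocities[:1]
        with pytest.raises(ValueError):
            pc.com_drift_velocity(traj)

    def test_z_translation_invariance(self):
        traj = fix.ballistic_trajectory(v=(0, 0, 0.03), n_frames=40, noise_sd=0.1, seed=3)
        v0 = pc.com_drift_velocity(traj)[0]
        shifted = fix.ballistic_trajectory(v=(0, 0, 0.03), n_frames=40, noise_sd=0.1, seed=3)
        shifted.offsets = shifted.offsets + 2 * shifted.box_length
        assert pc.com_drift_velocity(shifted)[0] == pytest.approx(v0, abs=1e-12)


class TestFluidVelocityProfile:
    def test_uniform_flow_every_shell(self):
        traj = fix.radial_flow_scene(v0=0.1, ell=1e12, rod_length=8, tracer_density=0.6, seed=1)
        prof = pc.fluid_velocity_profile(traj, r_max=6.0, dr=0.5)
        pop = prof.populated()
        assert pop.any()
        np.testing.assert_allclose(prof.v_z[pop], 0.1, rtol=1e-9)

    def test_exponential_flow_matches_mc_shell_average(self):
        v0, ell = 0.2, 2.0
        traj = fix.radial_flow_scene(
            v0=v0, ell=ell, rod_length=20, tracer_density=3.0, seed=2, r_max=8.0
        )
        dr = 0.5
        prof = pc.fluid_velocity_profile(traj, r_max=6.0, dr=dr)
        # independent Monte-Carlo oracle: fresh uniform tracers, brute-force
        # minimum distance to the same rod, same prescribed field
        rng = np.random.default_rng(77)
        rod = traj.positions[0, traj.indices("M")]
        Lz = traj.box_length
        n = 200_000
        rho = 8.0 * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(0, Lz, n)
        pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
        d = pts[:, None, :] - rod[None, :, :]
        d[:, :, 2] -= Lz * np.round(d[:, :, 2] / Lz)
        dmin = np.sqrt((d**2).sum(-1)).min(axis=1)
        vz = v0 * np.exp(-dmin / ell)
        for k in np.flatnonzero(prof.populated()):
            lo, hi = prof.r[k], prof.r[k] + dr
            sel = (dmin >= lo) & (dmin < hi)
            if sel.sum() < 100 or prof.counts[k] < 20:
                continue
            oracle = vz[sel].mean()
            oracle_se = vz[sel].std() / np.sqrt(sel.sum())
            se = np.hypot(prof.sem[k], oracle_se)
            assert abs(prof.v_z[k] - oracle) < 3.5 * max(se, 1e-6)

    def test_equidistant_tracer_counted_once(self):
        # one fluid particle exactly between two monomers
        pos = np.array([[[0, 0, 1.0], [0, 0, 3.0], [1.5, 0, 2.0]]])
        traj = pc.Trajectory(
            times=np.array([0.0]),
            positions=pos,
            offsets=np.zeros((1, 3)),
            velocities=np.zeros((1, 3, 3)),
            species=np.array(["M", "M", "S"]),
            charges=np.array([-1.0, -1.0, 0.0]),
            bonds=np.array([[0, 1]]),
            box_length=50.0,
        )
        prof = pc.fluid_velocity_profile(traj, r_max=5.0, dr=0.5)
        assert prof.counts.sum() == 1

    def test_invalid_dr(self):
        traj = fix.radial_flow_scene(v0=0.1, ell=1.0, seed=0)
        with pytest.raises(ValueError):
            pc.fluid_velocity_profile(traj, r_max=5.0, dr=3.0)


class TestCoulombForceOnMonomers:
    def _frame(self, mono, ions, ion_charges):
        n_m, n_i = len(mono), len(ions)
        pos = np.concatenate([mono, ions])
        species = np.array(["M"] * n_m + ["C+" if q > 0 else "C-" for q in ion_charges])
        charges = np.concatenate([-np.ones(n_m), ion_charges])
        return pos, charges, species

    def test_no_ions_in_range(self):
        pos, q, sp = self._frame(
            np.array([[0.0, 0, 0]]), np.array([[10.0, 0, 0]]), np.array([1.0])
        )
        f = pc.coulomb_force_on_monomers(pos, q, sp, Lz=100.0, r_control=5.0)
        np.testing.assert_array_equal(f, 0.0)

    def test_single_counterion_attraction(self):
        pos, q, sp = self._frame(
            np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]), np.array([1.0])
        )
        f = pc.coulomb_force_on_monomers(pos, q, sp, Lz=100.0, r_control=5.0)
        np.testing.assert_allclose(f, [[1.0, 0.0, 0.0]], atol=1e-14)

    def test_growing_control_volume_nests(self):
        rng = np.random.default_rng(0)
        mono = rng.uniform(-1, 1, size=(3, 3))
        ions = rng.uniform(-6, 6, size=(40, 3))
        qi = rng.choice([-1.0, 1.0], size=40)
        pos, q, sp = self._frame(mono, ions, qi)
        Lz = 40.0
        # the set of contributing ions never shrinks as r grows
        def contributing(r):
            d = mono[:, None, :] - ions[None, :, :]
            d[:, :, 2] -= Lz * np.round(d[:, :, 2] / Lz)
            return (np.sqrt((d**2).sum(-1)) < r).sum()

        assert contributing(4.0) <= contributing(8.0)

    def test_monomers_and_solvent_excluded_as_sources(self):
        # two monomers close together: no force without free ions
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, 1.0, 0]])
        species = np.array(["M", "M", "S"])
        charges = np.array([-1.0, -1.0, 0.0])
        f = pc.coulomb_force_on_monomers(pos, charges, species, 100.0, 5.0)
        np.testing.assert_array_equal(f, 0.0)


class TestElectrolyteFriction:
    def test_constant_forces_give_zero(self):
        F = np.ones((2000, 4, 3)) * np.array([1.0, -2.0, 0.5])
        res = pc.electrolyte_friction(F, dt_sample=1.0)
        assert res.xi_total == pytest.approx(0.0, abs=1e-20)

    def test_identical_series_cancel_by_mean_subtraction(self):
        rng = np.random.default_rng(0)
        one = fix.ou_force_series(1.0, 5.0, 0.5, 5000, n_monomers=1, seed=4)
        F = np.repeat(one, 8, axis=1)
        res = pc.electrolyte_friction(F, dt_sample=0.5)
        assert res.xi_total == pytest.approx(0.0, abs=1e-18)

    def test_ou_fixture_matches_analytic_integral(self):
        s, tau_c, dt = 1.0, 10.0, 1.0
        n, N = 200_000, 16
        F = fix.ou_force_series(s, tau_c, dt, n, n_monomers=N, seed=11)
        res = pc.electrolyte_friction(F, dt_sample=dt, lag_cutoff=12 * tau_c)
        expected = 3 * s**2 * tau_c * (1 - 1 / N)  # chain-mean subtraction
        assert res.xi_total == pytest.approx(expected, rel=0.08)

    def test_white_noise_limit_vanishes(self):
        # tau_c -> 0 at fixed variance: the integral 3 s^2 tau_c -> 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F = fix.ou_force_series(1.0, 0.02, 0.003, 100_000, n_monomers=4, seed=5)
            res = pc.electrolyte_friction(F, dt_sample=0.003, lag_cutoff=0.5)
            bigger = fix.ou_force_series(1.0, 2.0, 0.05, 100_000, n_monomers=4, seed=5)
            res2 = pc.electrolyte_friction(bigger, dt_sample=0.05, lag_cutoff=20.0)
        assert abs(res.xi_total) < 0.2  # 3 s^2 tau_c (1 - 1/N) = 0.045
        assert res2.xi_total > 5 * res.xi_total

    def test_running_integral_and_warning(self):
        F = fix.ou_force_series(1.0, 50.0, 1.0, 2000, n_monomers=2, seed=6)
        with pytest.warns(UserWarning, match="plateau"):
            res = pc.electrolyte_friction(F, dt_sample=1.0, lag_cutoff=60.0)
        assert not res.plateaued
        assert len(res.running_integral) == len(res.lags)

    def test_acf_normalization_at_zero_lag(self):
        F = fix.ou_force_series(2.0, 10.0, 1.0, 100_000, n_monomers=8, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pc.electrolyte_friction(F, dt_sample=1.0, lag_cutoff=50.0)
        # residual variance: 3 comps * s^2 * (1 - 1/N)
        assert res.acf[0] == pytest.approx(3 * 4.0 * (1 - 1 / 8), rel=0.05)


class TestFrictionVsRadius:
    def _traj_with_ions(self, ion_dist, n_frames=400):
        """Monomer at origin, one counterion orbit-hopping at fixed distance."""
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(n_frames):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            frames.append([[0.0, 0.0, 25.0], (np.array([0, 0, 25.0]) + ion_dist * u)])
        pos = np.array(frames)
        return pc.Trajectory(
            times=np.arange(n_frames, dtype=float),
            positions=pos,
            offsets=np.zeros((n_frames, 2)),
            velocities=np.zeros((n_frames, 2, 3)),
            species=np.array(["M", "C+"]),
            charges=np.array([-1.0, 1.0]),
            bonds=np.empty((0, 2), dtype=np.intp),
            box_length=50.0,
        )

    def test_ions_beyond_max_radius_zero_curve(self):
        traj = self._traj_with_ions(ion_dist=9.0)
        curve = pc.friction_vs_radius(traj, [1.0, 2.0, 4.0], lag_cutoff=5.0)
        np.testing.assert_array_equal(curve.xi, 0.0)

    def test_every_radius_reported(self):
        traj = self._traj_with_ions(ion_dist=3.0)
        radii = [1.0, 2.0, 4.0, 6.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = pc.friction_vs_radius(traj, radii, lag_cutoff=5.0)
        assert len(curve.xi) == len(radii)
        assert len(curve.results) == len(radii)
        # plateau = mean over the three largest radii
        assert curve.plateau == pytest.approx(np.mean(curve.xi[-3:]))


class TestWallContacts:
    def _traj(self, mono_pos, wall_pos):
        nm = len(mono_pos)
        pos = np.concatenate([mono_pos, wall_pos])[None, :, :]
        species = np.array(["M"] * nm + ["W"] * len(wall_pos))
        return pc.Trajectory(
            times=np.array([0.0]),
            positions=pos,
            offsets=np.zeros((1, len(species))),
            velocities=np.zeros((1, len(species), 3)),
            species=species,
            charges=np.zeros(len(species)),
            bonds=np.empty((0, 2), dtype=np.intp),
            box_length=20.0,
        )

    def test_chain_on_axis_zero(self):
        mono = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
        wall = np.array([[6.0, 0, z] for z in range(20)])
        c, _ = pc.wall_contacts(self._traj(mono, wall))
        assert c == 0.0

    def test_single_contact_counted(self):
        mono = np.array([[5.0, 0.0, 3.0], [0.0, 0.0, 5.0]])
        wall = np.array([[6.0, 0.0, 3.0]])
        c, _ = pc.wall_contacts(self._traj(mono, wall))
        assert c == pytest.approx(0.5)  # 1 contact / N=2

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        mono = rng.uniform(0, 5, size=(10, 3))
        wall = rng.uniform(0, 5, size=(50, 3))
        traj = self._traj(mono, wall)
        values = [pc.wall_contacts(traj, cutoff=c)[0] for c in (0.5, 1.0, 2.0, 4.0)]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestChainExtension:
    def _rod_traj(self, axis, N=10, b=1.0, Lz=50.0, z0=0.0):
        pos = np.zeros((N, 3))
        pos[:, axis] = b * np.arange(N)
        pos[:, 2] += z0
        pos[:, 2] %= Lz
        return pc.Trajectory(
            times=np.array([0.0]),
            positions=pos[None],
            offsets=np.zeros((1, N)),
            velocities=np.zeros((1, N, 3)),
            species=np.array(["M"] * N),
            charges=-np.ones(N),
            bonds=np.column_stack([np.arange(N - 1), np.arange(1, N)]),
            box_length=Lz,
        )

    def test_rod_along_z(self):
        ext, _ = pc.chain_extension(self._rod_traj(axis=2), b=1.0)
        assert ext == pytest.approx(0.9)  # (N-1) b / (b N)

    def test_rod_along_x_has_zero_z_extent(self):
        ext, _ = pc.chain_extension(self._rod_traj(axis=0), b=1.0)
        assert ext == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance_across_boundary(self):
        a = pc.chain_extension(self._rod_traj(axis=2, z0=0.0), b=1.0)[0]
        b = pc.chain_extension(self._rod_traj(axis=2, z0=45.0), b=1.0)[0]  # wraps
        assert a == pytest.approx(b, abs=1e-12)

    def test_unwrap_walk(self):
        z = np.array([48.0, 49.0, 0.0, 1.0])  # crosses the boundary of Lz=50
        unwrapped = _unwrap_chain_z(z, 50.0)
        np.testing.assert_allclose(unwrapped, [48, 49, 50, 51])


class TestDensityMap:
    def test_ideal_gas_flat_and_conserving(self, rng):
        spec = pc.ChannelSpec(mean_radius=5.0, harmonic=0, box_length=30.0)
        system = pc.fixtures.ideal_gas_scene(2.0, spec, seed=8)
        from polychannel.io import system_to_trajectory

        traj = system_to_trajectory(system)
        H, xe, ye = pc.density_map(traj, "S", extent=6.0, bins=24)
        # total integral * box length = particle count
        bin_area = (xe[1] - xe[0]) ** 2
        total = H.sum() * bin_area * traj.box_length
        assert total == pytest.approx(len(system.positions), rel=1e-9)
        # interior bins flat within Poisson noise
        xc = 0.5 * (xe[:-1] + xe[1:])
        X, Y = np.meshgrid(xc, xc, indexing="ij")
        interior = np.hypot(X, Y) < 3.5
        counts = H[interior] * bin_area * traj.box_length
        mean = counts.mean()
        assert np.all(np.abs(counts - mean) < 5 * np.sqrt(mean))

    def test_absent_species_zero_map(self):
        traj = fix.ballistic_trajectory(v=(0, 0, 0.1), n_frames=3)
        H, _, _ = pc.density_map(traj, "C+", extent=2.0, bins=5)
        assert np.all(H == 0.0)


class TestBlockError:
    def test_uncorrelated_series_scaling(self, rng):
        x = rng.normal(size=10000)
        be = pc.block_error(x, n_blocks=10)
        naive = x.std() / np.sqrt(len(x))
        assert 0.3 * naive < be < 3 * naive

    def test_short_series_nan(self):
        assert np.isnan(pc.block_error(np.arange(5.0), n_blocks=10))
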