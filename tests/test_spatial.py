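import numpy as np
import pytest

from swimtrap import (Trajectory, Trap, mean_tangential_flux, msd,
                      occupancy_flux, radial_density,
                      tangential_flux_profile)
from swimtrap.errors import GeometryError
from conftest import make_circle


class TestOccupancyFlux:
    def test_single_point_occupancy_no_flux(self, disk_trap):
        t = np.arange(50) * 0.002
        traj = Trajectory(t, np.full(50, 5.0), np.full(50, -3.0), 0.002,
                          trap=disk_trap)
        field = occupancy_flux(traj, n_bins=15)
        assert np.count_nonzero(field.occupancy) == 1
        assert field.occupancy.sum() == pytest.approx(1.0)
        assert np.all(field.flux == 0.0)

    def test_ccw_orbit_tangential_flux(self, disk_trap):
        # uniform CCW orbit: occupied ring, per-bin flux tangential at ~v0
        r0, om = 40.0, 0.5
        v0 = r0 * om
        traj = make_circle(radius=r0, omega=om, dt=5e-4,
                           duration=2 * np.pi / om, trap=disk_trap)
        field = occupancy_flux(traj, n_bins=31)
        occ = field.occupancy
        tang = field.tangential()
        radii = field.bin_radii()
        assert np.all(np.abs(radii[occ > 0] - r0) < 6.0)
        w = occ[occ > 0]
        t_occ = tang[occ > 0]
        assert np.average(t_occ, weights=w) == pytest.approx(v0, rel=0.05)
        assert mean_tangential_flux(field) == pytest.approx(v0, rel=0.05)

    def test_flux_zero_where_unoccupied(self, disk_trap, rng):
        traj = _random_walk(rng, disk_trap)
        field = occupancy_flux(traj)
        empty = field.occupancy == 0
        assert np.all(field.flux[empty] == 0.0)

    def test_telescoping_conservation(self, disk_trap, rng):
        traj = _random_walk(rng, disk_trap)
        field = occupancy_flux(traj)
        net = (field.occupancy[..., None] * field.flux).sum(axis=(0, 1))
        expected = (traj.positions[-1] - traj.positions[0]) / field.total_time
        np.testing.assert_allclose(net, expected, rtol=1e-9, atol=1e-12)

    def test_missing_trap(self):
        traj = make_circle()
        with pytest.raises(GeometryError):
            occupancy_flux(traj)

    def test_rotation_covariance(self, disk_trap, rng):
        """Rotating the trajectory rotates flux vectors and leaves P(r),
        MSD and the tangential profile unchanged."""
        traj = _random_walk(rng, disk_trap)
        a = 0.7
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        pos = traj.positions @ R.T
        rot = Trajectory(traj.times, pos[:, 0], pos[:, 1],
                         traj.frame_interval, trap=disk_trap)
        f0 = occupancy_flux(traj, n_bins=12)
        f1 = occupancy_flux(rot, n_bins=12)
        net0 = (f0.occupancy[..., None] * f0.flux).sum(axis=(0, 1))
        net1 = (f1.occupancy[..., None] * f1.flux).sum(axis=(0, 1))
        np.testing.assert_allclose(net1, R @ net0, rtol=1e-9, atol=1e-12)
        d0, d1 = radial_density(traj), radial_density(rot)
        np.testing.assert_allclose(d1.P, d0.P, atol=1e-12)
        m0, m1 = msd(traj), msd(rot)
        np.testing.assert_allclose(m1.msd, m0.msd, rtol=1e-9, atol=1e-9)


class TestTangentialProfile:
    def test_ccw_orbit_positive_at_r0(self, disk_trap):
        r0, om = 40.0, 0.5
        traj = make_circle(radius=r0, omega=om, dt=5e-4,
                           duration=2 * np.pi / om, trap=disk_trap)
        prof = tangential_flux_profile(occupancy_flux(traj, n_bins=31),
                                       n_annuli=6)
        k = np.nanargmax(np.abs(np.where(np.isnan(prof.flux_t), 0,
                                         prof.flux_t)))
        assert prof.flux_t[k] == pytest.approx(r0 * om, rel=0.1)
        assert prof.flux_t[k] > 0

    def test_cw_orbit_negated(self, disk_trap):
        r0, om = 40.0, 0.5
        ccw = make_circle(radius=r0, omega=om, dt=5e-4,
                          duration=2 * np.pi / om, trap=disk_trap)
        cw = Trajectory(ccw.times, ccw.x, -ccw.y, ccw.frame_interval,
                        trap=disk_trap)
        p_ccw = tangential_flux_profile(occupancy_flux(ccw, n_bins=31))
        p_cw = tangential_flux_profile(occupancy_flux(cw, n_bins=31))
        np.testing.assert_allclose(p_cw.flux_t, -p_ccw.flux_t, rtol=1e-9,
                                   atol=1e-12)

    def test_empty_annuli_nan(self, disk_trap):
        traj = make_circle(radius=55.0, omega=1.0, trap=disk_trap)
        prof = tangential_flux_profile(occupancy_flux(traj), n_annuli=10)
        assert np.isnan(prof.flux_t[0])   # centre annulus never visited


class TestRadialDensity:
    def test_uniform_disk_linear_in_r(self):
        rng = np.random.default_rng(7)
        R = 60.0
        n = 1_000_000
        r = R * np.sqrt(rng.random(n))
        ang = rng.random(n) * 2 * np.pi
        t = np.arange(n) * 0.002
        traj = Trajectory(t, r * np.cos(ang), r * np.sin(ang), 0.002,
                          trap=Trap(0, 0, R))
        dens = radial_density(traj, n_bins=30)
        expected = 2 * dens.r / R ** 2
        assert np.max(np.abs(dens.P - expected)) / expected.max() < 0.03

    def test_normalised(self, disk_trap, rng):
        traj = _random_walk(rng, disk_trap)
        dens = radial_density(traj)
        dr = dens.edges[1] - dens.edges[0]
        assert np.sum(dens.P) * dr == pytest.approx(1.0, abs=1e-6)

    def test_single_radius_single_bin(self, disk_trap):
        traj = make_circle(radius=30.0, omega=1.0, trap=disk_trap)
        dens = radial_density(traj, n_bins=25)
        assert np.count_nonzero(dens.P) == 1
        dr = dens.edges[1] - dens.edges[0]
        assert dens.P.sum() * dr == pytest.approx(1.0)

    def test_outside_points_clipped(self, disk_trap, caplog):
        t = np.arange(10) * 0.002
        traj = Trajectory(t, np.full(10, 65.0), np.zeros(10), 0.002,
                          trap=disk_trap)
        with caplog.at_level("WARNING"):
            dens = radial_density(traj)
        assert "clipped" in caplog.text
        assert dens.P[-1] > 0


class TestMsd:
    def test_ballistic_closed_form(self):
        v = 7.0
        t = np.arange(0.0, 4.0, 0.002)
        traj = Trajectory(t, v * t, np.zeros_like(t), 0.002)
        curve = msd(traj, max_lag_fraction=0.25)
        np.testing.assert_allclose(curve.msd, (v * curve.lags) ** 2,
                                   rtol=1e-8, atol=1e-8)

    def test_stationary_zero(self):
        t = np.arange(0.0, 2.0, 0.002)
        traj = Trajectory(t, np.full_like(t, 2.0), np.full_like(t, -1.0),
                          0.002)
        curve = msd(traj)
        np.testing.assert_allclose(curve.msd, 0.0, atol=1e-10)
        assert curve.msd[0] == 0.0

    def test_uniform_disk_plateau(self):
        # E|x1 - x2|^2 = R^2 for independent uniform points in a disk
        rng = np.random.default_rng(3)
        R = 60.0
        n = 20_000
        r = R * np.sqrt(rng.random(n))
        ang = rng.random(n) * 2 * np.pi
        t = np.arange(n) * 0.002
        traj = Trajectory(t, r * np.cos(ang), r * np.sin(ang), 0.002,
                          trap=Trap(0, 0, R))
        curve = msd(traj, max_lag_fraction=0.25)
        assert curve.plateau() == pytest.approx(R ** 2, rel=0.20)
        assert np.all(curve.msd <= (2 * R) ** 2)


def _random_walk(rng, trap, n=4000):
    steps = rng.normal(0, 0.5, size=(n, 2))
    pos = np.cumsum(steps, axis=0)
    # fold the walk into the disk so all points are inside
    r = np.hypot(pos[:, 0], pos[:, 1])
    scale = np.where(r > trap.radius - 1,
                     (trap.radius - 1) / np.maximum(r, 1e-9), 1.0)
    pos = pos * scale[:, None]
    t = np.arange(n) * 0.002
    return Trajectory(t, pos[:, 0], pos[:, 1], 0.002, trap=trap)
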