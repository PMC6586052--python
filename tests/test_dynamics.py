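"""Spin dynamics: reflection kernel, seeding, conservation laws."""

import numpy as np
import pytest
from scipy.stats import chisquare

from corddiff.dynamics import (
    DisplacementSeries,
    reflect_step,
    run_dynamics,
    seed_walkers,
)
from corddiff.metrics import perpendicular_diffusivity
from corddiff.substrate import Cylinder, Substrate, locate_compartment


class TestReflectStep:
    circle = Cylinder(x=0.0, y=0.0, r_out=2.0, r_in=1.0)

    def test_normal_incidence_reverses(self):
        # radial step from the center: hits the inner wall head-on and the
        # remainder comes straight back along the radius
        pos, rem = reflect_step([0.0, 0.0], [1.5, 0.0], self.circle, "inside")
        assert pos[0] == pytest.approx(1.0)
        assert rem[0] == pytest.approx(-0.5)
        assert rem[1] == 0.0

    def test_step_without_intersection_unchanged(self):
        pos, rem = reflect_step([0.0, 0.0], [0.3, 0.2], self.circle, "inside")
        np.testing.assert_allclose(pos, [0.3, 0.2])
        assert np.all(rem == 0)

    def test_path_length_preserved(self):
        start = np.array([0.5, 0.3])
        step = np.array([0.9, 0.4])
        pos, rem = reflect_step(start, step, self.circle, "inside")
        travelled = np.linalg.norm(pos - start) + np.linalg.norm(rem)
        assert travelled == pytest.approx(np.linalg.norm(step), rel=1e-9)

    def test_outside_reflection_stays_outside(self):
        pos, rem = reflect_step([3.0, 0.1], [-2.0, 0.0], self.circle, "outside")
        assert np.hypot(*pos) >= 2.0


class TestSeeding:
    def test_area_weighting_across_disks(self):
        sub = Substrate(
            L=40.0, g=1.0, centers=np.array([[10.0, 10.0], [30.0, 30.0]]),
            r_out=np.array([1.0, 2.0]),
        )
        ens = seed_walkers(sub, 10000, 0, np.random.default_rng(0))
        frac_small = np.mean(ens.cyl_index == 0)
        assert frac_small == pytest.approx(0.2, abs=0.015)

    def test_intra_walkers_inside_inner_circles(self):
        sub = Substrate(
            L=20.0, g=0.75, centers=np.array([[10.0, 10.0]]), r_out=np.array([3.0])
        )
        ens = seed_walkers(sub, 500, 0, np.random.default_rng(1))
        assert all(locate_compartment(ens.positions, sub) == "intra")

    def test_extra_walkers_outside_outer_circles(self):
        sub = Substrate(
            L=20.0, g=0.75, centers=np.array([[10.0, 10.0]]), r_out=np.array([3.0])
        )
        ens = seed_walkers(sub, 0, 500, np.random.default_rng(2))
        assert all(locate_compartment(ens.positions, sub) == "extra")

    def test_same_seed_identical(self):
        sub = Substrate(
            L=20.0, g=0.75, centers=np.array([[10.0, 10.0]]), r_out=np.array([3.0])
        )
        e1 = seed_walkers(sub, 100, 100, np.random.default_rng(3))
        e2 = seed_walkers(sub, 100, 100, np.random.default_rng(3))
        np.testing.assert_array_equal(e1.positions, e2.positions)

    def test_no_intra_space_raises(self):
        sub = Substrate(L=20.0, g=0.75, centers=np.empty((0, 2)), r_out=np.empty(0))
        with pytest.raises(ValueError):
            seed_walkers(sub, 10, 0, np.random.default_rng(0))


class TestFreeDiffusion:
    def test_msd_slope_matches_d0(self, free_diffusion_series):
        d = perpendicular_diffusivity(free_diffusion_series)
        np.testing.assert_allclose(d, 2.0, rtol=0.02)

    def test_isotropy(self, free_diffusion_series):
        s = free_diffusion_series
        for comp in (s.dx, s.dy):
            m = comp[:, -1].mean()
            se = comp[:, -1].std() / np.sqrt(comp.shape[0])
            assert abs(m) < 3 * se
        dx_var = s.dx[:, -1].var()
        dy_var = s.dy[:, -1].var()
        se = dx_var * np.sqrt(2.0 / s.dx.shape[0]) * np.sqrt(2)
        assert abs(dx_var - dy_var) < 3 * se


class TestConfinement:
    def test_intra_walker_never_leaves_cylinder(self, single_cylinder_series):
        s = single_cylinder_series
        # displacement between two points inside a disk of radius r is < 2r
        assert np.max(np.hypot(s.dx, s.dy)) <= 2 * 2.66 + 1e-9

    def test_single_cylinder_long_time_msd_is_r_squared(self, single_cylinder_series):
        s = single_cylinder_series
        msd = np.mean(s.dx[:, -1] ** 2 + s.dy[:, -1] ** 2)
        assert msd == pytest.approx(2.66**2, rel=0.03)

    def test_displacements_zero_at_t0(self):
        sub = Substrate(
            L=20.0, g=1.0, centers=np.array([[10.0, 10.0]]), r_out=np.array([2.0]),
            d_in0=2.0,
        )
        ens = seed_walkers(sub, 200, 0, np.random.default_rng(0))
        s = run_dynamics(sub, ens, 10.0, 1000, sample_times=[0, 5, 10], seed=0)[0]
        assert np.all(s.dx[:, 0] == 0) and np.all(s.dy[:, 0] == 0)

    def test_equilibrium_density_stays_uniform(self):
        """~10⁶ reflection-bearing steps must not distort the uniform
        equilibrium density inside a disk (χ² on an equal-area histogram)."""
        sub = Substrate(
            L=10.0, g=1.0, centers=np.array([[5.0, 5.0]]), r_out=np.array([1.0]),
            d_in0=2.0,
        )
        ens = seed_walkers(sub, 2000, 0, np.random.default_rng(9))
        s = run_dynamics(sub, ens, 5.0, 500, sample_times=[5.0], seed=9)[0]
        start = ens.positions - 5.0
        final = start + np.c_[s.dx[:, -1], s.dy[:, -1]]
        r = np.hypot(final[:, 0], final[:, 1])
        edges = np.sqrt(np.linspace(0, 1, 11))  # equal-area annuli
        counts, _ = np.histogram(r, bins=edges)
        assert chisquare(counts).pvalue > 0.01


class TestEngineContracts:
    def test_deterministic_given_seed(self):
        sub = Substrate(
            L=20.0, g=1.0, centers=np.array([[10.0, 10.0]]), r_out=np.array([2.0]),
            d_in0=1.0,
        )
        ens = seed_walkers(sub, 50, 50, np.random.default_rng(1))
        a = run_dynamics(sub, ens, 5.0, 500, sample_times=[5.0], seed=11)
        b = run_dynamics(sub, ens, 5.0, 500, sample_times=[5.0], seed=11)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.dx, sb.dx)

    def test_invalid_duration(self):
        sub = Substrate(L=20.0, g=1.0, centers=np.empty((0, 2)), r_out=np.empty(0))
        ens = seed_walkers(sub, 0, 10, np.random.default_rng(0))
        with pytest.raises(ValueError):
            run_dynamics(sub, ens, -1.0, 100)

    def test_short_time_diffusivity_near_intrinsic(self):
        # before walkers feel the walls, D⊥(t) ≈ D₀ in both compartments;
        # the √t wall correction scales with the surface-to-volume ratio,
        # so probe a large-pore substrate at a few steps' diffusion time
        from corddiff.substrate import make_preset_substrate

        sub = make_preset_substrate(
            "large_axons", "low", seed=6, L=100.0, d_in0=2.0, d_ex0=1.0
        )
        ens = seed_walkers(sub, 4000, 4000, np.random.default_rng(4))
        out = run_dynamics(sub, ens, 0.002, 100, sample_times=[0.001], seed=4)
        for series in out:
            d0 = 2.0 if series.compartment == "intra" else 1.0
            d = perpendicular_diffusivity(series)[0]
            assert d == pytest.approx(d0, rel=0.05), series.compartment

    def test_hdf5_round_trip(self, tmp_path):
        s = DisplacementSeries(
            times=np.array([1.0, 2.0]),
            dx=np.ones((5, 2)),
            dy=np.zeros((5, 2)),
            compartment="intra",
            seed=3,
        )
        p = tmp_path / "walk.h5"
        s.save_hdf5(p)
        back = DisplacementSeries.load_hdf5(p)
        np.testing.assert_array_equal(back.dx, s.dx)
        assert back.compartment == "intra"
        assert back.seed == 3
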