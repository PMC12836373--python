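"""Source rotation, WET ray tracing, and the analytic/MC dose-LET engines."""

import numpy as np
import pytest

import protonpbs as p
from protonpbs.transport import MEV_TO_J, LetAccumulator, rotation_matrix_x


def water_like(dims, spacing, density=1.0):
    sp = np.broadcast_to(np.asarray(spacing, float), (3,)).copy()
    origin = np.array([-0.5 * dims[0] * sp[0], -0.5 * dims[1] * sp[1], 0.0])
    return p.VoxelGrid(origin, sp, np.full(dims, density, dtype=float), "density")


class TestRotation:
    def test_zero_angle_is_identity(self):
        s = p.ParticleState([1.0, 2.0, 3.0], [0.0, 0.0, 1.0], 100.0)
        r = p.rotate_source(s, 0.0)
        np.testing.assert_allclose(r.position, s.position)
        np.testing.assert_allclose(r.direction, s.direction)

    def test_quarter_turn(self):
        s = p.ParticleState([0.0, 1.0, 0.0], [0.0, 0.0, 1.0], 100.0)
        r = p.rotate_source(s, 90.0)
        np.testing.assert_allclose(r.position, [0.0, 0.0, 1.0], atol=1e-12)

    def test_45_degrees_matrix_evaluation(self):
        s = p.ParticleState([0.0, 1.0, 0.0], [0.0, 0.0, 1.0], 100.0)
        r = p.rotate_source(s, 45.0)
        np.testing.assert_allclose(r.position, [0.0, 0.70711, 0.70711], atol=1e-5)

    def test_norms_and_angles_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pos = rng.normal(size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            alpha = rng.uniform(-360.0, 360.0)
            s = p.ParticleState(pos, d, 100.0)
            r = p.rotate_source(s, alpha)
            assert np.linalg.norm(r.position) == pytest.approx(np.linalg.norm(pos), abs=1e-10)
            assert np.linalg.norm(r.direction) == pytest.approx(1.0, abs=1e-10)
            # pairwise angle between position and direction preserved
            assert np.dot(r.position, r.direction) == pytest.approx(np.dot(pos, d), abs=1e-10)

    def test_rotation_matrix_orthonormal(self):
        m = rotation_matrix_x(37.0)
        np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-14)

    def test_nonunit_direction_rejected(self):
        with pytest.raises(ValueError):
            p.ParticleState([0, 0, 0], [0, 0, 2.0], 100.0)


class TestRadiologicalDepth:
    def test_uniform_water_equals_geometric_depth(self):
        g = water_like((20, 20, 100), 2.0)
        wet = p.radiological_depth(g, [0.0, 0.0, 0.0], [0.0, 0.0, 1.0], 150.0)
        assert wet == pytest.approx(15.0, rel=1e-12)

    def test_half_density_slab_hand_sum(self):
        g = water_like((10, 10, 100), 2.0)
        g.values[:, :, 50:] = 0.5  # second half at half density
        wet = p.radiological_depth(g, [0.0, 0.0, 0.0], [0.0, 0.0, 1.0], 200.0)
        assert wet == pytest.approx(0.75 * 20.0, rel=1e-12)

    def test_additivity_over_concatenated_segments(self):
        g = water_like((10, 10, 100), 2.0)
        rng = np.random.default_rng(3)
        g.values *= rng.uniform(0.2, 2.0, g.values.shape)
        entry = np.array([1.0, -2.0, 0.0])
        d = np.array([0.1, 0.05, 1.0])
        d /= np.linalg.norm(d)
        t = 80.0
        total = p.radiological_depth(g, entry, d, 190.0)
        first = p.radiological_depth(g, entry, d, t)
        second = p.radiological_depth(g, entry + t * d, d, 190.0 - t)
        assert first + second == pytest.approx(total, abs=1e-9)

    def test_oblique_ray_through_uniform_grid(self):
        g = water_like((50, 50, 50), 2.0)
        d = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        wet = p.radiological_depth(g, g.origin, d, 60.0)
        assert wet == pytest.approx(6.0, rel=1e-9)

    def test_missing_ray_warns_and_returns_zero(self):
        g = water_like((10, 10, 10), 2.0)
        with pytest.warns(UserWarning):
            wet = p.radiological_depth(g, [1000.0, 0.0, 0.0], [0.0, 0.0, 1.0], 50.0)
        assert wet == 0.0


class TestAnalyticDose:
    def test_peak_depth_matches_bragg_curve(self, water_density_coarse, single_spot_source, erm):
        dose = p.analytic_dose(water_density_coarse, single_spot_source, erm)
        curve = p.depth_dose_from_grid(dose, mode="axis")
        peak_engine = curve.depths[np.argmax(curve.dose)]
        ref = p.bragg_curve(150.0, None, None, erm)
        peak_ref = ref.depths[np.argmax(ref.dose)]
        assert abs(peak_engine - peak_ref) <= 0.1  # one 1 mm voxel

    def test_linearity_in_spot_weight(self, water_density_coarse, erm):
        def run(w):
            src = p.BeamSource(0.0, [0, 0, 0], [p.Spot(100.0, w, fwhm_x_mm=8, fwhm_y_mm=8)])
            return p.analytic_dose(water_density_coarse, src, erm).values

        np.testing.assert_allclose(run(2.0), 2.0 * run(1.0), rtol=1e-12, atol=1e-300)

    def test_entrance_lateral_fwhm_matches_spot(self, erm):
        # 1 mm lateral sampling so the discrete FWHM resolves the spot width
        g = water_like((60, 60, 30), (1.0, 1.0, 1.0))
        src = p.BeamSource(0.0, [0, 0, 0], [p.Spot(150.0, 1.0, fwhm_x_mm=12.0, fwhm_y_mm=12.0)])
        dose = p.analytic_dose(g, src, erm, sigma_mcs=0.0)
        iy = dose.dims[1] // 2
        profile = dose.values[:, iy, 2]  # shallow slice
        x = dose.axis_centers(0)
        fwhm = p.beam_model.profile_fwhm(x, profile)
        assert fwhm == pytest.approx(12.0, rel=0.02)

    def test_out_of_validity_energy_rejected(self, water_density_coarse):
        with pytest.raises(ValueError, match="validity"):
            p.BeamSource(0.0, [0, 0, 0], [p.Spot(500.0, 1.0)])


class TestMcDose:
    def test_same_seed_bit_identical(self, water_density_coarse, single_spot_source):
        d1, l1 = p.mc_dose(water_density_coarse, single_spot_source, n_primaries=2000, seed=5)
        d2, l2 = p.mc_dose(water_density_coarse, single_spot_source, n_primaries=2000, seed=5)
        assert np.array_equal(d1.values, d2.values)
        assert np.array_equal(l1.values, l2.values)

    def test_different_seed_differs(self, water_density_coarse, single_spot_source):
        d1, _ = p.mc_dose(water_density_coarse, single_spot_source, n_primaries=2000, seed=5)
        d2, _ = p.mc_dose(water_density_coarse, single_spot_source, n_primaries=2000, seed=6)
        assert not np.array_equal(d1.values, d2.values)

    def test_energy_bookkeeping_single_pencil(self, water_density_coarse):
        # no straggling, no lateral spread: deposited energy = beam energy
        src = p.BeamSource(0.0, [0, 0, 0], [p.Spot(150.0, 1.0, fwhm_x_mm=0.0, fwhm_y_mm=0.0)])
        dose, _ = p.mc_dose(water_density_coarse, src, n_primaries=1, seed=0, sigma_r_cm=0.0)
        voxmass = water_density_coarse.values * np.prod(water_density_coarse.spacing) * 1e-6
        deposited = float((dose.values * voxmass).sum()) / MEV_TO_J
        assert deposited == pytest.approx(150.0, rel=5e-3)

    def test_dose_conservation_with_straggling(self, water_density_coarse, single_spot_source):
        # sampled ranges scatter the effective initial energy around E0, so
        # conservation holds in the mean (0.5%), not as a hard bound
        dose, _ = p.mc_dose(water_density_coarse, single_spot_source, n_primaries=5000, seed=9)
        voxmass = water_density_coarse.values * np.prod(water_density_coarse.spacing) * 1e-6
        deposited = float((dose.values * voxmass).sum()) / MEV_TO_J
        assert deposited == pytest.approx(150.0, rel=5e-3)

    def test_hard_energy_bound_without_straggling(self, water_density_coarse, single_spot_source):
        dose, _ = p.mc_dose(
            water_density_coarse, single_spot_source, n_primaries=2000, seed=9, sigma_r_cm=0.0
        )
        voxmass = water_density_coarse.values * np.prod(water_density_coarse.spacing) * 1e-6
        deposited = float((dose.values * voxmass).sum()) / MEV_TO_J
        assert deposited <= 150.0 * (1 + 1e-9)
        assert deposited == pytest.approx(150.0, rel=5e-3)

    def test_nonpositive_primaries_rejected(self, water_density_coarse, single_spot_source):
        with pytest.raises(ValueError):
            p.mc_dose(water_density_coarse, single_spot_source, n_primaries=0)

    def test_central_axis_matches_analytic(self, mc_water_run, analytic_water_run):
        mc_axis = p.depth_dose_from_grid(mc_water_run[0], mode="axis")
        an_axis = p.depth_dose_from_grid(analytic_water_run, mode="axis")
        peak = an_axis.dose.max()
        rms = float(np.sqrt(np.mean((mc_axis.dose - an_axis.dose) ** 2)))
        assert rms < 0.02 * peak

    def test_letd_nondecreasing_to_distal_r80(self, mc_water_run, water_density_fine):
        dose, letd = mc_water_run
        idd = p.depth_dose_from_grid(dose, water_density_fine, mode="idd")
        r80 = p.extract_range_metrics(idd).r80
        ix, iy = dose.dims[0] // 2, dose.dims[1] // 2
        col = letd.values[ix, iy, :]
        z = (np.arange(col.size) + 0.5) * dose.spacing[2] / 10.0
        sel = (z <= r80) & (col >= 0)
        assert np.all(np.diff(col[sel]) >= -1e-6)

    def test_rotated_beam_deposits_along_rotated_axis(self, hu_table):
        # 90-degree gantry rotates +z into -y: the beam enters at the +y face
        g = p.VoxelGrid([-50.0, -100.0, -50.0], [2.0, 2.0, 2.0],
                        np.ones((50, 100, 50)), "density")
        src = p.BeamSource(90.0, [0.0, 0.0, 0.0],
                           [p.Spot(100.0, 1.0, fwhm_x_mm=4.0, fwhm_y_mm=4.0)])
        dose, _ = p.mc_dose(g, src, n_primaries=3000, seed=2)
        proj = dose.values.sum(axis=(0, 2))
        y = g.axis_centers(1)
        r0_mm = 10.0 * p.range_from_energy(100.0)
        peak_y = y[np.argmax(proj)]
        assert peak_y == pytest.approx(100.0 - r0_mm, abs=4.0)


class TestHeterogeneityShift:
    def test_upstream_slab_shifts_distal_r80(self, hu_table, erm):
        spacing = (5.0, 5.0, 1.0)
        water = p.densify(p.make_slab_phantom([("water", 20.0)], 10.0, spacing), hu_table)
        stack = p.densify(
            p.make_slab_phantom([("bone", 2.0), ("water", 18.0)], 10.0, spacing), hu_table
        )
        bone_rel = p.hu_to_density(700.0, hu_table)
        extra_wet = 2.0 * (bone_rel - 1.0)  # cm
        src = p.BeamSource(0.0, [0, 0, 0], [p.Spot(150.0, 1.0, fwhm_x_mm=6.0, fwhm_y_mm=6.0)])

        def r80(dose, dens):
            return p.extract_range_metrics(p.depth_dose_from_grid(dose, dens, "idd")).r80

        shift_an = r80(p.analytic_dose(water, src, erm), water) - r80(
            p.analytic_dose(stack, src, erm), stack
        )
        assert shift_an == pytest.approx(extra_wet, abs=0.1)

        mc_w, _ = p.mc_dose(water, src, erm, n_primaries=20000, seed=4)
        mc_s, _ = p.mc_dose(stack, src, erm, n_primaries=20000, seed=4)
        shift_mc = r80(mc_w, water) - r80(mc_s, stack)
        assert shift_mc == pytest.approx(extra_wet, abs=0.1)


class TestLetAccumulator:
    def test_single_contribution_identity(self, water_density_coarse):
        acc = LetAccumulator(water_density_coarse)
        acc.add(np.array([0]), np.array([2.0]), np.array([5.0]))
        letd = p.finalize_letd(acc)
        assert letd.values.ravel()[0] == pytest.approx(5.0)

    def test_weighted_mean_oracle(self, water_density_coarse):
        acc = LetAccumulator(water_density_coarse)
        acc.add(np.array([7, 7]), np.array([1.0, 3.0]), np.array([10.0, 2.0]))
        letd = p.finalize_letd(acc)
        assert letd.values.ravel()[7] == pytest.approx(4.0)

    def test_equal_doses_average(self, water_density_coarse):
        acc = LetAccumulator(water_density_coarse)
        acc.add(np.array([1, 1]), np.array([2.0, 2.0]), np.array([2.0, 4.0]))
        assert p.finalize_letd(acc).values.ravel()[1] == pytest.approx(3.0)

    def test_empty_voxels_carry_sentinel(self, water_density_coarse):
        acc = LetAccumulator(water_density_coarse)
        letd = p.finalize_letd(acc)
        assert np.all(letd.values == float(letd.meta["nodata"]))

    def test_result_bounded_by_contributing_lets(self, water_density_coarse):
        rng = np.random.default_rng(8)
        acc = LetAccumulator(water_density_coarse)
        lets = rng.uniform(1.0, 9.0, 100)
        acc.add(np.zeros(100, dtype=int), rng.uniform(0.1, 2.0, 100), lets)
        v = p.finalize_letd(acc).values.ravel()[0]
        assert lets.min() <= v <= lets.max()

    def test_brute_force_weighted_mean_many_voxels(self, water_density_coarse):
        rng = np.random.default_rng(12)
        n = 5000
        idx = rng.integers(0, 50, n)
        d = rng.uniform(0.0, 1.0, n)
        l = rng.uniform(0.5, 12.0, n)
        acc = LetAccumulator(water_density_coarse)
        acc.add(idx, d, l)
        letd = p.finalize_letd(acc).values.ravel()
        for v in range(50):
            sel = idx == v
            if d[sel].sum() > 0:
                assert letd[v] == pytest.approx(np.sum(d[sel] * l[sel]) / np.sum(d[sel]), rel=1e-9)
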