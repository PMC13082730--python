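"""Hyphoid geometry, the turgid equilibrium solver, and noise models."""

import numpy as np
import pytest
from scipy.optimize import brentq

import tipwall.forward_simulator as fs
from tipwall.shell_model import NondimScheme


class TestHyphoidGeometry:
    def test_apex_limit(self):
        assert fs._hyphoid_x(1e-9, 4.1) == pytest.approx(0.0, abs=1e-12)

    def test_half_radius_value(self):
        # cot(pi/2) = 0 so x(0.5) = -1/a
        assert fs._hyphoid_x(0.5, 4.1) == pytest.approx(-1.0 / 4.1)

    def test_larger_a_is_blunter(self):
        for y in (0.3, 0.5, 0.8):
            assert abs(fs._hyphoid_x(y, 5.7)) < abs(fs._hyphoid_x(y, 4.1))

    def test_outline_monotone_and_scaled(self):
        spec = fs.caulonema(radius=2.0)
        out = fs.hyphoid_outline(spec)
        assert out.shape == (129, 2)
        assert out[0] == pytest.approx([0.0, 0.0], abs=1e-5)
        assert np.all(np.diff(out[:, 1]) > 0)       # radius grows from apex
        assert np.all(np.diff(out[:, 0]) < 0)       # x strictly decreasing
        assert out[-1, 1] == pytest.approx(2.0 * 0.93, rel=1e-3)


class TestModulusProfile:
    def test_constant(self):
        p = fs.ModulusProfile.constant(5.0)
        assert np.all(p.bulk_at(np.array([0.0, 1.0, 3.0]), 3.4) == 5.0)
        assert p.moduli_at(0.0, 3.4).mu_h == pytest.approx(5.0 / 3.0)  # nu = 0.5

    def test_linear_midpoint(self):
        p = fs.ModulusProfile(kind="linear", K_side=6.0, K_tip=2.0, transition_width=1e-3)
        assert p.bulk_at(2.0, 4.0) == pytest.approx(4.0, rel=1e-6)

    def test_nonlinear_closed_form(self):
        p = fs.ModulusProfile(kind="nonlinear", K_side=5.0, K_tip=2.0,
                              transition_mid=0.8, transition_width=0.15)
        z = 0.95
        expected = 2.0 + 3.0 / (1.0 + np.exp(-(z - 0.8) / 0.15))
        assert p.bulk_at(z, 3.4) == pytest.approx(expected)
        # plateaus at the ends
        assert p.bulk_at(0.0, 3.4) == pytest.approx(2.0, abs=0.02)
        assert p.bulk_at(3.4, 3.4) == pytest.approx(5.0, abs=0.01)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            fs.ModulusProfile(kind="constant", K_side=5.0, K_tip=2.0)
        with pytest.raises(ValueError):
            fs.ModulusProfile(kind="linear", K_side=2.0, K_tip=5.0)


class TestForwardSolver:
    def test_equilibrium_self_consistency(self, caul_solution):
        assert caul_solution.max_equilibrium_residual() < 1e-6

    def test_apex_regularity(self, caul_solution):
        st = caul_solution.stations(257)
        assert st["lambda_s"][0] == pytest.approx(st["lambda_theta"][0], rel=1e-6)
        assert st["kappa_s"][0] == pytest.approx(st["kappa_theta"][0], rel=1e-6)

    def test_shank_matches_cylinder_oracle(self, caul_spec):
        """Far-field stretches solve the two scalar cylinder equations."""
        K, nu = 5.0, 0.5
        mu = K * (1 - nu) / (1 + nu)
        prof = fs.ModulusProfile.constant(K, nu=nu)
        spec = fs.HyphoidSpec(a=caul_spec.a, shank_fraction=0.98)
        sol = fs.solve_turgid_outline(spec, prof)
        st = sol.stations(513)
        rho_end = st["r_u"][-1]

        def sig(ls, lt):
            s = 0.5 * mu * (1 / lt**2 - 1 / ls**2) + K * (ls * lt - 1)
            t = 0.5 * mu * (1 / ls**2 - 1 / lt**2) + K * (ls * lt - 1)
            return s, t

        def resid(lt):
            # axial balance fixes sigma_s; circumferential must then match
            ls = brentq(lambda v: sig(v, lt)[0] - lt * rho_end / 2, 0.5, 3.0)
            return sig(ls, lt)[1] - lt * rho_end

        lt_oracle = brentq(resid, 1.0001, 2.0)
        assert st["lambda_theta"][-1] == pytest.approx(lt_oracle, rel=5e-3)

    def test_zero_pressure_is_identity(self, caul_spec):
        sol = fs.solve_turgid_outline(caul_spec, fs.ModulusProfile.constant(5.0),
                                      NondimScheme(P=0.0))
        st = sol.stations(129)
        np.testing.assert_allclose(st["lambda_s"], 1.0, atol=1e-9)
        np.testing.assert_allclose(st["r_t"][1:], st["r_u"][1:], atol=1e-9)

    def test_pressure_monotonicity_of_area_stretch(self, caul_spec):
        prof = fs.ModulusProfile.constant(5.0)
        stretches = []
        for P in (0.5, 1.0, 1.5):
            sol = fs.solve_turgid_outline(caul_spec, prof, NondimScheme(P=P))
            st = sol.stations(65)
            stretches.append(st["lambda_s"] * st["lambda_theta"])
        assert np.all(stretches[1] >= stretches[0] - 1e-9)
        assert np.all(stretches[2] >= stretches[1] - 1e-9)

    def test_rounder_cells_stretch_more_at_apex(self, caul_solution, chlo_solution):
        assert chlo_solution.apex_area_stretch > caul_solution.apex_area_stretch


class TestRevolve:
    def test_station_radius_exact(self):
        mer = np.array([[0.0, 0.0], [-1.0, 0.5], [-2.0, 1.0]])
        pts, sid = fs.revolve_surface(mer, 8)
        assert len(pts) == 1 + 8 + 8
        for i, r in [(1, 0.5), (2, 1.0)]:
            ring = pts[sid == i]
            np.testing.assert_allclose(np.hypot(ring[:, 1], ring[:, 2]), r, atol=1e-12)

    def test_uniform_azimuth(self):
        pts, sid = fs.revolve_surface(np.array([[0.0, 1.0]]), 16)
        th = np.sort(np.arctan2(pts[:, 2], pts[:, 1]))
        np.testing.assert_allclose(np.diff(th), 2 * np.pi / 16, atol=1e-9)


class TestMarkerSets:
    def test_correspondence_and_determinism(self, caul_solution):
        mu_, mt_ = caul_solution.meridians(17)
        a = fs.generate_marker_sets(mu_, mt_, 60, 0.3, np.random.default_rng(5))
        b = fs.generate_marker_sets(mu_, mt_, 60, 0.3, np.random.default_rng(5))
        np.testing.assert_array_equal(a[2], b[2])
        np.testing.assert_allclose(a[0], b[0])
        assert len(np.unique(a[2])) == len(a[2])  # bijection by ids

    def test_min_distance_enforced(self, caul_solution):
        mu_, mt_ = caul_solution.meridians(17)
        pu, pt, ids = fs.generate_marker_sets(mu_, mt_, 40, 0.5, np.random.default_rng(1))
        from scipy.spatial.distance import pdist
        assert pdist(pt).min() >= 0.5 - 1e-12

    def test_zero_min_dist_plain_subset(self, caul_solution):
        mu_, mt_ = caul_solution.meridians(17)
        pu, pt, ids = fs.generate_marker_sets(mu_, mt_, 50, 0.0, np.random.default_rng(2))
        assert len(ids) == 50

    def test_infeasible_combination_warns(self, caul_solution):
        mu_, mt_ = caul_solution.meridians(17)
        with pytest.warns(UserWarning, match="admits only"):
            pu, pt, ids = fs.generate_marker_sets(mu_, mt_, 200, 0.5, np.random.default_rng(3))
        assert len(ids) < 200

    def test_larger_min_dist_gives_larger_triangles(self, caul_spec, caul_solution):
        """Monte-Carlo over seeds: mean triangle area grows with min_dist."""
        from tipwall import ensemble_analysis as ea
        prof = fs.ModulusProfile.constant(5.0)
        areas = {}
        for d, n in [(0.12, 155), (0.42, 55)]:
            vals = []
            for seed in range(3):
                cell = fs.generate_cell(caul_spec, prof, fs.NoiseSpec.preset("none"),
                                        seed=seed, solution=caul_solution,
                                        n_subset=n, min_dist=d)
                run = ea.run_single_cell(cell, ea.RunConfig(n_markers=n, min_dist=d))
                vals.append(run.mean_area)
            areas[d] = np.mean(vals)
        assert areas[0.42] > 2.0 * areas[0.12]


class TestNoise:
    def test_zero_noise_is_identity(self, rng):
        pts = rng.normal(size=(50, 3))
        out = fs.apply_marker_noise(pts, 0.0, 0.0, rng)
        np.testing.assert_array_equal(out, pts)

    def test_sample_sd_matches_specification(self):
        rng = np.random.default_rng(7)
        pts = np.zeros((10000, 3))
        out = fs.apply_marker_noise(pts, 0.002, 0.005, rng)
        assert np.std(out[:, 0]) == pytest.approx(0.002, rel=0.05)
        assert np.std(out[:, 1]) == pytest.approx(0.002, rel=0.05)
        assert np.std(out[:, 2]) == pytest.approx(0.005, rel=0.05)

    def test_low_preset_is_the_printed_software_pair(self):
        low = fs.NoiseSpec.preset("low")
        assert (low.sd_xy_unturgid, low.sd_z_unturgid) == (0.002, 0.005)
        assert (low.sd_xy_turgid, low.sd_z_turgid) == (0.002, 0.005)
        assert low.sd_z_unturgid / low.sd_xy_unturgid == pytest.approx(2.5)

    def test_higher_presets_double_z(self):
        for level in ("medium", "high"):
            n = fs.NoiseSpec.preset(level)
            assert n.sd_z_unturgid == pytest.approx(2.0 * n.sd_xy_unturgid)
            assert n.sd_xy_unturgid > fs.NoiseSpec.preset("low").sd_xy_unturgid

    def test_outline_bias_is_normal_shift(self, rng):
        pts = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        normals = pts.copy()
        out = fs.apply_outline_noise(pts, normals, 0.05, np.random.default_rng(0))
        radii = np.linalg.norm(out, axis=1)
        assert np.allclose(radii, radii[0])
        assert radii[0] == pytest.approx(1.05, abs=0.0501)
        assert abs(radii[0] - 1.0) == pytest.approx(0.05)

    def test_zero_amplitude_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        out = fs.apply_outline_noise(pts, pts, 0.0, rng)
        np.testing.assert_array_equal(out, pts)


class TestCohort:
    def test_reproducible_and_sized(self, caul_spec):
        prof = fs.ModulusProfile.constant(5.0)
        noise = fs.NoiseSpec.preset("low")
        a = fs.generate_cohort(3, caul_spec, prof, noise, seed=9)
        b = fs.generate_cohort(3, caul_spec, prof, noise, seed=9)
        for ca, cb in zip(a, b):
            assert ca.radius == cb.radius
            np.testing.assert_array_equal(ca.markers_turgid, cb.markers_turgid)
        radii = [c.radius for c in a]
        assert all(0.8 <= r <= 1.2 for r in radii)
        assert len(set(radii)) == 3

    def test_single_cell_cohort(self, caul_spec):
        cells = fs.generate_cohort(1, caul_spec, fs.ModulusProfile.constant(5.0),
                                   fs.NoiseSpec.preset("none"), seed=1)
        assert len(cells) == 1

    def test_resample_markers_shares_truth(self, caul_cell):
        rng = np.random.default_rng(3)
        other = fs.resample_markers(caul_cell, rng, n_subset=60, min_dist=0.3)
        assert other.truth is caul_cell.truth
        np.testing.assert_array_equal(other.outline_turgid, caul_cell.outline_turgid)
        assert other.markers_turgid.shape[0] == 60
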