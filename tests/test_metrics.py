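"""Layer metric engine: maps, fovea localization, point/area/volume
measurements and en face attenuation."""

import dataclasses

import numpy as np
import pytest

from retmetrics.geometry import ScanGeometry
from retmetrics.metrics import (AnalysisConfig, EyeMetrics, ThicknessMap,
                                bscan_area, compute_eye_metrics,
                                enface_attenuation, layer_volume,
                                locate_fovea, point_thickness, thickness_map)
from retmetrics.phantom import SurfaceModelParams, generate_surfaces
from retmetrics.surfaces import BoundarySurfaces

from conftest import SMALL_GEO, flat_surfaces, random_valid_surfaces


class TestThicknessMap:
    def test_flat_surfaces_constant_map(self):
        geo = dataclasses.replace(SMALL_GEO, axial_scale=2.0)
        s = flat_surfaces(geo, 100, 120, 150, 200)
        m = thickness_map(s, "ILM-RPE")
        assert np.allclose(m.values, 200.0)  # (200 - 100) * 2 µm

    def test_ez_equal_rpe_gives_zero_map(self):
        s = flat_surfaces(SMALL_GEO, 50, 100, 220, 220)
        assert np.allclose(thickness_map(s, "EZ-RPE").values, 0.0)

    def test_elementwise_oracle_on_random_surfaces(self):
        s = random_valid_surfaces(SMALL_GEO, 11)
        m = thickness_map(s, "ONLHFL-EZ")
        oracle = (s.positions[2] - s.positions[1]) * SMALL_GEO.axial_scale
        assert np.array_equal(m.values, oracle)

    def test_decomposition_identities(self):
        s = random_valid_surfaces(SMALL_GEO, 12)
        total = thickness_map(s, "ILM-RPE").values
        inner = thickness_map(s, "ILM-OPL").values
        outer = thickness_map(s, "ONLHFL-RPE").values
        onl_ez = thickness_map(s, "ONLHFL-EZ").values
        ez_rpe = thickness_map(s, "EZ-RPE").values
        assert np.allclose(total, inner + outer, atol=1e-9)
        assert np.allclose(outer, onl_ez + ez_rpe, atol=1e-9)

    def test_unknown_pair_rejected(self):
        s = flat_surfaces(SMALL_GEO, 50, 100, 220, 230)
        with pytest.raises(ValueError, match="layer pair"):
            thickness_map(s, "ILM-EZ")


class TestFovea:
    def test_centered_pit_found_at_center(self):
        s = generate_surfaces(SMALL_GEO, SurfaceModelParams(
            perturbation_sd=0.0, nasal_temporal_asymmetry=0.0))
        f = locate_fovea(s)
        assert abs(f.x_mm) <= SMALL_GEO.pitch_x
        assert abs(f.y_mm) <= SMALL_GEO.pitch_y
        assert not f.flagged

    def test_offset_pit_found_within_one_cell(self):
        s = generate_surfaces(SMALL_GEO, SurfaceModelParams(
            pit_center_offset=(0.5, 0.25), perturbation_sd=0.0))
        f = locate_fovea(s)
        assert abs(f.x_mm - 0.5) <= SMALL_GEO.pitch_x
        assert abs(f.y_mm - 0.25) <= SMALL_GEO.pitch_y

    def test_flat_inner_retina_returns_center_flagged(self):
        s = flat_surfaces(SMALL_GEO, 50, 150, 250, 280)
        f = locate_fovea(s)
        assert f.flagged
        assert abs(f.x_mm) <= SMALL_GEO.pitch_x


class TestPointThickness:
    def test_constant_map_any_offset(self):
        s = flat_surfaces(SMALL_GEO, 0, 50, 80, 0 + 200 / SMALL_GEO.axial_scale)
        m = ThicknessMap(np.full(SMALL_GEO.enface_shape, 200.0), "ILM-RPE",
                         SMALL_GEO)
        f = locate_fovea(s)
        for off in (-2.0, -1.0, 0.0, 1.0, 2.5):
            assert point_thickness(m, f, off, "OD") == pytest.approx(200.0)

    def test_laterality_flip_swaps_nasal_and_temporal(self):
        # the same physical map read as the other eye: nasal becomes temporal
        rng = np.random.default_rng(3)
        vals = rng.uniform(100, 300, SMALL_GEO.enface_shape)
        m = ThicknessMap(vals, "ILM-RPE", SMALL_GEO)
        from retmetrics.metrics import FoveaLocation
        xi = SMALL_GEO.n_ascans_x // 2 - 3
        x_mm = SMALL_GEO.x_mm()
        f = FoveaLocation(xi, 5, float(x_mm[xi]), float(SMALL_GEO.y_mm()[5]))
        assert point_thickness(m, f, +1.0, "OD") == pytest.approx(
            point_thickness(m, f, -1.0, "OS"), abs=1e-9)

    def test_mirrored_grid_swaps_nasal_and_temporal(self):
        # mirroring the surfaces grid along x (same laterality) swaps sides
        rng = np.random.default_rng(4)
        vals = rng.uniform(100, 300, SMALL_GEO.enface_shape)
        m = ThicknessMap(vals, "ILM-RPE", SMALL_GEO)
        m_mirror = ThicknessMap(vals[::-1, :].copy(), "ILM-RPE", SMALL_GEO)
        from retmetrics.metrics import FoveaLocation
        nx = SMALL_GEO.n_ascans_x
        x_mm, y5 = SMALL_GEO.x_mm(), float(SMALL_GEO.y_mm()[5])
        xi = nx // 2 - 3
        xj = nx - 1 - xi  # cell centers are symmetric about the cube center
        f = FoveaLocation(xi, 5, float(x_mm[xi]), y5)
        f_mirror = FoveaLocation(xj, 5, float(x_mm[xj]), y5)
        assert point_thickness(m, f, +1.0, "OD") == pytest.approx(
            point_thickness(m_mirror, f_mirror, -1.0, "OD"), abs=1e-9)

    def test_analytic_pit_profile_at_one_millimetre(self):
        params = SurfaceModelParams(perturbation_sd=0.0,
                                    nasal_temporal_asymmetry=0.0)
        geo = ScanGeometry(n_ascans_x=512, n_bscans_y=96, n_axial_z=320,
                           axial_scale=2.0)
        s = generate_surfaces(geo, params)
        m = thickness_map(s, "ILM-OPL")
        f = locate_fovea(s)
        got = point_thickness(m, f, 1.0, "OD")
        y_mm = geo.y_mm()[f.y_index]
        r2 = 1.0 ** 2 + y_mm ** 2
        expected = (params.inner_thickness_peripheral - params.pit_depth
                    * np.exp(-r2 / (2 * params.pit_radius ** 2)))
        assert got == pytest.approx(expected, abs=0.5)

    def test_offset_beyond_extent_rejected(self):
        m = ThicknessMap(np.full(SMALL_GEO.enface_shape, 100.0), "ILM-RPE",
                         SMALL_GEO)
        from retmetrics.metrics import FoveaLocation
        f = FoveaLocation(48, 6, 0.03125, 0.25)
        with pytest.raises(ValueError, match="outside the sampled extent"):
            point_thickness(m, f, 4.0, "OD")


class TestAreaVolume:
    def test_uniform_hundred_micron_area(self):
        # 100 µm over the 6 mm B-scan: 0.1 mm x 6 mm = 0.6 mm^2
        target = 100.0 / SMALL_GEO.axial_scale
        s = flat_surfaces(SMALL_GEO, 50, 50 + target, 200, 250)
        assert bscan_area(s, "ILM-OPL", 3) == pytest.approx(0.6)

    def test_area_matches_riemann_refinement_oracle(self):
        s = random_valid_surfaces(SMALL_GEO, 21)
        area = bscan_area(s, "ONLHFL-EZ", 5)
        profile = thickness_map(s, "ONLHFL-EZ").values[:, 5] / 1000.0
        x = SMALL_GEO.x_mm()
        # dense Riemann sum over the piecewise-linear interpolant with
        # constant extension into the half-cell margins
        fine = np.linspace(-3.0, 3.0, 600001)
        vals = np.interp(fine, x, profile)
        oracle = np.trapezoid(vals, fine)
        assert area == pytest.approx(oracle, abs=1e-6)

    def test_uniform_volume(self):
        # 50 µm over 6x6 mm: 0.05 x 36 = 1.8 mm^3
        target = 50.0 / SMALL_GEO.axial_scale
        s = flat_surfaces(SMALL_GEO, 50, 100, 200, 200 + target)
        assert layer_volume(thickness_map(s, "EZ-RPE")) == pytest.approx(1.8)

    def test_zero_map_zero_volume(self):
        m = ThicknessMap(np.zeros(SMALL_GEO.enface_shape), "EZ-RPE", SMALL_GEO)
        assert layer_volume(m) == 0.0

    def test_volume_matches_brute_force_accumulation(self):
        s = random_valid_surfaces(SMALL_GEO, 22)
        m = thickness_map(s, "ILM-RPE")
        cell = SMALL_GEO.pitch_x * SMALL_GEO.pitch_y
        oracle = 0.0
        for i in range(SMALL_GEO.n_ascans_x):
            for j in range(SMALL_GEO.n_bscans_y):
                oracle += m.values[i, j] / 1000.0 * cell
        assert layer_volume(m) == pytest.approx(oracle, abs=1e-9)

    def test_volume_equals_mean_times_area(self):
        s = random_valid_surfaces(SMALL_GEO, 23)
        m = thickness_map(s, "ONLHFL-RPE")
        assert layer_volume(m) == pytest.approx(
            m.values.mean() / 1000.0 * 36.0, abs=1e-9)


class TestAttenuation:
    def make_map(self, values):
        return ThicknessMap(values, "EZ-RPE", ScanGeometry(n_axial_z=4))

    def test_all_zero_map(self):
        geo = ScanGeometry(n_axial_z=4)
        att, loss = enface_attenuation(
            ThicknessMap(np.zeros(geo.enface_shape), "EZ-RPE", geo))
        assert (att, loss) == (100.0, 100.0)

    def test_constant_fifty_micron_map(self):
        geo = ScanGeometry(n_axial_z=4)
        att, loss = enface_attenuation(
            ThicknessMap(np.full(geo.enface_shape, 50.0), "EZ-RPE", geo))
        assert (att, loss) == (0.0, 0.0)

    def test_counted_cells_on_full_grid(self):
        geo = ScanGeometry(n_axial_z=4)  # 512 x 128 en face grid
        vals = np.full(geo.enface_shape, 50.0)
        flat = vals.ravel()
        flat[:1000] = 10.0
        flat[1000:1500] = 0.0
        att, loss = enface_attenuation(
            ThicknessMap(flat.reshape(geo.enface_shape), "EZ-RPE", geo))
        assert att == pytest.approx(100 * 1500 / 65536)   # 2.2888...%
        assert loss == pytest.approx(100 * 500 / 65536)   # 0.76293...%

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        geo = ScanGeometry(n_axial_z=4)
        vals = rng.uniform(0, 60, geo.enface_shape)
        m = ThicknessMap(vals, "EZ-RPE", geo)
        last = -1.0
        for thr in (5.0, 10.0, 20.0, 40.0):
            att, _ = enface_attenuation(
                m, AnalysisConfig(attenuation_threshold_um=thr))
            assert att >= last
            last = att

    def test_requires_ez_rpe_map(self):
        geo = ScanGeometry(n_axial_z=4)
        m = ThicknessMap(np.zeros(geo.enface_shape), "ILM-RPE", geo)
        with pytest.raises(ValueError, match="EZ-RPE"):
            enface_attenuation(m)


class TestEyeMetrics:
    def test_closed_form_battery_on_analytic_surfaces(self):
        params = SurfaceModelParams(perturbation_sd=0.0,
                                    nasal_temporal_asymmetry=0.0)
        geo = ScanGeometry(n_ascans_x=512, n_bscans_y=96, n_axial_z=320,
                           axial_scale=2.0)
        s = generate_surfaces(geo, params)
        m = compute_eye_metrics(s, "OD")
        # at the fovea the full pit depth is removed from the inner layers
        assert m.ilm_opl_central_um == pytest.approx(
            params.inner_thickness_peripheral - params.pit_depth, abs=1.0)
        assert m.ez_rpe_central_um == pytest.approx(
            params.ez_rpe_thickness, abs=1e-6)
        assert m.onl_rpe_central_um == pytest.approx(
            params.outer_thickness, abs=1e-6)
        # EZ-RPE is constant: volume is exactly thickness x 36 mm^2
        assert m.ez_rpe_volume_mm3 == pytest.approx(
            params.ez_rpe_thickness / 1000.0 * 36.0, abs=1e-9)
        assert m.ez_rpe_area_mm2 == pytest.approx(
            params.ez_rpe_thickness / 1000.0 * 6.0, abs=1e-9)
        assert m.ez_attenuation_pct == 0.0
        assert m.ez_total_loss_pct == 0.0

    def test_ez_equal_rpe_everywhere(self):
        s = flat_surfaces(SMALL_GEO, 50, 120, 250, 250)
        m = compute_eye_metrics(s, "OD")
        assert m.ez_rpe_central_um == 0.0
        assert m.ez_rpe_volume_mm3 == 0.0
        assert m.ez_rpe_area_mm2 == 0.0
        assert m.ez_total_loss_pct == 100.0
        assert m.ez_attenuation_pct == 100.0

    def test_invariant_loss_below_attenuation_enforced(self):
        with pytest.raises(ValueError, match="total loss"):
            EyeMetrics(ez_attenuation_pct=1.0, ez_total_loss_pct=2.0)
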