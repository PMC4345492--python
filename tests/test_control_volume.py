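"""Control-volume theory: screening numbers, wall-pressure force recovery,
aperture behaviour and the compressible transmission delay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afplab import presets
from afplab.control_volume import (
    Aperture,
    BoxGeometry,
    FluidProperties,
    IncompleteSurfaceError,
    PointForcing,
    WallPressureField,
    acoustic_delay,
    afp_number,
    aperture_area_ratio,
    blasius_shear_force,
    compressible_delay_demo,
    integrate_wall_force,
    pressure_sensitivity,
    reynolds_number,
    wall_pressure_point_force,
)

from oracles import blasius_drag_by_integration, image_wall_pressure


class TestScreeningNumbers:
    def test_afp_number_platform_extremes(self):
        # largest enclosure scale / highest force frequency of the platform
        assert afp_number(0.41, 18.0, 340.0) == pytest.approx(0.0217, abs=5e-4)
        assert afp_number(0.41, 18.0, 340.0) <= 0.022

    def test_afp_number_steady_forcing_is_zero(self):
        assert afp_number(0.5, 0.0, 340.0) == 0.0

    def test_afp_number_linear_in_length(self):
        assert afp_number(0.82, 18, 340) == pytest.approx(2 * afp_number(0.41, 18, 340))

    @pytest.mark.parametrize("bad", [(-0.1, 1.0, 340.0), (0.4, 1.0, 0.0)])
    def test_afp_number_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            afp_number(*bad)

    def test_acoustic_delay_is_about_one_ms(self):
        assert acoustic_delay(0.41, 340.0) == pytest.approx(1.206e-3, rel=1e-3)
        assert acoustic_delay(0.0, 340.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        L=st.floats(0.01, 10.0),
        f=st.floats(0.0, 1e3),
        c=st.floats(1.0, 1e4),
    )
    def test_delay_fraction_identity(self, L, f, c):
        # delay * f == AFP number, identically
        _, frac = acoustic_delay(L, c, f)
        assert frac == pytest.approx(afp_number(L, f, c) if L > 0 else f * L / c)

    def test_reynolds_number_platform(self, air):
        # near-wall speed 0.95 m/s over the 0.42 m platform height
        assert reynolds_number(0.95, 0.42, air) == pytest.approx(27_000, rel=0.02)
        assert reynolds_number(0.0, 0.42, air) == 0.0
        assert reynolds_number(1.9, 0.42, air) == pytest.approx(
            2 * reynolds_number(0.95, 0.42, air)
        )

    def test_pressure_sensitivity(self, geom):
        # 2 mN resolution over the horizontal cross-section -> ~0.008 Pa
        assert pressure_sensitivity(2e-3, geom) == pytest.approx(0.008, abs=5e-4)

    @pytest.mark.parametrize(
        "diameter,expected",
        [(0.100, 0.036), (0.175, 0.109), (0.250, 0.223)],
    )
    def test_front_wall_aperture_area_ratios(self, geom, diameter, expected):
        assert aperture_area_ratio(diameter, geom, "front") == pytest.approx(
            expected, abs=5e-4
        )


class TestBlasiusShear:
    def test_zero_speed_gives_zero_drag(self, air):
        assert blasius_shear_force(0.0, 0.42, 0.525, air) == 0.0

    def test_three_halves_power_scaling(self, air):
        d1 = blasius_shear_force(0.5, 0.42, 0.525, air)
        d4 = blasius_shear_force(2.0, 0.42, 0.525, air)
        assert d4 == pytest.approx(8 * d1, rel=1e-9)

    def test_against_boundary_layer_integration(self):
        # independent oracle: integrate the similarity-solution wall shear
        fluid = presets.AIR_25C
        ours = blasius_shear_force(0.95, 0.420, 0.525, fluid)
        oracle = blasius_drag_by_integration(0.95, 0.420, 0.525, fluid.rho, fluid.nu)
        assert ours == pytest.approx(oracle, rel=2e-3)

    def test_shear_is_below_one_percent_of_reference_force(self):
        # the justification for leaving shear un-instrumented
        shear = blasius_shear_force(0.95, 0.420, 0.525, presets.AIR_25C)
        assert shear < 0.01 * 1.0


class TestWallPressure:
    def test_zero_force_gives_zero_field(self, geom, air):
        fld = wall_pressure_point_force(
            geom, PointForcing((0.2, 0.2, 0.2), (0, 0, 0)), air
        )
        assert all(np.all(w["p"] == 0.0) for w in fld.walls.values())

    def test_center_vertical_force_mirror_antisymmetry(self, geom, air):
        center = tuple(geom.lengths / 2)
        fld = wall_pressure_point_force(geom, PointForcing(center, (0, 0, 1.0)), air)
        np.testing.assert_allclose(
            fld.walls["top"]["p"], -fld.walls["bottom"]["p"], atol=1e-12
        )

    def test_source_outside_box_rejected(self, geom, air):
        with pytest.raises(ValueError):
            wall_pressure_point_force(geom, PointForcing((1.0, 0.2, 0.2), (0, 0, 1)), air)

    def test_matches_method_of_images_near_wall(self, geom, air):
        # small instance: spectral field vs image-charge summation on the
        # bottom wall for a near-wall source; gauge (additive constant)
        # removed before comparison
        x0 = np.array([0.26, 0.23, 0.08])
        F = np.array([0.2, -0.1, 1.0])
        sigma = 0.015
        fld = wall_pressure_point_force(
            geom, PointForcing(tuple(x0), tuple(F)), air,
            n_modes=48, grid_resolution=16, source_width=sigma,
        )
        w = fld.walls["bottom"]
        U, V = np.meshgrid(w["u"], w["v"], indexing="ij")
        pts = np.column_stack([U.ravel(), V.ravel(), np.zeros(U.size)])
        p_img = image_wall_pressure(pts, x0, F, geom.lengths, sigma, shells=5)
        p_img = p_img.reshape(U.shape)
        a = w["p"] - w["p"].mean()
        b = p_img - p_img.mean()
        rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2))
        assert rms < 0.01

    def test_uniform_pressure_integrates_to_zero(self, geom):
        # closed-surface identity: a constant pressure exerts no net force
        walls = {}
        for wid in ("left", "right", "front", "back", "bottom", "top"):
            lu, lv = geom.wall_extent(wid)
            u = np.linspace(0, lu, 17)
            v = np.linspace(0, lv, 17)
            walls[wid] = {"u": u, "v": v, "p": np.full((17, 17), 101325.0)}
        fld = WallPressureField(walls=walls)
        np.testing.assert_allclose(integrate_wall_force(fld, geom), 0.0, atol=1e-9)

    def test_missing_wall_raises(self, geom, air):
        fld = wall_pressure_point_force(
            geom, PointForcing((0.2, 0.2, 0.2), (0, 0, 1.0)), air
        )
        del fld.walls["top"]
        with pytest.raises(IncompleteSurfaceError):
            integrate_wall_force(fld, geom)

    def test_force_recovery_randomized(self, geom, air, rng):
        # 20 randomized interior positions and directions, default resolution
        for _ in range(20):
            pos = geom.lengths * rng.uniform(0.15, 0.85, 3)
            F = rng.normal(0.0, 1.0, 3)
            fld = wall_pressure_point_force(
                geom, PointForcing(tuple(pos), tuple(F)), air
            )
            rec = integrate_wall_force(fld, geom)
            assert np.linalg.norm(rec - F) / np.linalg.norm(F) < 1e-3

    def test_force_recovery_converges_monotonically(self, geom, air):
        pos = (0.31, 0.17, 0.22)
        F = np.array([0.4, 0.8, -0.3])
        errs = []
        for n_modes, res in [(8, 16), (16, 32), (32, 64)]:
            fld = wall_pressure_point_force(
                geom, PointForcing(pos, tuple(F)), air,
                n_modes=n_modes, grid_resolution=res, source_width=0.035,
            )
            rec = integrate_wall_force(fld, geom)
            errs.append(np.linalg.norm(rec - F) / np.linalg.norm(F))
        assert errs[0] > errs[1] > errs[2]

    def test_convergence_diagnostic_reports_under_resolution(self, geom, air):
        fld = wall_pressure_point_force(
            geom, PointForcing((0.2, 0.2, 0.2), (0, 0, 1.0)), air,
            n_modes=4, source_width=0.005,
        )
        assert not fld.diagnostics["converged"]


class TestAperture:
    def test_vertical_wall_hole_leaves_vertical_force_unchanged(self, geom, air):
        # the front wall's outward normal is horizontal, so its pressure
        # integral carries no vertical component: removing any disc of it
        # cannot change the recovered vertical force
        forcing = PointForcing((0.26, 0.23, 0.21), (0.0, 0.0, 1.0))
        closed = integrate_wall_force(
            wall_pressure_point_force(geom, forcing, air), geom
        )
        for diameter in (0.100, 0.175, 0.250):
            holed = BoxGeometry(
                geom.Lx, geom.Ly, geom.Lz,
                aperture=Aperture("front", (geom.Lx / 2, geom.Lz / 2), diameter),
            )
            fld = wall_pressure_point_force(holed, forcing, air)
            rec = integrate_wall_force(fld, holed)
            # exact in the model: the holed wall never enters F_z; only
            # float rounding of the atmospheric gauge shift remains
            assert rec[2] == pytest.approx(closed[2], abs=1e-12)

    def test_aperture_must_fit_in_wall(self, geom):
        with pytest.raises(ValueError):
            BoxGeometry(
                geom.Lx, geom.Ly, geom.Lz,
                aperture=Aperture("front", (0.01, 0.01), 0.2),
            )


class TestCompressibleDelay:
    def test_incompressible_limit_has_vanishing_delay_fraction(self):
        geom = BoxGeometry(0.41, 0.41, 0.41)
        center = tuple(geom.lengths / 2)
        forc = PointForcing(center, (0, 0, 1.0), "sinusoid", 18.0)
        fast = FluidProperties(1.2, 1.48e-5, 340.0 * 64)
        res = compressible_delay_demo(
            geom, forc, fast, n_modes=24, duration=8 * 0.41 / fast.c
        )
        assert res.delay_fraction < 1e-3

    def test_delay_fraction_monotone_in_afp_number(self):
        geom = BoxGeometry(0.41, 0.41, 0.41)
        center = tuple(geom.lengths / 2)
        forc = PointForcing(center, (0, 0, 1.0), "sinusoid", 18.0)
        fracs = []
        for target in np.logspace(-3, -1, 5):
            c = 18.0 * 0.41 / target
            fluid = FluidProperties(1.2, 1.48e-5, c)
            res = compressible_delay_demo(
                geom, forc, fluid, n_modes=24, duration=8 * 0.41 / c
            )
            fracs.append(res.delay_fraction)
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_platform_extremes_delay_below_compactness_bound(self):
        # the transmission delay fraction is of the order of, and bounded
        # by, the AFP number (~2% at the platform extremes)
        geom = BoxGeometry(0.41, 0.41, 0.41)
        center = tuple(geom.lengths / 2)
        res = compressible_delay_demo(
            geom,
            PointForcing(center, (0, 0, 1.0), "sinusoid", 18.0),
            FluidProperties(1.2, 1.48e-5, 340.0),
            duration=0.08,
        )
        assert 1e-3 < res.delay_fraction < res.afp_number
        assert res.afp_number == pytest.approx(0.0217, abs=5e-4)

    def test_resonant_forcing_is_flagged(self):
        geom = BoxGeometry(0.41, 0.41, 0.41)
        center = tuple(geom.lengths / 2)
        f_mode1 = 340.0 / (2 * 0.41)  # first axial acoustic mode
        res = compressible_delay_demo(
            geom,
            PointForcing(center, (0, 0, 1.0), "sinusoid", f_mode1 * 1.002),
            FluidProperties(1.2, 1.48e-5, 340.0),
            duration=0.05,
        )
        assert res.resonance_flagged
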