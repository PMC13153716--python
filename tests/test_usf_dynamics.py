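"""Dynamic USF signal/velocity behavior on reduced-scale conditions."""

import numpy as np
import pytest

import usfsim as u
from usfsim.usf_dynamics import pair_kernel, signal_prefactor

C0 = 4.4e-11


@pytest.fixture(scope="module")
def ctx(small_thermal, geometry, optics_ex, optics_fl, sd, agent):
    return dict(
        thermal=small_thermal,
        geom=geometry,
        optics_ex=optics_ex,
        optics_fl=optics_fl,
        sd=sd,
        agent=agent,
    )


def _signal(ctx, cmap):
    return u.usf_signal(
        ctx["thermal"], cmap, ctx["geom"], ctx["optics_ex"], ctx["optics_fl"],
        ctx["sd"], ctx["agent"],
    )


class TestSignal:
    def test_baseline_is_zero_for_every_scenario(self, ctx, small_thermal):
        for tag in ("single_voxel", "two_voxel", "uniform"):
            cmap = u.make_fixture(tag, small_thermal.grid, C0=C0)
            series = _signal(ctx, cmap)
            assert series.phi[0] == 0.0

    def test_linear_in_concentration(self, ctx, small_thermal):
        cmap1 = u.make_fixture("uniform", small_thermal.grid, C0=C0)
        cmap2 = u.make_fixture("uniform", small_thermal.grid, C0=2 * C0)
        s1, s2 = _signal(ctx, cmap1), _signal(ctx, cmap2)
        np.testing.assert_allclose(s2.phi, 2.0 * s1.phi, rtol=1e-10)
        np.testing.assert_allclose(s2.velocity, 2.0 * s1.velocity, rtol=1e-10)

    def test_single_voxel_reduces_to_one_term(self, ctx, small_thermal):
        # the volume sum collapses to w * [Q(T_focal) - Q(T_BG)]
        cmap = u.make_fixture("single_voxel", small_thermal.grid, C0=C0)
        series = _signal(ctx, cmap)
        grid = small_thermal.grid
        kern = pair_kernel(
            np.zeros((1, 3)), ctx["geom"], ctx["optics_ex"], ctx["optics_fl"],
            clamp=0.5 * np.sqrt(grid.dx**2 + grid.dy**2 + grid.dz**2),
        )
        K = signal_prefactor(ctx["optics_ex"], ctx["optics_fl"], ctx["sd"])
        w = K * C0 * grid.voxel_volume * kern.item()
        trace = small_thermal.focal_trace()
        agent = ctx["agent"]
        expected = w * (
            u.quantum_yield(agent.T_BG + trace, agent) - u.quantum_yield(agent.T_BG, agent)
        )
        np.testing.assert_allclose(
            series.phi, expected, rtol=1e-6, atol=1e-9 * np.max(np.abs(expected))
        )

    def test_single_voxel_plateau_shape(self, ctx, small_thermal):
        cmap = u.make_fixture("single_voxel", small_thermal.grid, C0=C0)
        n = _signal(ctx, cmap).normalized()
        t = n.t
        # sharp rise to a plateau before the exposure ends, held past it
        assert n.phi[np.argmin(np.abs(t - 0.397))] >= 0.99
        assert n.phi[np.argmin(np.abs(t - 0.521))] >= 0.99
        # monotone while focal temperature is rising
        heating = t <= 0.4
        assert np.all(np.diff(n.phi[heating]) >= -1e-12)

    def test_uniform_map_rises_then_falls_at_exposure_end(self, ctx, small_thermal):
        cmap = u.make_fixture("uniform", small_thermal.grid, C0=C0)
        n = _signal(ctx, cmap).normalized()
        t = n.t
        heating = (t > 0) & (t <= 0.4)
        assert np.all(np.diff(n.phi[t <= 0.4]) > 0)  # keeps growing, no saturation
        i_end = int(np.argmin(np.abs(t - 0.4)))
        assert np.argmax(n.phi) == i_end  # peak right at exposure end
        assert n.phi[i_end + 1] < n.phi[i_end]  # falls immediately after

    def test_mirror_term_present_and_subtractive(self, ctx, small_thermal):
        grid = small_thermal.grid
        pts = np.zeros((1, 3))
        _, G_ex = u.excitation_fluence(ctx["geom"], ctx["optics_ex"], 1.0, pts)
        G_fl = u.emission_green(pts, ctx["geom"].detector_point, ctx["optics_fl"])
        G_fl_i = u.emission_green(
            ctx["geom"].mirror(pts), ctx["geom"].detector_point, ctx["optics_fl"]
        )
        kern = pair_kernel(pts, ctx["geom"], ctx["optics_ex"], ctx["optics_fl"])
        image = (G_ex * G_fl_i).item()
        real = (G_ex * G_fl).item()
        assert kern.item() == pytest.approx(real - image, rel=1e-12)
        assert 0 < image < real  # present, subtracted, smaller than the real term

    def test_quadrature_convergence_on_refined_grid(self, ctx, geometry, optics_ex, optics_fl, sd, agent, tissue):
        # same physical concentration block and confinement temperature field,
        # integrated on a grid and its 2x refinement
        spec = u.TransducerSpec(Pa=2.4e6, a_bar=0.5e-3, f=2.5e6, c0=1540.0, focus_depth=10e-3)
        alpha = u.alpha_np_from_db(58.0, 2.5)
        phis = []
        for factor in (1, 2):
            g = u.CartesianGrid(
                dx=100e-6 / factor, dy=100e-6 / factor, dz=350e-6 / factor,
                Lx=1.5e-3, Ly=1.5e-3, Lz=3.5e-3,
            )
            field = u.evaluate_pressure(g, spec, alpha)
            src = u.heating_source(field, alpha, 1064.0, 1540.0, 0.4)
            dT = u.confinement_temperature(src, tissue, 0.3)
            thermal = u.ThermalField(
                grid=g, times=np.array([0.0, 0.3]),
                dT=np.stack([np.zeros(g.shape), dT]), T_BG=tissue.T_BG,
            )
            cmap = u.make_fixture("uniform", g, C0=C0)
            series = u.usf_signal(thermal, cmap, geometry, optics_ex, optics_fl, sd, agent)
            phis.append(series.phi[1])
        assert abs(phis[1] - phis[0]) / abs(phis[1]) < 0.02


class TestVelocity:
    def test_constant_signal_has_zero_velocity(self):
        s = u.USFTimeSeries(t=np.linspace(0, 1, 11), phi=np.full(11, 3.3))
        np.testing.assert_allclose(s.velocity, 0.0, atol=1e-12)

    def test_numeric_and_analytic_modes_agree(self, ctx, small_thermal):
        cmap = u.make_fixture("single_voxel", small_thermal.grid, C0=C0)
        series = _signal(ctx, cmap)
        v_num, _ = u.usf_velocity(series, mode="numeric")
        v_ana, _ = u.usf_velocity(
            series, mode="analytic", thermal=small_thermal, cmap=cmap,
            geom=ctx["geom"], optics_ex=ctx["optics_ex"], optics_fl=ctx["optics_fl"],
            sd=ctx["sd"], agent=ctx["agent"],
        )
        heating = (series.t > 0.02) & (series.t < 0.38)
        scale = np.max(np.abs(v_ana[heating]))
        assert np.max(np.abs(v_num[heating] - v_ana[heating])) / scale < 0.03

    def test_velocity_pulse_peaks_at_midpoint_crossing(self, ctx, small_thermal):
        cmap = u.make_fixture("single_voxel", small_thermal.grid, C0=C0)
        series = _signal(ctx, cmap)
        v = series.velocity
        t = series.t
        trace = small_thermal.focal_trace()
        agent = ctx["agent"]
        t_cross = np.interp(agent.T_M - agent.T_BG, trace[t <= 0.4], t[t <= 0.4])
        assert t[np.argmax(v)] == pytest.approx(t_cross, abs=0.04)
        # broader, negative pulse during cooling
        cooling = t > 0.45
        assert v[cooling].min() < 0
        assert abs(v[cooling].min()) < v.max()

    def test_too_few_snapshots_refused(self):
        s = u.USFTimeSeries(t=np.array([0.0, 0.1]), phi=np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="3 snapshots"):
            _ = s.velocity


class TestSurfaceMap:
    def test_peak_on_axis_and_reflection_symmetry(self, ctx, small_thermal):
        cmap = u.make_fixture("single_voxel", small_thermal.grid, C0=C0)
        xs = np.linspace(-5e-3, 5e-3, 11)
        raster = np.array([[x, 0.0, -10e-3] for x in xs])
        i_t = int(np.argmin(np.abs(small_thermal.times - 0.397)))
        m = u.surface_map(
            small_thermal, cmap, ctx["geom"], ctx["optics_ex"], ctx["optics_fl"],
            ctx["sd"], ctx["agent"], i_t, raster, normalize=True,
        )
        assert np.argmax(m) == 5  # on-axis detector
        np.testing.assert_allclose(m, m[::-1], rtol=1e-9)

    def test_plateau_maps_nearly_identical(self, ctx, small_thermal):
        cmap = u.make_fixture("single_voxel", small_thermal.grid, C0=C0)
        xs = np.linspace(-4e-3, 4e-3, 9)
        raster = np.array([[x, 0.0, -10e-3] for x in xs])
        maps = []
        for target in (0.397, 0.521):
            i_t = int(np.argmin(np.abs(small_thermal.times - target)))
            maps.append(
                u.surface_map(
                    small_thermal, cmap, ctx["geom"], ctx["optics_ex"],
                    ctx["optics_fl"], ctx["sd"], ctx["agent"], i_t, raster,
                    normalize=True,
                )
            )
        np.testing.assert_allclose(maps[0], maps[1], rtol=0.05)


@pytest.fixture(scope="module")
def times():
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 9)


class TestTwoPoint:
    def test_zero_separation_degenerates(self, small_source, tissue, ctx, times):
        res = u.two_point_experiment(
            0.0, small_source, tissue, ctx["geom"], ctx["optics_ex"],
            ctx["optics_fl"], ctx["sd"], ctx["agent"], times,
        )
        assert res["dt_X12"] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res["series_X1"].phi, res["series_X2"].phi)

    def test_offset_point_switches_later_and_weaker(self, small_source, tissue, ctx, times):
        res = u.two_point_experiment(
            0.3e-3, small_source, tissue, ctx["geom"], ctx["optics_ex"],
            ctx["optics_fl"], ctx["sd"], ctx["agent"], times,
        )
        assert res["dt_X12"] > 0
        v1 = res["series_X1"].velocity
        v2 = res["series_X2"].velocity
        assert v2.max() <= v1.max()
        assert res["dt_v"] > 0

    def test_delay_monotone_in_separation(self, small_source, tissue, ctx, times):
        delays = []
        for sep in (0.1e-3, 0.2e-3, 0.3e-3, 0.4e-3):
            res = u.two_point_experiment(
                sep, small_source, tissue, ctx["geom"], ctx["optics_ex"],
                ctx["optics_fl"], ctx["sd"], ctx["agent"], times,
            )
            delays.append(res["dt_X12"])
        assert all(b > a for a, b in zip(delays, delays[1:]))
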