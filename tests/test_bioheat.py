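"""Pennes bioheat solver: closed-form limits, conservation, convergence."""

import numpy as np
import pytest

import usfsim as u


@pytest.fixture(scope="module")
def grid():
    return u.CartesianGrid(dx=100e-6, dy=100e-6, dz=350e-6, Lx=1.5e-3, Ly=1.5e-3, Lz=3.5e-3)


@pytest.fixture(scope="module")
def source(grid):
    spec = u.TransducerSpec(Pa=2.4e6, a_bar=0.5e-3, f=2.5e6, c0=1540.0, focus_depth=10e-3)
    alpha = u.alpha_np_from_db(58.0, 2.5)
    field = u.evaluate_pressure(grid, spec, alpha)
    return u.heating_source(field, alpha, 1064.0, 1540.0, exposure_dt=0.4)


class TestTissueThermal:
    def test_derived_constants(self, tissue):
        assert tissue.alpha_th == pytest.approx(0.6 / (1064 * 4200))
        assert 1.2e-7 <= tissue.alpha_th <= 1.6e-7  # soft-tissue range
        assert tissue.tau == pytest.approx(
            1064 * 4200 / (0.0189 * 1060 * 3780)
        )

    def test_zero_perfusion_gives_infinite_tau(self):
        t = u.TissueThermal(omega_b=0.0)
        assert np.isinf(t.tau)


class TestStableTimestep:
    def test_reference_value(self, tissue):
        g = u.CartesianGrid(dx=50e-6, dy=50e-6, dz=175e-6, Lx=1e-3, Ly=1e-3, Lz=1.75e-3)
        dt = u.stable_timestep(g, tissue, safety=0.9)
        assert dt == pytest.approx(4.0e-3, rel=0.02)

    def test_isotropic_reduction_and_scaling(self, tissue):
        g1 = u.CartesianGrid(dx=200e-6, dy=200e-6, dz=200e-6, Lx=1e-3, Ly=1e-3, Lz=1e-3)
        dt1 = u.stable_timestep(g1, tissue, safety=0.5)
        assert dt1 == pytest.approx(0.5 * g1.dx**2 / (6 * tissue.alpha_th))
        g2 = u.CartesianGrid(dx=100e-6, dy=100e-6, dz=100e-6, Lx=1e-3, Ly=1e-3, Lz=1e-3)
        assert u.stable_timestep(g2, tissue, safety=0.5) == pytest.approx(dt1 / 4)


class TestSolveBioheat:
    def test_initial_condition_and_positivity(self, source, tissue):
        th = u.solve_bioheat(source, tissue, snapshot_times=[0.0, 0.1, 0.2])
        assert np.all(th.dT[0] == 0.0)
        assert np.all(th.dT >= 0.0)
        trace = th.focal_trace()
        assert np.all(np.diff(trace) > 0)  # non-decreasing during heating

    def test_refuses_unstable_step(self, source, tissue):
        with pytest.raises(ValueError, match="stability"):
            u.solve_bioheat(source, tissue, snapshot_times=[0.1], dt=1.0)

    def test_rejects_bad_snapshot_times(self, source, tissue):
        with pytest.raises(ValueError):
            u.solve_bioheat(source, tissue, snapshot_times=[-0.1, 0.1])
        with pytest.raises(ValueError):
            u.solve_bioheat(source, tissue, snapshot_times=[0.2, 0.1])

    def test_no_diffusion_no_perfusion_matches_linear_growth(self, source):
        # kt -> 0, omega_b -> 0 reduces the PDE to dT/dt = H/(rho0 Ct)
        frozen = u.TissueThermal(kt=1e-12, omega_b=0.0)
        th = u.solve_bioheat(source, frozen, snapshot_times=[0.2])
        expected = u.confinement_temperature(source, frozen, 0.2)
        np.testing.assert_allclose(th.dT[0], expected, rtol=1e-5, atol=1e-12)

    def test_pure_perfusion_decay_closed_form(self, source, tissue):
        # prepared field, no conduction, no heating: dT = dT0 exp(-t/tau)
        frozen = u.TissueThermal(kt=1e-12)
        dT0 = u.confinement_temperature(source, frozen, 0.4)
        cold = u.HeatSource(grid=source.grid, H=np.zeros(source.grid.shape), exposure_dt=1e-9)
        th = u.solve_bioheat(cold, frozen, snapshot_times=[5.0], dT0=dT0, dt=0.02)
        np.testing.assert_allclose(
            th.dT[0], dT0 * np.exp(-5.0 / frozen.tau), rtol=1e-3, atol=1e-12
        )

    def test_energy_conservation_without_perfusion(self, source, tissue):
        # insulated boundaries, omega_b = 0: absorbed power == dE/dt
        adiabatic = u.TissueThermal(omega_b=0.0)
        th = u.solve_bioheat(source, adiabatic, snapshot_times=[0.1, 0.3])
        dV = source.grid.voxel_volume
        E = [adiabatic.rho0 * adiabatic.Ct * float(d.sum(dtype=np.float64)) * dV for d in th.dT]
        power_in = float(source.H.sum()) * dV
        measured = (E[1] - E[0]) / 0.2
        assert measured == pytest.approx(power_in, rel=0.01)

    def test_confinement_upper_bounds_the_solution(self, source, tissue):
        times = [0.1, 0.2, 0.3, 0.4]
        th = u.solve_bioheat(source, tissue, snapshot_times=times)
        ci, trace = source.grid.center_index, th.focal_trace()
        for t, val in zip(times, trace):
            bound = u.confinement_temperature(source, tissue, t)[ci]
            assert val <= bound * (1 + 1e-6)

    def test_halving_dt_changes_peak_below_half_percent(self, source, tissue):
        dt = u.stable_timestep(source.grid, tissue, safety=0.9)
        a = u.solve_bioheat(source, tissue, snapshot_times=[0.4], dt=dt)
        b = u.solve_bioheat(source, tissue, snapshot_times=[0.4], dt=dt / 2)
        pa, pb = a.dT[0].max(), b.dT[0].max()
        assert abs(pa - pb) / pb < 0.005

    def test_thermal_fwhm_grows_and_stays_below_pressure_fwhm(self, source, tissue):
        times = [0.149, 0.397]
        th = u.solve_bioheat(source, tissue, snapshot_times=times)
        widths = [u.profile_fwhm(*th.lateral_profile(i)) for i in range(len(times))]
        assert widths[0] < widths[1]
        # during heating the thermal focus is narrower than the acoustic one
        spec = u.TransducerSpec(Pa=2.4e6, a_bar=0.5e-3, f=2.5e6, c0=1540.0, focus_depth=10e-3)
        pf = u.evaluate_pressure(source.grid, spec, u.alpha_np_from_db(58.0, 2.5))
        p_fwhm = u.profile_fwhm(*pf.lateral_profile())
        assert all(w < p_fwhm for w in widths)

    def test_observer_sees_every_snapshot_without_storage(self, source, tissue):
        seen = []
        th = u.solve_bioheat(
            source,
            tissue,
            snapshot_times=[0.0, 0.1, 0.2],
            observer=lambda t, dT: seen.append((t, float(dT.max()))),
            store=False,
        )
        assert [t for t, _ in seen] == [0.0, 0.1, 0.2]
        assert th.dT.shape[0] == 0
        assert seen[0][1] == 0.0 and seen[1][1] > 0.0


class TestConfinementAndPerfusion:
    def test_confinement_examples(self, source):
        tissue = u.TissueThermal()
        dT = u.confinement_temperature(source, tissue, 0.4)
        # H_max ~6.36e7 W/m^3 for 0.4 s gives ~5.7 K
        assert dT.max() == pytest.approx(source.H.max() * 0.4 / (1064 * 4200))
        assert dT.max() == pytest.approx(5.69, rel=0.02)
        assert np.all(u.confinement_temperature(source, tissue, 0.0) == 0.0)
        np.testing.assert_allclose(dT / dT.max(), source.H / source.H.max(), rtol=1e-12)
        with pytest.raises(ValueError, match="exposure"):
            u.confinement_temperature(source, tissue, 0.5)

    def test_perfusion_metrics_reference_values(self, tissue):
        m = u.perfusion_metrics(tissue, 0.4)
        assert m["tau"] == pytest.approx(59.0, rel=0.01)
        assert m["attenuation_fraction"] == pytest.approx(0.007, rel=0.05)
        assert m["L_d"] == pytest.approx(np.sqrt(4 * tissue.alpha_th * 0.4))
        tiny = u.perfusion_metrics(tissue, 1e-9)
        assert tiny["attenuation_fraction"] < 1e-10 and tiny["L_d"] < 1e-7
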