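"""Run configuration, fixtures and figure-style presets.

A :class:`RunConfig` gathers every physical and numerical parameter of a
simulation in validated blocks whose defaults are the canonical
simulation conditions: a 2.5 MHz focused transducer (Pa = 2.4 MPa,
ā = 0.5 mm) focused 10 mm below the tissue surface, soft-tissue acoustic
and thermal constants, an ICG-liposome-like switching agent
(Q0 = 0.05, R0 = 2.6, T_M = 38.7 °C, σ = 1/(3√2) °C), 808/830 nm diffuse
optics, a 0.4 s exposure and a 10 ms snapshot cadence.

Presets assemble the full pipeline (pressure → temperature → switching →
diffusion → signal/velocity or sensitivity) for the standard experiment
layouts and write CSV / TIFF / JSON / HDF5 outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import acoustic_field as ac
from . import analytics as an
from . import bioheat as bh
from . import photon_diffusion as pd_
from . import sensitivity as se
from . import switching as sw
from . import usf_dynamics as dy
from .grids import CartesianGrid

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "make_fixture",
    "run_preset",
    "PRESETS",
]

_SIGMA_DEFAULT = float(1.0 / (3.0 * 2.0**0.5))


@dataclass
class TransducerBlock:
    Pa: float = 2.4e6
    a_bar: float = 0.5e-3
    f: float = 2.5e6
    c0: float = 1540.0
    focus_depth: float = 10e-3


@dataclass
class TissueBlock:
    alpha_db_per_m_mhz: float = 58.0
    alpha_power: float = 2.0
    rho0: float = 1064.0
    rho_b: float = 1060.0
    Ct: float = 4200.0
    Cb: float = 3780.0
    kt: float = 0.6
    omega_b: float = 0.0189
    T_BG: float = 37.0


@dataclass
class NanoagentBlock:
    Q0: float = 0.05
    R0: float = 2.6
    T_M: float | None = 38.7
    sigma: float | None = _SIGMA_DEFAULT
    T_th: float | None = None
    T_sa: float | None = None


@dataclass
class OpticsBlock:
    mu_a: float
    mu_s_prime: float
    n: float = 1.333
    R_eff: float = 0.475
    epsilon: float | None = None
    M0: float = 0.003


@dataclass
class GeometryBlock:
    placement: str = "top"
    sd_offset: tuple[float, float] = (0.0, 0.0)
    shared_ezb: bool = False


@dataclass
class TimingBlock:
    exposure_dt: float = 0.4
    total_time: float = 1.0
    cadence: float = 0.01


@dataclass
class GridBlock:
    # thermal grid (bioheat + signal integration)
    dx: float = 50e-6
    dy: float = 50e-6
    dz: float = 175e-6
    Lx: float = 3e-3
    Ly: float = 3e-3
    Lz: float = 7e-3
    # fine acoustic sampling for FWHM profiles
    fine_dx: float = 12.5e-6
    fine_dz: float = 43.75e-6


@dataclass
class ScenarioBlock:
    tag: str = "single_voxel"
    C0: float = 4.4e-11
    separation: float = 0.3e-3
    axis: str = "x"
    n_blobs: int = 3
    seed: int = 0


@dataclass
class OutputBlock:
    normalization: str = "per_curve_max"
    attenuation: str = "axial"


@dataclass
class RunConfig:
    """Validated parameter set for one simulation run."""

    transducer: TransducerBlock = field(default_factory=TransducerBlock)
    tissue: TissueBlock = field(default_factory=TissueBlock)
    nanoagent: NanoagentBlock = field(default_factory=NanoagentBlock)
    optics_ex: OpticsBlock = field(
        default_factory=lambda: OpticsBlock(mu_a=15.0, mu_s_prime=1500.0, epsilon=6.09e6)
    )
    optics_fl: OpticsBlock = field(
        default_factory=lambda: OpticsBlock(mu_a=12.0, mu_s_prime=1700.0, epsilon=6.54e5)
    )
    geometry: GeometryBlock = field(default_factory=GeometryBlock)
    timing: TimingBlock = field(default_factory=TimingBlock)
    grids: GridBlock = field(default_factory=GridBlock)
    scenario: ScenarioBlock = field(default_factory=ScenarioBlock)
    output: OutputBlock = field(default_factory=OutputBlock)

    def __post_init__(self) -> None:
        # constructing the physics objects exercises every invariant
        self.transducer_spec()
        self.tissue_thermal()
        self.agent()
        self.medium_ex()
        self.medium_fl()
        if self.timing.exposure_dt <= 0 or self.timing.total_time <= 0:
            raise ValueError("exposure_dt and total_time must be positive")
        if self.timing.cadence <= 0:
            raise ValueError("snapshot cadence must be positive")

    # -- builders --------------------------------------------------------
    def alpha_np(self) -> float:
        return ac.alpha_np_from_db(
            self.tissue.alpha_db_per_m_mhz,
            self.transducer.f / 1e6,
            self.tissue.alpha_power,
        )

    def transducer_spec(self) -> ac.TransducerSpec:
        t = self.transducer
        return ac.TransducerSpec(
            Pa=t.Pa, a_bar=t.a_bar, f=t.f, c0=t.c0, focus_depth=t.focus_depth
        )

    def tissue_thermal(self) -> bh.TissueThermal:
        t = self.tissue
        return bh.TissueThermal(
            rho0=t.rho0,
            rho_b=t.rho_b,
            Ct=t.Ct,
            Cb=t.Cb,
            kt=t.kt,
            omega_b=t.omega_b,
            T_BG=t.T_BG,
        )

    def agent(self) -> sw.NanoagentSpec:
        n = self.nanoagent
        has_mid = n.T_M is not None and n.sigma is not None
        has_thr = n.T_th is not None and n.T_sa is not None
        if has_thr:
            return sw.NanoagentSpec.from_thresholds(
                n.Q0, n.R0, n.T_th, n.T_sa, T_BG=self.tissue.T_BG
            )
        if has_mid:
            return sw.NanoagentSpec.from_midpoint(
                n.Q0, n.R0, n.T_M, n.sigma, T_BG=self.tissue.T_BG
            )
        raise ValueError("nanoagent needs either (T_M, sigma) or (T_th, T_sa)")

    def medium_ex(self) -> pd_.OpticalMedium:
        o = self.optics_ex
        return pd_.derive_optics(o.mu_a, o.mu_s_prime, o.n, o.R_eff, o.epsilon)

    def medium_fl(self) -> pd_.OpticalMedium:
        o = self.optics_fl
        return pd_.derive_optics(o.mu_a, o.mu_s_prime, o.n, o.R_eff, o.epsilon)

    def thermal_grid(self) -> CartesianGrid:
        g = self.grids
        return CartesianGrid(dx=g.dx, dy=g.dy, dz=g.dz, Lx=g.Lx, Ly=g.Ly, Lz=g.Lz)

    def boundary_geometry(self) -> pd_.BoundaryGeometry:
        medium = self.medium_ex()
        return pd_.BoundaryGeometry.for_placement(
            self.geometry.placement,
            self.transducer.focus_depth,
            medium,
            sd_offset=tuple(self.geometry.sd_offset),
        )

    def source_detector(self) -> dy.SourceDetectorConfig:
        return dy.SourceDetectorConfig(
            M0=self.optics_ex.M0,
            epsilon_fl=self.optics_fl.epsilon,
            placement=self.geometry.placement,
            sd_offset=tuple(self.geometry.sd_offset),
        )

    def snapshot_times(self) -> np.ndarray:
        t = self.timing
        n = int(round(t.total_time / t.cadence))
        return np.round(np.arange(n + 1) * t.cadence, 9)

    def pressure_on_thermal_grid(self) -> ac.PressureField:
        f = ac.evaluate_pressure(
            self.thermal_grid(),
            self.transducer_spec(),
            self.alpha_np(),
            attenuation=self.output.attenuation,
        )
        return ac.intensity_field(f, self.tissue.rho0, self.transducer.c0)

    def heat_source(self) -> ac.HeatSource:
        return ac.heating_source(
            self.pressure_on_thermal_grid(),
            self.alpha_np(),
            self.tissue.rho0,
            self.transducer.c0,
            self.timing.exposure_dt,
        )


def _build(cls, data: dict, path: str = ""):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in block '{path or cls.__name__}'")
    kwargs = {}
    for key, value in data.items():
        ftype = allowed[key].type
        sub = _BLOCKS.get(key) if path == "" else None
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, path=key)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_BLOCKS = {
    "transducer": TransducerBlock,
    "tissue": TissueBlock,
    "nanoagent": NanoagentBlock,
    "optics_ex": OpticsBlock,
    "optics_fl": OpticsBlock,
    "geometry": GeometryBlock,
    "timing": TimingBlock,
    "grids": GridBlock,
    "scenario": ScenarioBlock,
    "output": OutputBlock,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; missing keys take the canonical defaults.

    ``overrides`` maps dotted keys (``"timing.exposure_dt"``) to values
    applied after the file is read.  Unknown keys are rejected.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    for dotted, value in (overrides or {}).items():
        block, _, key = dotted.partition(".")
        if not key:
            raise ValueError(f"override '{dotted}' must be 'block.key'")
        data.setdefault(block, {})[key] = value
    return _build(RunConfig, data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the canonical YAML form of a config."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def make_fixture(
    tag: str,
    grid: CartesianGrid,
    C0: float = 4.4e-11,
    separation: float = 0.3e-3,
    axis: str = "x",
    n_blobs: int = 3,
    seed: int = 0,
) -> dy.NanoagentMap:
    """Deterministic concentration-map fixtures for the standard scenarios.

    ``random_blobs`` draws Gaussian blobs from a seeded generator (same
    seed → identical map); the other tags are parameter-exact.
    """
    if tag == "single_voxel":
        return dy.NanoagentMap.single_voxel(grid, C0)
    if tag == "two_voxel":
        return dy.NanoagentMap.two_voxel(grid, C0, separation, axis=axis)
    if tag == "uniform":
        return dy.NanoagentMap.uniform(grid, C0)
    if tag == "random_blobs":
        rng = np.random.default_rng(seed)
        X, Y, Z = grid.meshgrid()
        C = np.zeros(grid.shape)
        for _ in range(n_blobs):
            cx = rng.uniform(-grid.Lx / 2, grid.Lx / 2)
            cy = rng.uniform(-grid.Ly / 2, grid.Ly / 2)
            cz = rng.uniform(-grid.Lz / 2, grid.Lz / 2)
            s = rng.uniform(0.2e-3, 0.6e-3)
            C += C0 * np.exp(
                -((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2 * s**2)
            )
        return dy.NanoagentMap(grid=grid, C=C, scenario="random_blobs")
    raise ValueError(f"unknown scenario tag {tag!r}")


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def _write_volume(path: Path, volume: np.ndarray, meta: dict) -> None:
    """Multi-page TIFF (pages along the last axis) plus a JSON sidecar."""
    import tifffile

    pages = np.moveaxis(np.asarray(volume, dtype=np.float32), -1, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _write_csv(path: Path, columns: dict[str, np.ndarray]) -> None:
    import pandas as pd

    pd.DataFrame(columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _preset_fig2(config: RunConfig, out: Path) -> dict:
    """Pressure field metrics and temperature snapshots."""
    spec = config.transducer_spec()
    alpha = config.alpha_np()
    fine = config.grids
    lat = CartesianGrid(
        dx=fine.fine_dx, dy=fine.fine_dx, dz=fine.fine_dz,
        Lx=config.grids.Lx, Ly=fine.fine_dx, Lz=fine.fine_dz,
    )
    axi = CartesianGrid(
        dx=fine.fine_dx, dy=fine.fine_dx, dz=fine.fine_dz,
        Lx=fine.fine_dx, Ly=fine.fine_dx, Lz=config.grids.Lz,
    )
    mode = config.output.attenuation
    f_lat = ac.evaluate_pressure(lat, spec, alpha, attenuation=mode)
    f_axi = ac.evaluate_pressure(axi, spec, alpha, attenuation=mode)
    x, px = f_lat.lateral_profile()
    z, pz = f_axi.axial_profile()
    _write_csv(out / "pressure_lateral.csv", {"coordinate_m": x, "value": px})
    _write_csv(out / "pressure_axial.csv", {"coordinate_m": z, "value": pz})

    source = config.heat_source()
    snaps = [0.149, 0.397, 0.521, 0.708]
    thermal = bh.solve_bioheat(source, config.tissue_thermal(), snapshot_times=snaps)
    _write_volume(
        out / "dT_snapshots.tif",
        np.moveaxis(thermal.dT, 0, -1)[:, thermal.grid.center_index[1], :, :],
        {"times_s": snaps, "plane": "XZ", "dx_m": config.grids.dx, "dz_m": config.grids.dz},
    )
    trace_t = config.snapshot_times()
    trace = dy.probe_temperature_series(
        source, config.tissue_thermal(), trace_t, [(0.0, 0.0, 0.0)]
    )[:, 0]
    _write_csv(
        out / "focal_trace.csv",
        {"t_s": trace_t, "dT_K": trace, "dTdt_K_per_s": np.gradient(trace, trace_t)},
    )
    lat_fwhm = [ac.profile_fwhm(*thermal.lateral_profile(i)) for i in range(len(snaps))]
    axi_fwhm = [ac.profile_fwhm(*thermal.axial_profile(i)) for i in range(len(snaps))]
    return {
        "focal_peak_pressure_MPa": f_lat.focal_amplitude() / 1e6,
        "pressure_lateral_fwhm_mm": ac.profile_fwhm(x, px) * 1e3,
        "pressure_axial_fwhm_mm": ac.profile_fwhm(z, pz) * 1e3,
        "peak_dT_C": float(max(thermal.dT[i].max() for i in range(len(snaps)))),
        "snapshot_times_s": snaps,
        "thermal_lateral_fwhm_mm": [v * 1e3 for v in lat_fwhm],
        "thermal_axial_fwhm_mm": [v * 1e3 for v in axi_fwhm],
    }


def _preset_fig3(config: RunConfig, out: Path) -> dict:
    """Quantum-yield curve, derivative, and recovered switching params."""
    agent = config.agent()
    T = np.arange(36.0, 41.0 + 1e-9, 0.01)
    Q = sw.quantum_yield(T, agent)
    dQ = sw.yield_derivative(T, agent)
    _write_csv(out / "quantum_yield.csv", {"temperature_C": T, "Q": Q, "dQdT": dQ})
    rec = sw.characterize_curve(T, Q)
    return {"input": {"T_M": agent.T_M, "sigma": agent.sigma, "T_BW": agent.T_BW}, "recovered": rec}


def _dynamics_run(config: RunConfig, out: Path, tag: str) -> dict:
    source = config.heat_source()
    grid = source.grid
    cmap = make_fixture(
        tag,
        grid,
        C0=config.scenario.C0,
        separation=config.scenario.separation,
        axis=config.scenario.axis,
        seed=config.scenario.seed,
    )
    times = config.snapshot_times()
    series, focal = dy.simulate_usf(
        source,
        config.tissue_thermal(),
        cmap,
        config.boundary_geometry(),
        config.medium_ex(),
        config.medium_fl(),
        config.source_detector(),
        config.agent(),
        times,
    )
    norm = series.normalized()
    v = norm.velocity
    a = norm.acceleration
    v_scale = np.max(np.abs(v)) or 1.0
    a_scale = np.max(np.abs(a)) or 1.0
    _write_csv(
        out / f"usf_dynamics_{tag}.csv",
        {
            "t_s": times,
            "phi_norm": norm.phi,
            "v_norm": v / v_scale,
            "a_norm": a / a_scale,
            "dT_focal_K": focal,
        },
    )
    i_peak = int(np.argmax(norm.phi))
    return {
        "scenario": tag,
        "peak_time_s": float(times[i_peak]),
        "peak_focal_dT_C": float(focal.max()),
        "plateau_fraction_at_0.521s": float(
            norm.phi[np.argmin(np.abs(times - 0.521))]
        ),
    }


def _preset_fig4_single(config: RunConfig, out: Path) -> dict:
    return _dynamics_run(config, out, "single_voxel")


def _preset_fig4_uniform(config: RunConfig, out: Path) -> dict:
    return _dynamics_run(config, out, "uniform")


def _preset_fig5(config: RunConfig, out: Path) -> dict:
    source = config.heat_source()
    result = dy.two_point_experiment(
        config.scenario.separation,
        source,
        config.tissue_thermal(),
        config.boundary_geometry(),
        config.medium_ex(),
        config.medium_fl(),
        config.source_detector(),
        config.agent(),
        config.snapshot_times(),
        C0=config.scenario.C0,
        axis=config.scenario.axis,
    )
    times = result["series_X1"].t
    _write_csv(
        out / "two_point_series.csv",
        {
            "t_s": times,
            "phi_X1": result["series_X1"].normalized().phi,
            "phi_X2": result["series_X2"].normalized().phi,
            "phi_both": result["series_combined"].normalized().phi,
        },
    )
    summary = {
        "dt_X12_s": result["dt_X12"],
        "dt_v_s": result["dt_v"],
        "separation_m": result["separation"],
    }
    (out / "two_point_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _sensitivity_preset(config: RunConfig, out: Path, which: str) -> dict:
    import h5py

    source = config.heat_source()
    scan = se.default_scan_grid()
    frame_times = np.round(np.arange(0.0, 0.35 + 1e-9, 0.05), 9)
    dT = se.subgrid_temperature_series(source, config.tissue_thermal(), frame_times, scan)
    results = {}
    with h5py.File(out / f"sensitivity_{which}.h5", "w") as h5:
        for placement in ("top", "bottom", "side"):
            geom = pd_.BoundaryGeometry.for_placement(
                placement, config.transducer.focus_depth, config.medium_ex()
            )
            mat = se.sensitivity_kernel(
                dT,
                frame_times,
                scan,
                geom,
                config.medium_ex(),
                config.medium_fl(),
                config.source_detector(),
                config.agent(),
                sd_label=placement,
            ).normalized("global")
            grp = h5.create_group(placement)
            grp.create_dataset("W_signal", data=mat.W_signal.astype(np.float32))
            grp.create_dataset("W_velocity", data=mat.W_velocity.astype(np.float32))
            grp.create_dataset("times_s", data=frame_times)
            grp.attrs["geometry"] = json.dumps(
                {"placement": placement, "focus_depth_m": config.transducer.focus_depth}
            )
            W = mat.W_signal if which == "signal" else mat.W_velocity
            iy = scan.shape[1] // 2
            _write_volume(
                out / f"W_{which}_{placement}_xz.tif",
                np.moveaxis(W[:, :, iy, :], 0, -1),
                {"times_s": frame_times.tolist(), "plane": "XZ", "placement": placement},
            )
            last = se.support_metrics(W[-1], scan)
            results[placement] = {k: last[k] for k in ("support_fraction", "ring_thickness_x", "ring_thickness_z")}
    h5_coords = {"dx_m": scan.dx, "dz_m": scan.dz}
    results["scan_grid"] = h5_coords
    return results


def _preset_fig6(config: RunConfig, out: Path) -> dict:
    return _sensitivity_preset(config, out, "signal")


def _preset_fig7(config: RunConfig, out: Path) -> dict:
    return _sensitivity_preset(config, out, "velocity")


PRESETS = {
    "fig2": _preset_fig2,
    "fig3": _preset_fig3,
    "fig4_single": _preset_fig4_single,
    "fig4_uniform": _preset_fig4_uniform,
    "fig5": _preset_fig5,
    "fig6": _preset_fig6,
    "fig7": _preset_fig7,
}


def run_preset(
    name: str, config: RunConfig | None = None, out_dir: str | Path = "usfsim_out"
) -> dict:
    """Execute a named preset pipeline and write its output bundle.

    Returns the scalar summary, which is also written with a run log
    (parameters, stage runtime) to ``<out_dir>/<name>_summary.json``.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        summary = PRESETS[name](config, out)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"preset '{name}' failed: {exc}") from exc
    log = {
        "preset": name,
        "runtime_s": round(time.perf_counter() - t0, 3),
        "summary": summary,
        "config": dataclasses.asdict(config),
    }
    (out / f"{name}_summary.json").write_text(json.dumps(log, indent=2, default=float))
    return summary
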