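"""Time-dependent sensitivity (weight) matrices for USF tomography.

The sensitivity of a source–detector measurement to the nanoagent content
of voxel j at time t is obtained by placing a unit-concentration agent in
that voxel alone and recording the USF signal and velocity it produces —
conceptually a scan of a single filled voxel through the calculation
volume.  Because the signal is linear in concentration, the scan can be
collapsed into a closed-form kernel

    W_signal(j, t) = K·dΩ·[G_ex(r_j)·G_fl(r_j, r_D) − mirror]·(Q(T_j,t) − Q(T_BG)),

evaluated for all voxels at once; :func:`sensitivity_scan` keeps the
literal per-voxel loop as the brute-force reference.  The velocity weight
is the time derivative, which forms the narrow expanding ring structure
that makes velocity-based reconstruction better conditioned than
signal-based reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .acoustic_field import HeatSource
from .bioheat import TissueThermal, solve_bioheat
from .grids import CartesianGrid
from .photon_diffusion import BoundaryGeometry, OpticalMedium
from .switching import NanoagentSpec, quantum_yield
from .usf_dynamics import (
    SourceDetectorConfig,
    pair_kernel,
    signal_from_trace,
    signal_prefactor,
)

__all__ = [
    "SensitivityMatrix",
    "default_scan_grid",
    "subgrid_temperature_series",
    "sensitivity_kernel",
    "sensitivity_scan",
    "support_metrics",
]


@dataclass
class SensitivityMatrix:
    """Per-voxel, per-time weights of the USF signal and its velocity."""

    grid: CartesianGrid
    times: np.ndarray
    W_signal: np.ndarray  # (n_times, nx, ny, nz)
    W_velocity: np.ndarray
    sd_label: str = "top"
    normalization: str = "raw"

    def normalized(self, mode: str = "global") -> "SensitivityMatrix":
        """``global``: one scale across voxels and times; ``per_frame``:
        each snapshot scaled to its own maximum."""
        if mode == "global":
            s = np.max(np.abs(self.W_signal)) or 1.0
            v = np.max(np.abs(self.W_velocity)) or 1.0
            return replace(
                self,
                W_signal=self.W_signal / s,
                W_velocity=self.W_velocity / v,
                normalization="global",
            )
        if mode == "per_frame":
            axes = (1, 2, 3)
            s = np.max(np.abs(self.W_signal), axis=axes, keepdims=True)
            v = np.max(np.abs(self.W_velocity), axis=axes, keepdims=True)
            s[s == 0] = 1.0
            v[v == 0] = 1.0
            return replace(
                self,
                W_signal=self.W_signal / s,
                W_velocity=self.W_velocity / v,
                normalization="per_frame",
            )
        raise ValueError("mode must be 'global' or 'per_frame'")


def default_scan_grid() -> CartesianGrid:
    """Scan voxels covering the focal region: 0.1 mm lateral / 0.35 mm
    axial spacing over ±1.5 mm × ±4 mm.

    The spacings are integer multiples of the default thermal spacings so
    scan voxel centers coincide with thermal grid points.
    """
    return CartesianGrid(dx=1e-4, dy=1e-4, dz=3.5e-4, Lx=1.5e-3, Ly=1.5e-3, Lz=4e-3)


def subgrid_temperature_series(
    source: HeatSource,
    tissue: TissueThermal,
    times,
    scan_grid: CartesianGrid,
) -> np.ndarray:
    """ΔT at the scan-grid voxel centers for each snapshot time.

    The scan voxels must coincide with thermal grid points; the series is
    extracted with a streaming observer (no full-field storage) and has
    shape ``(n_times, nx, ny, nz)`` on the scan grid.
    """
    tg = source.grid
    ix = np.array([int(round(x / tg.dx)) + tg.x.size // 2 for x in scan_grid.x])
    iy = np.array([int(round(y / tg.dy)) + tg.y.size // 2 for y in scan_grid.y])
    iz = np.array([int(round(z / tg.dz)) + tg.z.size // 2 for z in scan_grid.z])
    for idx, axis, coords in (
        (ix, tg.x, scan_grid.x),
        (iy, tg.y, scan_grid.y),
        (iz, tg.z, scan_grid.z),
    ):
        if idx.min() < 0 or idx.max() >= axis.size:
            raise ValueError("scan grid extends beyond the thermal grid")
        if not np.allclose(axis[idx], coords, atol=1e-9):
            raise ValueError(
                "scan voxel centers must coincide with thermal grid points"
            )
    frames: list[np.ndarray] = []

    def _observe(t: float, dT: np.ndarray) -> None:
        frames.append(dT[np.ix_(ix, iy, iz)].copy())

    solve_bioheat(source, tissue, snapshot_times=times, observer=_observe, store=False)
    return np.stack(frames)


def sensitivity_kernel(
    dT_series: np.ndarray,
    times,
    scan_grid: CartesianGrid,
    geom: BoundaryGeometry,
    optics_ex: OpticalMedium,
    optics_fl: OpticalMedium,
    sd: SourceDetectorConfig,
    agent: NanoagentSpec,
    sd_label: str = "top",
) -> SensitivityMatrix:
    """Closed-form sensitivity matrix exploiting linearity in C.

    ``dT_series`` holds the temperature rise on the scan grid per
    snapshot (see :func:`subgrid_temperature_series`).  Weights use unit
    molar concentration and the scan voxel volume dΩ.
    """
    times = np.asarray(times, dtype=float)
    dT_series = np.asarray(dT_series, dtype=float)
    if dT_series.shape != (times.size, *scan_grid.shape):
        raise ValueError("dT_series shape does not match times and scan grid")
    pts = scan_grid.points()
    clamp = 0.5 * np.sqrt(scan_grid.dx**2 + scan_grid.dy**2 + scan_grid.dz**2)
    kern = pair_kernel(pts, geom, optics_ex, optics_fl, clamp=clamp)
    K = signal_prefactor(optics_ex, optics_fl, sd)
    w = (K * scan_grid.voxel_volume * kern).reshape(scan_grid.shape)
    Q_bg = quantum_yield(agent.T_BG, agent)
    W_signal = w[None] * (quantum_yield(agent.T_BG + dT_series, agent) - Q_bg)
    W_velocity = np.gradient(W_signal, times, axis=0)
    return SensitivityMatrix(
        grid=scan_grid,
        times=times,
        W_signal=W_signal,
        W_velocity=W_velocity,
        sd_label=sd_label,
    )


def sensitivity_scan(
    dT_series: np.ndarray,
    times,
    scan_grid: CartesianGrid,
    geom: BoundaryGeometry,
    optics_ex: OpticalMedium,
    optics_fl: OpticalMedium,
    sd: SourceDetectorConfig,
    agent: NanoagentSpec,
    sd_label: str = "top",
) -> SensitivityMatrix:
    """Brute-force scan: one single-voxel signal computation per voxel.

    Definitionally equivalent to :func:`sensitivity_kernel`; kept as the
    explicit reference implementation of scanning a lone filled voxel
    through the volume.
    """
    times = np.asarray(times, dtype=float)
    pts = scan_grid.points()
    clamp = 0.5 * np.sqrt(scan_grid.dx**2 + scan_grid.dy**2 + scan_grid.dz**2)
    K = signal_prefactor(optics_ex, optics_fl, sd)
    n = pts.shape[0]
    flat_dT = dT_series.reshape(times.size, n)
    W = np.empty((times.size, n))
    for j in range(n):
        kern_j = pair_kernel(pts[j : j + 1], geom, optics_ex, optics_fl, clamp=clamp)
        w_j = K * scan_grid.voxel_volume * kern_j
        series = signal_from_trace(times, flat_dT[:, j : j + 1], w_j, agent)
        W[:, j] = series.phi
    W_signal = W.reshape(times.size, *scan_grid.shape)
    W_velocity = np.gradient(W_signal, times, axis=0)
    return SensitivityMatrix(
        grid=scan_grid,
        times=times,
        W_signal=W_signal,
        W_velocity=W_velocity,
        sd_label=sd_label,
    )


def support_metrics(
    W: np.ndarray, grid: CartesianGrid, level: float = 0.5
) -> dict[str, float]:
    """Support fraction and focal-ray thickness of one weight frame.

    ``W`` is either a full ``(nx, ny, nz)`` frame or its ``(nx, nz)``
    XZ-plane slice through the focus (the plane the weight maps are
    usually displayed on).  ``support_fraction`` is the share of voxels
    with |W| at or above ``level`` times the frame maximum.  The ring
    thickness along +X (+Z) is the path length (m) where |W| is at or
    above ``level`` times the maximum of that ray, measured on the
    positive ray from the focal center; the ray-relative threshold keeps
    the measure meaningful under the strong optical depth weighting.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    absW = np.abs(np.asarray(W, dtype=float))
    peak = absW.max()
    if peak == 0:
        return {
            "support_fraction": 0.0,
            "ring_thickness_x": 0.0,
            "ring_thickness_z": 0.0,
            "empty": True,
        }
    if absW.ndim == 3:
        ix, iy, iz = (s // 2 for s in absW.shape)
        ray_x = absW[ix:, iy, iz]
        ray_z = absW[ix, iy, iz:]
    elif absW.ndim == 2:
        ix, iz = (s // 2 for s in absW.shape)
        ray_x = absW[ix:, iz]
        ray_z = absW[ix, iz:]
    else:
        raise ValueError("W must be a 3-D frame or a 2-D XZ slice")

    def _thickness(ray: np.ndarray, spacing: float) -> float:
        m = ray.max()
        if m == 0:
            return 0.0
        return float(np.count_nonzero(ray >= level * m) * spacing)

    return {
        "support_fraction": float((absW >= level * peak).mean()),
        "ring_thickness_x": _thickness(ray_x, grid.dx),
        "ring_thickness_z": _thickness(ray_z, grid.dz),
        "empty": False,
    }
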