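"""Pennes bioheat finite-difference solver for ultrasound heating.

Solves the temperature-rise form of the Pennes equation

    ρ0·Ct·∂ΔT/∂t = kt·∇²ΔT − ωb·ρb·Cb·ΔT + H(r)·s(t),

where ΔT = T − T_BG, the perfusion sink acts on the rise above the
steady-state background, and ``s(t)`` is the rectangular exposure window
of the ultrasound heat source.  The scheme is explicit forward-time,
central-space (FTCS) with a 7-point Laplacian, zero initial condition and
zero-gradient (mirror) boundaries on all faces — appropriate because the
tissue is much larger than the heated focal region.

The solver hits every requested snapshot time exactly by locally
shortening the time step, and supports streaming observers so that
downstream signal integrals can be accumulated without storing the full
ΔT(r, t) history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .acoustic_field import HeatSource
from .grids import CartesianGrid

__all__ = [
    "TissueThermal",
    "ThermalField",
    "stable_timestep",
    "solve_bioheat",
    "confinement_temperature",
    "perfusion_metrics",
]


@dataclass(frozen=True)
class TissueThermal:
    """Thermal and perfusion properties of soft tissue.

    Attributes
    ----------
    rho0, rho_b:
        Tissue and blood density (kg/m³).
    Ct, Cb:
        Tissue and blood specific heat (J/kg/K).
    kt:
        Thermal conductivity (W/m/K).
    omega_b:
        Blood perfusion rate (1/s).
    T_BG:
        Background temperature (°C).
    """

    rho0: float = 1064.0
    rho_b: float = 1060.0
    Ct: float = 4200.0
    Cb: float = 3780.0
    kt: float = 0.6
    omega_b: float = 0.0189
    T_BG: float = 37.0

    def __post_init__(self) -> None:
        for name in ("rho0", "rho_b", "Ct", "Cb", "kt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.omega_b < 0:
            raise ValueError("omega_b must be non-negative")

    @property
    def alpha_th(self) -> float:
        """Thermal diffusivity kt/(ρ0·Ct) (m²/s)."""
        return self.kt / (self.rho0 * self.Ct)

    @property
    def tau(self) -> float:
        """Perfusion time constant ρ0·Ct/(ωb·ρb·Cb) (s)."""
        if self.omega_b == 0:
            return np.inf
        return self.rho0 * self.Ct / (self.omega_b * self.rho_b * self.Cb)


@dataclass
class ThermalField:
    """Snapshots of the temperature rise ΔT(r, t) on a grid."""

    grid: CartesianGrid
    times: np.ndarray
    dT: np.ndarray  # (n_times, nx, ny, nz), Kelvin
    T_BG: float

    @property
    def T(self) -> np.ndarray:
        """Absolute temperature snapshots (°C)."""
        return self.T_BG + self.dT

    @property
    def dTdt(self) -> np.ndarray:
        """Time derivative at the snapshots (K/s), central differences.

        One-sided differences are used at the first and last snapshot.
        """
        return np.gradient(self.dT.astype(np.float64), self.times, axis=0)

    def focal_trace(self) -> np.ndarray:
        """ΔT at the focal-center voxel for each snapshot time."""
        ix, iy, iz = self.grid.center_index
        return np.asarray(self.dT[:, ix, iy, iz], dtype=float)

    def lateral_profile(self, i_time: int) -> tuple[np.ndarray, np.ndarray]:
        _, iy, iz = self.grid.center_index
        return self.grid.x, np.asarray(self.dT[i_time, :, iy, iz], dtype=float)

    def axial_profile(self, i_time: int) -> tuple[np.ndarray, np.ndarray]:
        ix, iy, _ = self.grid.center_index
        return self.grid.z, np.asarray(self.dT[i_time, ix, iy, :], dtype=float)


def stable_timestep(
    grid: CartesianGrid, tissue: TissueThermal, safety: float = 0.9
) -> float:
    """Largest stable FTCS step times a safety factor.

    ``dt = safety / (2·α_th·(1/dx² + 1/dy² + 1/dz²))``, additionally capped
    at ``safety·τ/10`` so the perfusion decay is well resolved.
    """
    if not 0 < safety <= 1:
        raise ValueError("safety must be in (0, 1]")
    diff = 2.0 * tissue.alpha_th * (
        1.0 / grid.dx**2 + 1.0 / grid.dy**2 + 1.0 / grid.dz**2
    )
    dt = safety / diff
    if np.isfinite(tissue.tau):
        dt = min(dt, safety * tissue.tau / 10.0)
    return dt


def _laplacian(dT: np.ndarray, grid: CartesianGrid, out: np.ndarray) -> np.ndarray:
    """7-point Laplacian with zero-gradient (mirror) boundary faces."""
    p = np.pad(dT, 1, mode="edge")
    out[:] = (
        (p[2:, 1:-1, 1:-1] - 2.0 * dT + p[:-2, 1:-1, 1:-1]) / grid.dx**2
        + (p[1:-1, 2:, 1:-1] - 2.0 * dT + p[1:-1, :-2, 1:-1]) / grid.dy**2
        + (p[1:-1, 1:-1, 2:] - 2.0 * dT + p[1:-1, 1:-1, :-2]) / grid.dz**2
    )
    return out


def solve_bioheat(
    source: HeatSource,
    tissue: TissueThermal,
    grid: CartesianGrid | None = None,
    snapshot_times: Sequence[float] = (),
    dt: float | None = None,
    safety: float = 0.9,
    observer: Callable[[float, np.ndarray], None] | None = None,
    store: bool = True,
    snapshot_dtype=np.float32,
    dT0: np.ndarray | None = None,
) -> ThermalField:
    """Integrate the Pennes equation and sample ΔT at ``snapshot_times``.

    Parameters
    ----------
    source:
        Ultrasound heat deposition with its rectangular exposure window.
    grid:
        Defaults to the source's grid (the two must match).
    snapshot_times:
        Sorted, non-negative times (s) at which ΔT is sampled.  Each is
        hit exactly by shortening the step that would overshoot it.
    dt:
        Base time step; defaults to the FTCS stability bound times
        ``safety``.  A value above the stability bound is refused.
    observer:
        Optional callback ``observer(t, dT)`` invoked at every snapshot
        (including t = 0 if requested) with the live ΔT array.  The array
        must not be mutated or kept by the callback.
    store:
        If False, snapshots are not retained (the returned field has an
        empty ``dT``); use an observer to extract reductions instead.
    dT0:
        Initial temperature rise; defaults to the zero field.
    """
    if grid is None:
        grid = source.grid
    if source.H.shape != grid.shape:
        raise ValueError("heat source grid does not match solver grid")
    times = np.asarray(snapshot_times, dtype=float)
    if times.size == 0:
        raise ValueError("at least one snapshot time is required")
    if np.any(times < 0):
        raise ValueError("snapshot times must be non-negative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("snapshot times must be strictly increasing")

    dt_max = stable_timestep(grid, tissue, safety=1.0)
    if dt is None:
        dt = stable_timestep(grid, tissue, safety=safety)
    elif dt > dt_max:
        raise ValueError(
            f"dt = {dt:g} s violates the FTCS stability bound {dt_max:g} s"
        )

    inv_rhoC = 1.0 / (tissue.rho0 * tissue.Ct)
    perf = tissue.omega_b * tissue.rho_b * tissue.Cb * inv_rhoC  # 1/s
    kappa = tissue.kt * inv_rhoC

    if dT0 is None:
        dT = np.zeros(grid.shape)
    else:
        if dT0.shape != grid.shape:
            raise ValueError("dT0 shape does not match the grid")
        dT = np.array(dT0, dtype=float)
    lap = np.empty_like(dT)
    snapshots: list[np.ndarray] = []

    def _take(t_now: float) -> None:
        if store:
            snapshots.append(dT.astype(snapshot_dtype))
        if observer is not None:
            observer(t_now, dT)

    t = 0.0
    i_snap = 0
    if times[0] == 0.0:
        _take(0.0)
        i_snap = 1
    t_end = times[-1]
    # integration loop; each sub-step is heated only if it starts inside
    # the exposure window (the window edge is aligned with a step boundary
    # below whenever a snapshot or the window itself is crossed)
    boundaries = np.unique(np.concatenate([times, [source.exposure_dt]]))
    boundaries = boundaries[(boundaries > 0) & (boundaries <= t_end)]
    for t_next in boundaries:
        while t < t_next - 1e-12:
            step = min(dt, t_next - t)
            heated = source.schedule(t + 0.5 * step)
            _laplacian(dT, grid, lap)
            dT += step * (kappa * lap - perf * dT)
            if heated:
                dT += step * inv_rhoC * source.H
            t += step
        t = t_next
        if i_snap < times.size and abs(t - times[i_snap]) < 1e-12:
            _take(t)
            i_snap += 1

    stacked = (
        np.stack(snapshots) if store else np.empty((0,) + grid.shape, snapshot_dtype)
    )
    return ThermalField(grid=grid, times=times, dT=stacked, T_BG=tissue.T_BG)


def confinement_temperature(
    source: HeatSource, tissue: TissueThermal, t: float
) -> np.ndarray:
    """Thermal-confinement closed form ΔT(r, t) = H(r)·t/(ρ0·Ct).

    Valid while diffusion and perfusion are negligible, i.e. during a
    short exposure; ``t`` must not exceed the exposure window.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t > source.exposure_dt:
        raise ValueError("confinement form only applies during the exposure")
    return source.H * t / (tissue.rho0 * tissue.Ct)


def perfusion_metrics(tissue: TissueThermal, exposure_dt: float) -> dict[str, float]:
    """Perfusion time constant, exposure attenuation and diffusion length.

    Returns ``tau`` (s), ``attenuation_fraction`` = 1 − exp(−Δt/τ), and
    ``L_d`` = √(4·α_th·Δt) (m), the transient conduction length.
    """
    if exposure_dt <= 0:
        raise ValueError("exposure_dt must be positive")
    tau = tissue.tau
    attenuation = 1.0 - np.exp(-exposure_dt / tau) if np.isfinite(tau) else 0.0
    L_d = float(np.sqrt(4.0 * tissue.alpha_th * exposure_dt))
    return {"tau": float(tau), "attenuation_fraction": float(attenuation), "L_d": L_d}
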