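"""Semi-infinite photon diffusion with extrapolated-zero-boundary sources.

Excitation light entering highly scattering tissue through a small spot is
modelled as an isotropic point source one transport mean free path
``z_tr = 1/(μs' + μa)`` below the surface.  The semi-infinite boundary is
handled with the extrapolated zero boundary (EZB): the diffuse fluence is
forced to vanish on a virtual plane offset ``z_b`` outside the tissue by
adding a negative mirror-image source reflected across that plane.  The
steady-state propagation kernels are attenuated spherical waves

    G(r1, r2) = exp(−μ_eff·|r1 − r2|)/|r1 − r2|,

with ``μ_eff = √(3·μa·(μa + μs'))``; the excitation kernel is the real
minus the image term, and the emission kernel from a fluorescent voxel to
a surface detector is the single real term (its image partner enters the
signal integral through the mirrored focal volume).

One :class:`OpticalMedium` is built per wavelength (excitation ≈808 nm,
emission ≈830 nm); the light speed used in the diffusion coefficient
``D = v/[3(μa + μs')]`` is the in-medium speed ``v = c/n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import CartesianGrid

__all__ = [
    "SPEED_OF_LIGHT",
    "OpticalMedium",
    "BoundaryGeometry",
    "derive_optics",
    "excitation_fluence",
    "emission_green",
]

SPEED_OF_LIGHT = 2.99792458e8  # m/s, in vacuum


@dataclass(frozen=True)
class OpticalMedium:
    """Diffuse optical properties at one wavelength.

    Attributes
    ----------
    mu_a, mu_s_prime:
        Absorption and reduced scattering coefficients (1/m).
    n:
        Refractive index of the tissue.
    R_eff:
        Effective boundary reflection coefficient for the tissue/air
        refractive-index mismatch.
    epsilon:
        Molar extinction coefficient (1/m/(mol/L)); stored for use in the
        emission prefactor (the excitation value is carried but unused by
        the steady-state kernels).
    """

    mu_a: float
    mu_s_prime: float
    n: float = 1.333
    R_eff: float = 0.475
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_prime < 0 or self.mu_a + self.mu_s_prime == 0:
            raise ValueError("invalid medium: need mu_a + mu_s_prime > 0")
        if not 0 <= self.R_eff < 1:
            raise ValueError("R_eff must be in [0, 1)")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def v(self) -> float:
        """Light speed in the medium, c/n (m/s)."""
        return SPEED_OF_LIGHT / self.n

    @property
    def mu_t_prime(self) -> float:
        return self.mu_a + self.mu_s_prime

    @property
    def D(self) -> float:
        """Diffusion coefficient v/[3(μa + μs')] (m²/s)."""
        return self.v / (3.0 * self.mu_t_prime)

    @property
    def D_length(self) -> float:
        """Length-form diffusion coefficient D/v = 1/[3(μa + μs')] (m)."""
        return 1.0 / (3.0 * self.mu_t_prime)

    @property
    def mu_eff(self) -> float:
        """Effective attenuation √(3·μa·(μa + μs')) (1/m)."""
        return np.sqrt(3.0 * self.mu_a * self.mu_t_prime)

    @property
    def z_tr(self) -> float:
        """Transport mean free path 1/(μs' + μa) (m)."""
        return 1.0 / self.mu_t_prime

    @property
    def z_b(self) -> float:
        """EZB extrapolation distance [(1+R_eff)/(1−R_eff)]·2·(D/v) (m)."""
        return (1.0 + self.R_eff) / (1.0 - self.R_eff) * 2.0 * self.D_length


def derive_optics(
    mu_a: float,
    mu_s_prime: float,
    n: float = 1.333,
    R_eff: float = 0.475,
    epsilon: float | None = None,
) -> OpticalMedium:
    """Build an :class:`OpticalMedium` with all derived quantities."""
    return OpticalMedium(
        mu_a=mu_a, mu_s_prime=mu_s_prime, n=n, R_eff=R_eff, epsilon=epsilon
    )


@dataclass(frozen=True)
class BoundaryGeometry:
    """Semi-infinite tissue boundary with EZB mirror bookkeeping.

    The tissue surface is the plane through ``surface_point`` with outward
    unit normal ``normal``; tissue occupies the half-space on the inward
    side.  The EZB lies ``z_b`` outside the surface.  The real excitation
    source sits one transport mean free path below the surface entry
    point; its negative image is the mirror across the EZB.

    ``z_b`` and ``z_tr`` default to the excitation medium's values; a
    separate geometry may be built per wavelength if desired.
    """

    surface_point: tuple[float, float, float]
    normal: tuple[float, float, float]
    z_b: float
    z_tr: float
    source_surface: tuple[float, float, float] | None = None
    detector: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("normal must be a unit vector")
        if self.z_b <= 0 or self.z_tr <= 0:
            raise ValueError("z_b and z_tr must be positive")
        for name in ("source_surface", "detector"):
            p = getattr(self, name)
            if p is not None and abs(self._signed_height(np.asarray(p))) > 1e-9:
                raise ValueError(f"{name} must lie on the surface plane")

    @classmethod
    def for_placement(
        cls,
        placement: str,
        focus_depth: float,
        medium: OpticalMedium,
        sd_offset: tuple[float, float] = (0.0, 0.0),
    ) -> "BoundaryGeometry":
        """Standard geometries around a focus at the origin.

        ``placement`` is ``"top"`` (surface at z = −focus_depth, the
        ultrasound entry side), ``"bottom"`` (z = +focus_depth) or
        ``"side"`` (x = +focus_depth).  The co-located source/detector
        pair sits on the surface at the foot of the focal center, offset
        by ``sd_offset`` within the surface plane.
        """
        u, w = sd_offset
        if placement == "top":
            p0, n = (0.0, 0.0, -focus_depth), (0.0, 0.0, -1.0)
            sd = (u, w, -focus_depth)
        elif placement == "bottom":
            p0, n = (0.0, 0.0, focus_depth), (0.0, 0.0, 1.0)
            sd = (u, w, focus_depth)
        elif placement == "side":
            p0, n = (focus_depth, 0.0, 0.0), (1.0, 0.0, 0.0)
            sd = (focus_depth, u, w)
        else:
            raise ValueError(f"unknown placement {placement!r}")
        return cls(
            surface_point=p0,
            normal=n,
            z_b=medium.z_b,
            z_tr=medium.z_tr,
            source_surface=sd,
            detector=sd,
        )

    # -- plane helpers ---------------------------------------------------
    def _signed_height(self, points: np.ndarray) -> np.ndarray:
        """Signed distance above the surface along the outward normal."""
        p0 = np.asarray(self.surface_point)
        n = np.asarray(self.normal)
        return (points - p0) @ n

    def depth(self, points) -> np.ndarray:
        """Depth below the surface (positive inside the tissue)."""
        return -self._signed_height(np.asarray(points, dtype=float))

    @property
    def ezb_point(self) -> np.ndarray:
        """A point on the extrapolated zero boundary plane."""
        return np.asarray(self.surface_point) + self.z_b * np.asarray(self.normal)

    def mirror(self, points) -> np.ndarray:
        """Mirror points across the EZB plane (an involution)."""
        pts = np.asarray(points, dtype=float)
        n = np.asarray(self.normal)
        h = (pts - self.ezb_point) @ n
        return pts - 2.0 * h[..., None] * n

    # -- source/detector -------------------------------------------------
    @property
    def real_source(self) -> np.ndarray:
        """Isotropic point source z_tr below the surface entry point."""
        if self.source_surface is None:
            raise ValueError("no source position configured")
        return np.asarray(self.source_surface) - self.z_tr * np.asarray(self.normal)

    @property
    def image_source(self) -> np.ndarray:
        """Negative image of the real source across the EZB."""
        return self.mirror(self.real_source)

    @property
    def detector_point(self) -> np.ndarray:
        if self.detector is None:
            raise ValueError("no detector position configured")
        return np.asarray(self.detector, dtype=float)


def _attenuated_spherical(
    dist: np.ndarray, mu_eff: float, clamp: float | None
) -> np.ndarray:
    if clamp is not None:
        dist = np.maximum(dist, clamp)
    elif np.any(dist == 0):
        raise ZeroDivisionError("evaluation point coincides with the source")
    return np.exp(-mu_eff * dist) / dist


def excitation_fluence(
    geom: BoundaryGeometry,
    medium: OpticalMedium,
    M0: float,
    points,
    clamp: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Excitation fluence rate φ_ex and kernel G_ex at ``points``.

    ``G_ex`` is the real-source spherical kernel minus the image-source
    term; ``φ_ex = v·M0/(4π·D)·G_ex``.  The same call evaluates points in
    image space (the mirrored focal volume).  ``clamp`` bounds distances
    away from zero (half a voxel diagonal is a sensible choice) for
    robustness when a field point coincides with the source.
    """
    pts = np.asarray(points, dtype=float)
    d_real = np.linalg.norm(pts - geom.real_source, axis=-1)
    d_img = np.linalg.norm(pts - geom.image_source, axis=-1)
    G = _attenuated_spherical(d_real, medium.mu_eff, clamp) - _attenuated_spherical(
        d_img, medium.mu_eff, clamp
    )
    phi = medium.v * M0 / (4.0 * np.pi * medium.D) * G
    return phi, G


def emission_green(points, r_D, medium: OpticalMedium, clamp: float | None = None):
    """Emission kernel G_fl = exp(−μ_eff·|r − r_D|)/|r − r_D| (1/m).

    Symmetric in its endpoints (reciprocity).  Image-volume contributions
    use the same kernel evaluated from the mirrored point.
    """
    pts = np.asarray(points, dtype=float)
    dist = np.linalg.norm(pts - np.asarray(r_D, dtype=float), axis=-1)
    return _attenuated_spherical(dist, medium.mu_eff, clamp)
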