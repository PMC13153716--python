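"""Temperature-gated fluorescence quantum yield of USF nanoagents.

Thermosensitive nanoagents (e.g. ICG-loaded liposomes) fluoresce weakly
below a threshold temperature T_th (OFF) and strongly above a saturation
temperature T_sa (ON).  The smooth step between the states is modelled
with a complementary error function,

    Q(T) = Q0·{1 + [(R0 − 1)/2]·erfc[−(T − T_M)/(√2·σ)]},

whose temperature derivative is a Gaussian of mean T_M = (T_th + T_sa)/2
and standard deviation σ.  The transition bandwidth T_BW = T_sa − T_th is
identified with the FWHM of that Gaussian, hence σ = T_BW/(2√(2 ln 2)).

``characterize_curve`` runs the inverse procedure used on measured
fluorescence-vs-temperature data: differentiate numerically, take the
left/right half-maximum temperatures of the derivative as T_th and T_sa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

__all__ = [
    "NanoagentSpec",
    "quantum_yield",
    "yield_derivative",
    "characterize_curve",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class NanoagentSpec:
    """Switching parameters of a USF nanoagent.

    Construct either from the threshold pair via :meth:`from_thresholds`
    or from the midpoint/width via :meth:`from_midpoint`; the two routes
    describe the same agent.

    Attributes
    ----------
    Q0:
        Quantum yield at the background temperature (OFF state).
    R0:
        On-to-off fluorescence ratio; must satisfy 1 < R0 < 1/Q0 so the
        yield stays within (0, 1].
    T_M, sigma:
        Gaussian midpoint (°C) and width (°C) of dQ/dT.
    T_BG:
        Tissue background temperature (°C).
    """

    Q0: float
    R0: float
    T_M: float
    sigma: float
    T_BG: float = 37.0

    def __post_init__(self) -> None:
        if self.Q0 <= 0:
            raise ValueError("Q0 must be positive")
        if not (1.0 < self.R0 < 1.0 / self.Q0):
            raise ValueError("R0 must satisfy 1 < R0 < 1/Q0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_thresholds(
        cls, Q0: float, R0: float, T_th: float, T_sa: float, T_BG: float = 37.0
    ) -> "NanoagentSpec":
        if T_sa <= T_th:
            raise ValueError("T_sa must exceed T_th")
        T_BW = T_sa - T_th
        return cls(
            Q0=Q0,
            R0=R0,
            T_M=0.5 * (T_th + T_sa),
            sigma=T_BW / _FWHM_PER_SIGMA,
            T_BG=T_BG,
        )

    @classmethod
    def from_midpoint(
        cls, Q0: float, R0: float, T_M: float, sigma: float, T_BG: float = 37.0
    ) -> "NanoagentSpec":
        return cls(Q0=Q0, R0=R0, T_M=T_M, sigma=sigma, T_BG=T_BG)

    @property
    def T_BW(self) -> float:
        """Transition bandwidth T_sa − T_th (°C), the FWHM of dQ/dT."""
        return self.sigma * _FWHM_PER_SIGMA

    @property
    def T_th(self) -> float:
        """Switch-on threshold (°C), lower half-maximum point of dQ/dT."""
        return self.T_M - 0.5 * self.T_BW

    @property
    def T_sa(self) -> float:
        """Saturation temperature (°C), upper half-maximum point of dQ/dT."""
        return self.T_M + 0.5 * self.T_BW

    @property
    def Q_background(self) -> float:
        """Quantum yield at the background temperature T_BG."""
        return float(quantum_yield(self.T_BG, self))


def quantum_yield(T, spec: NanoagentSpec):
    """Quantum yield Q(T); elementwise on arrays.

    Ranges from Q0 (T ≪ T_th) to Q0·R0 (T ≫ T_sa), with Q(T_M) equal to
    the midpoint Q0·(1 + (R0 − 1)/2).
    """
    T = np.asarray(T, dtype=float)
    arg = -(T - spec.T_M) / (np.sqrt(2.0) * spec.sigma)
    return spec.Q0 * (1.0 + 0.5 * (spec.R0 - 1.0) * erfc(arg))


def yield_derivative(T, spec: NanoagentSpec):
    """dQ/dT (1/°C): a Gaussian of mean T_M, width σ, area Q0·(R0 − 1)."""
    T = np.asarray(T, dtype=float)
    g = np.exp(-(((T - spec.T_M) / (np.sqrt(2.0) * spec.sigma)) ** 2))
    return spec.Q0 * (spec.R0 - 1.0) * g / (np.sqrt(2.0 * np.pi) * spec.sigma)


def characterize_curve(
    T_samples: np.ndarray, F_samples: np.ndarray
) -> dict[str, float]:
    """Extract switching temperatures from a measured fluorescence curve.

    Differentiates F(T) numerically and locates the left and right
    half-maximum temperatures of the derivative by linear interpolation;
    these define T_th and T_sa, hence T_M, T_BW and σ.  The result is
    invariant to affine rescaling (gain/offset) of the fluorescence.
    """
    T = np.asarray(T_samples, dtype=float)
    F = np.asarray(F_samples, dtype=float)
    if T.ndim != 1 or T.shape != F.shape or T.size < 5:
        raise ValueError("need matching 1-D arrays with at least 5 samples")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature samples must be strictly increasing")
    dFdT = np.gradient(F, T)
    i_pk = int(np.argmax(dFdT))
    if i_pk == 0 or i_pk == dFdT.size - 1 or dFdT[i_pk] <= 0:
        raise ValueError("no transition found in the sampled curve")
    half = dFdT[i_pk] / 2.0

    def _cross(idx_range) -> float:
        prev = i_pk
        for i in idx_range:
            if dFdT[i] < half:
                f = (half - dFdT[i]) / (dFdT[prev] - dFdT[i])
                return T[i] + f * (T[prev] - T[i])
            prev = i
        raise ValueError("no transition found in the sampled curve")

    T_th = _cross(range(i_pk - 1, -1, -1))
    T_sa = _cross(range(i_pk + 1, dFdT.size))
    T_BW = T_sa - T_th
    return {
        "T_th": float(T_th),
        "T_sa": float(T_sa),
        "T_M": float(0.5 * (T_th + T_sa)),
        "T_BW": float(T_BW),
        "sigma": float(T_BW / _FWHM_PER_SIGMA),
    }
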