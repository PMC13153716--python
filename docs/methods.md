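# Methods

This note documents the physical models in `usfsim`, the numerical choices
behind them, and the conditions under which the test suite exercises them.

## Acoustic field

The focal pressure amplitude is the analytic two-source ("complex source
point") model: two monopoles at complex axial positions ±j·z_d, with
z_d = k·ā²/2.  The lateral scale parameter ā defaults to 0.5 mm, close to
the lateral focal FWHM of a 2.5 MHz imaging transducer; the model's focal
FWHMs are 0.855 mm (lateral) and 4.495 mm (axial) at 12.5/43.75 µm
sampling, which are the numbers the rest of the pipeline inherits.  (A
physical transducer of this class has a hardware axial FWHM nearer
3.5 mm; the simulator deliberately targets its own model output, not the
hardware datasheet.)  The `sin(k√D)/√D` kernel is even in √D, so the
complex square-root branch is irrelevant; |D| < 1e−20 m² is replaced by
the series limit k.

Absorption: the soft-tissue coefficient 58 dB m⁻¹ MHz⁻¹ with a quadratic
frequency law gives α = (58/8.686)·f² ≈ 41.73 Np/m at 2.5 MHz.  The
default attenuation factor is exp(−α(z + d)), accumulating along the
propagation axis from the tissue surface a distance d above the focus;
this yields the attenuated focal peak Pa·e^{−αd} (1.581 MPa for
Pa = 2.4 MPa, d = 10 mm) *and* the slight axial broadening of the
attenuated beam (axial FWHM 4.495 mm rather than the unattenuated
4.417 mm).  A depth-uniform exp(−αd) variant is available
(`attenuation="uniform"`).

Grid extents default to ±3 mm laterally and ±7 mm axially — more than
three pressure FWHMs — so boundary effects on FWHMs and heating are
negligible.  For heat deposition the field is evaluated directly on the
thermal grid; |P1|² is spectrally smooth at 50 µm resolution near the
focus, and the fine 12.5 µm sampling is reserved for 1-D FWHM profiles
(avoiding a ~10⁸-voxel volume).

## Bioheat solver

The Pennes equation is written for the temperature rise ΔT above the
perfused steady state, so the perfusion sink acts on ΔT (not absolute
temperature).  The scheme is explicit FTCS with a 7-point Laplacian:
with the default thermal voxels (50×50×175 µm³) and diffusivity
α_th = k_t/(ρ₀C_t) ≈ 1.34×10⁻⁷ m²/s the stability bound is ≈4.5 ms, so a
full exposure-plus-cooling second costs only a few hundred vectorized
steps — the simplest correct choice.  The step is additionally capped at
τ/10 (τ = ρ₀C_t/(ω_bρ_bC_b) ≈ 59 s, so this cap is inactive at the
defaults).  Snapshot times are hit exactly by locally shortening the
step; the step grid is also aligned with the end of the exposure window
so the rectangular source is never smeared across a step.

Boundaries are zero-gradient (mirror) on all faces, justified because the
tissue is much larger than the heated region; domain extents match the
acoustic grid.  Scale checks for the 0.4 s exposure: diffusion length
L_d = √(4α_thΔt) ≈ 0.45 mm (smaller than the focus — thermal confinement
approximately holds), perfusion loss 1 − e^{−Δt/τ} ≈ 0.7% (negligible).
The confinement closed form ΔT = H·t/(ρ₀C_t) is exposed separately and
upper-bounds the solver's focal temperature, a property the tests assert.

Memory: solvers can stream.  `solve_bioheat` accepts an observer called
with the live ΔT at each snapshot, so dense cadences (10 ms over 1 s on
the 1.2M-voxel grid) never materialize the full history; stored snapshots
are float32.

## Switching model

The quantum yield is an erfc step from Q₀ to Q₀R₀ with midpoint T_M and
Gaussian derivative of standard deviation σ.  The transition bandwidth
T_BW is *defined* as the FWHM of dQ/dT (σ = T_BW/(2√(2 ln 2))); other
conventions exist, but every derived number here uses the FWHM one.
Defaults: Q₀ = 0.05, R₀ = 2.6, T_M = 38.7 °C, σ = 1/(3√2) °C, hence
T_BW = 0.56 °C, T_th = 38.42 °C, T_sa = 38.98 °C on a 37 °C background.
Validity (0 ≤ Q ≤ 1) is enforced at construction by requiring
1 < R₀ < 1/Q₀ — outputs are never clamped.

`characterize_curve` is the measurement-side inverse: numerically
differentiate a fluorescence-vs-temperature curve and read T_th/T_sa off
the half-maximum points of the derivative by linear interpolation.  On a
0.01 °C grid it recovers 38.41/38.97 °C (the grid quantization accounts
for the last 0.01 °C).  The procedure is invariant to affine rescaling of
the fluorescence, so uncalibrated measurements work.

## Photon diffusion

Steady-state diffusion in a semi-infinite medium with the
extrapolated-zero-boundary method: the excitation fiber becomes an
isotropic point source one transport mean free path
z_tr = 1/(μ_s′ + μ_a) below the surface, plus a negative image reflected
across the EZB plane at z_b = [(1+R_eff)/(1−R_eff)]·2/[3(μ_a+μ_s′)]
outside the surface (≈1.24 mm for the excitation medium).  Two design
points deserve note:

- **Light speed in D.**  The diffusion coefficient is defined with the
  in-medium speed v = c/n (n = 1.333): D_ex = 4.95×10⁴ m²/s at 808 nm
  (μ_a = 15, μ_s′ = 1500 m⁻¹) and D_fl = 4.38×10⁴ m²/s at 830 nm
  (μ_a = 12, μ_s′ = 1700 m⁻¹).  The z_b formula uses the length form
  D/v so it is dimensionally a length.
- **Image-volume sign.**  The two-term excitation kernel is exactly
  antisymmetric across the EZB, so "evaluate the same formula at the
  mirrored point" flips its sign.  The signal integral therefore uses
  the physically consistent form G_ex(r)·[G_fl(r,r_D) − G_fl(r_i,r_D)]:
  the emission field of each fluorescent voxel carries its own negative
  image, and the detected fluence also vanishes on the EZB.  At a 10 mm
  focus depth this image term *reduces* the detected signal by roughly
  40% — the mirror plane sits just outside the surface, so the image
  path is only ≈2.5 mm longer than the real one — and it is therefore
  never negligible in this geometry.

Excitation and emission each use their own z_b (slightly different mirror
planes); the volume mirror defaults to the excitation EZB.  Distances
below half a voxel diagonal are clamped to that value purely for
robustness — the standard geometries never place sources inside the
integration volume.  Only steady-state, single-layer, semi-infinite
geometry is modelled (no time-resolved or frequency-domain transport).

## USF signal, velocity and the two-point experiment

Because concentration, temperature and quantum yield in the image volume
are mirrored copies of the real ones, the double (real + image) integral
collapses to one sum over real voxels with static geometric weights; the
midpoint rule over thermal voxels is the quadrature (a 2× refinement
changes the signal by <2%, asserted in the tests).  The integration
support is the full thermal grid — the integrand dies off naturally where
Q(T) − Q(T_BG) ≈ 0, and the defaults keep switched voxels well inside the
domain.  Background subtraction is φ(t) − φ(0), matching the experimental
ultrasound-off acquisition; this differs from replacing Q with Q − Q₀ only
by Q(T_BG) − Q₀ ≈ 10⁻⁸ (the erfc argument is ≈5σ at 37 °C).

Velocity defaults to numeric differentiation of the signal trace (central
differences), with the chain-rule volume form (G_ex·C·(dQ/dT)·(dT/dt)·G_fl)
retained as an independent cross-check; on the default 10 ms cadence the
two agree within 3% (L∞ over the heating interval) and the cadence
resolves the ≈40–70 ms velocity pulse with several samples.  Normalized
outputs divide each curve by its own maximum.

The two-point experiment probes ΔT at the two voxel centers with a
streaming observer (one solver run serves all three series), localizes
velocity peaks with parabolic interpolation, and measures the X1 pulse
width as the FWHM of the positive pulse.  For 0.3 mm separation at the
default conditions the delay (≈135 ms) exceeds the width (≈66 ms) — the
temporal-separability effect; note the simulated delay is larger than the
pure-confinement prediction because diffusion progressively flattens the
heating rate at the off-center point.

## Sensitivity matrices

The weight of voxel j at time t is the signal (or velocity) produced by a
lone unit-concentration voxel there — by linearity, a closed-form kernel
evaluated for all voxels at once.  The literal per-voxel scan loop is kept
as the brute-force reference and the two agree to 1e−10 (relative) in the
tests.  The default scan region is ±1.5 × ±1.5 × ±4 mm at 0.1/0.35 mm
spacing (integer multiples of the thermal spacings, so scan centers
coincide with thermal grid points and temperatures are subsampled, not
interpolated; the alignment is validated).  Global normalization (one
scale across voxels and times) is the default because the weights grow
with time; per-frame normalization is available for frame-by-frame
structure.

Support metrics quantify the ring structure of the velocity weights.  The
co-located source–detector pair imposes a steep optical depth weighting
(round-trip attenuation ≈ e^{−509 z} along the beam axis), which clips
frame-max-relative supports of both matrices toward the SD side; the
velocity-narrower-than-signal ordering emerges once the focal center
saturates (≳0.25 s) and is asserted on the XZ display plane.  Ring
thickness along a ray is measured against that ray's own maximum, which
keeps the X-vs-Z anisotropy (gentler axial intensity gradient → thicker
axial ring) visible under the depth weighting.

## Resolution analytics

Under confinement each point heats at rate 2αI(r)/(ρ₀C_t) (≈14.2 K/s at
the attenuated focal peak), so threshold/midpoint/saturation crossings
happen at (T_x − T_BG)/rate.  The velocity pulse width is T_BW/rate and
the two-point delay is the difference of midpoint crossings.  Expanding
the rate to first order in the intensity gradient, the printed separation
limit ΔX = 1/{|∇I/I|·[(T_th−T_BG)/(T_BW/2)+1]} corresponds to the delay
equaling *half* the pulse width (a Rayleigh-like criterion); the delay
equals the full width at exactly 2·ΔX.  These closed forms are first-order
re-derivations from the confinement picture and intentionally ignore
diffusion, which the full simulation includes — hence order-level (not
exact) agreement between the analytics and the simulated delays.
The improvement factor spans 7× (3 °C elevation, 1 °C bandwidth) to
≈14.3× (4 °C, 0.6 °C) for typical liposome agents.

## Problem sizes and test conditions

The canonical conditions (Table-defaults in `RunConfig`) are: 2.5 MHz,
Pa = 2.4 MPa, ā = 0.5 mm, 10 mm focus depth, thermal grid 121×121×81
(50×50×175 µm³ over ±3 × ±3 × ±7 mm), 0.4 s exposure, 10 ms cadence.  The
end-to-end tests and the acceptance script run at these conditions (a
full bioheat second costs seconds of wall time).  Unit and property tests
use a coarsened grid (100/350 µm over ±2 × ±5 mm) chosen so every asserted
property is insensitive to the coarsening; the fine-sampling FWHM numbers
are always measured at the canonical 12.5/43.75 µm profile sampling.

## Known limitations

- Linear acoustics only: no nonlinear propagation, aperture diffraction
  integrals, standing waves or radiation-force streaming.
- Constant tissue properties; no temperature dependence, vasculature or
  thermal-dose bookkeeping.
- Semi-infinite optics; no slab/multi-layer geometry, Monte-Carlo
  transport or Robin boundary conditions.
- No detector noise, collection optics, or multi-focus scan assembly; the
  simulator describes a single exposure at a fixed focal position, and
  pulse-repetition effects are out of scope.
- The tomographic *inverse* problem is not implemented — the sensitivity
  matrices are the forward ingredient for it.
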