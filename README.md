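# usfsim

A forward simulator for **ultrasound-switchable fluorescence (USF)**
deep-tissue imaging dynamics.

Near-infrared fluorescence can be detected through centimeters of tissue,
but photon scattering limits its resolution to several millimeters.  USF
imaging recovers sub-millimeter resolution by loading the tissue with
thermosensitive nanoagents (e.g. ICG-loaded liposomes) that fluoresce only
above a switching temperature T_th, and using a focused-ultrasound (FUS)
pulse to heat just the focal volume past that threshold.  `usfsim` couples
the four physical stages of this measurement into one deterministic
pipeline, for researchers designing USF experiments, contrast agents and
reconstruction schemes:

1. **Acoustics** — the complex focal pressure amplitude of a focused beam,

       P1(x,y,z) = Pa·z_d/(2 sinh²(k z_d)) · [e^{k z_d} sin(k√D₋)/√D₋ − e^{−k z_d} sin(k√D₊)/√D₊],

   with D∓ = x² + y² + (z ∓ j·z_d)², z_d = k·ā²/2, attenuated by tissue
   absorption α; intensity I = |P1|²/(2ρ₀c₀) and volumetric heating
   H = 2αI.

2. **Bioheat** — the Pennes equation for the temperature rise ΔT = T − T_BG,

       ρ₀C_t ∂ΔT/∂t = k_t ∇²ΔT − ω_b ρ_b C_b ΔT + H(r)·[u(t) − u(t−Δt)],

   solved by explicit finite differences (zero initial condition,
   zero-gradient boundaries) on a 50×50×175 µm³ voxel grid.

3. **Switching** — a smooth-step quantum yield
   Q(T) = Q₀{1 + [(R₀−1)/2]·erfc[−(T−T_M)/(√2σ)]}, whose temperature
   derivative is a Gaussian of FWHM T_BW = T_sa − T_th.

4. **Photon diffusion** — semi-infinite excitation/emission propagation
   with extrapolated-zero-boundary (EZB) image sources; the detected USF
   signal is the volume integral of G_ex·C·Q(T)·G_fl minus its mirrored
   image-volume term, and its time derivative (the *signal velocity*)
   forms a narrow pulse as each voxel sweeps through the transition band.

On top of the signal model the package provides surface point-spread maps,
the two-point temporal-separability experiment, time-dependent sensitivity
(weight) matrices for tomography, and the closed-form separation limit
ΔX = 1/{|∇I/I|·[(T_th − T_BG)/(T_BW/2) + 1]}.

## Worked example

```python
import numpy as np
import usfsim as u

cfg = u.RunConfig()                     # canonical simulation conditions
src = cfg.heat_source()                 # H = 2*alpha*I on the thermal grid

thermal = u.solve_bioheat(src, cfg.tissue_thermal(), snapshot_times=[0.149, 0.397])
print(f"peak focal dT at 0.397 s : {thermal.dT[1].max():.2f} K")
print(f"lateral thermal FWHM     : {u.profile_fwhm(*thermal.lateral_profile(1))*1e3:.3f} mm")

res = u.two_point_experiment(
    0.3e-3, src, cfg.tissue_thermal(), cfg.boundary_geometry(),
    cfg.medium_ex(), cfg.medium_fl(), cfg.source_detector(), cfg.agent(),
    np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 9),
)
print(f"velocity pulse delay dt_X12 : {res['dt_X12']*1e3:.1f} ms")
print(f"velocity pulse width dt_v   : {res['dt_v']*1e3:.1f} ms")
```

prints

```
peak focal dT at 0.397 s : 3.34 K
lateral thermal FWHM     : 0.766 mm
velocity pulse delay dt_X12 : 134.6 ms
velocity pulse width dt_v   : 65.5 ms
```

A 0.4 s FUS exposure at 2.5 MHz raises the focal temperature by ≈3.3 °C —
enough to switch agents with T_th ≈ 38.4 °C on a 37 °C background — while
the thermal focus (0.77 mm) stays narrower than the acoustic one
(0.855 mm).  Two agent-filled voxels only 0.3 mm apart, unresolvable in
the blurred surface image, produce velocity pulses separated by ≈135 ms:
more than the 66 ms pulse width, so they are separable in time.

The same pipelines are scriptable from the shell:

```bash
usfsim preset fig5 --out out/            # two-point experiment bundle
usfsim sensitivity --quantity velocity   # weight matrices, 3 SD placements
usfsim analytics --grad-log-i 4000 --rate 14.2
```

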