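# knucklecrack

A physics simulator of the sound produced by cracking a knuckle.

During an articular release of a metacarpophalangeal (MCP) joint the
articulating surfaces spring apart, viscous adhesion pulls the synovial
fluid into deep tension (tribonucleation), a cavitation bubble forms, and
the recovering ambient pressure then drives a partial collapse of that
bubble.  This package resolves the whole chain for an idealized 2-D joint —
transient squeeze-film pressure, stiff Rayleigh–Plesset bubble dynamics, and
the radiated acoustic waveform — and reproduces the characteristic "crack":
a single dominant pressure peak about 0.1 ms after collapse onset followed
by damped oscillations, with a dominant spectral frequency near 130 Hz.

It is intended for biomechanics / bioacoustics researchers who want a
transparent, scriptable reference implementation of the cavitation-collapse
theory of knuckle-cracking sounds, including its sensitivity analyses
(load, joint acceleration, bubble size, viscosity, anatomy) and the
limiting load beyond which the coupled model stops converging.

## The model

**Geometry and kinematics.** The joint is two eccentric circular arcs with
radii R_m = 6.44 mm (metacarpal head) and R_p = 11.46 mm (phalanx base),
clearance c = R_p − R_m = 5.02 mm, half sector θ₁ = π/4.  With a 1.6 mm gap
at the onset of cracking the eccentricity is e₀ = c − 1.6 mm = 3.42 mm and
evolves under constant separation acceleration: e(t) = e₀ − ½at², a = 72 m/s².

**Squeeze-film pressure.** For film load w, the pressure drop at angle θ is

    Δp(θ) = w / (2π R_m² A) · [ (1 − ε cos θ)⁻² − (1 − ε cos θ₁)⁻² ],
    ε = e/c,

with the standard five-term geometric factor A(ε, θ₁).  At w = 13 N the
film pressure at the joint centre dives to ≈ −3.9·10⁵ Pa, far below the
vapour pressure P_v = 6.5 kPa — the tribonucleation argument for bubble
inception.  The transient suction excess over the fully separated limit,
scaled by the calibrated film load fraction η (see `docs/methods.md`),
gives the ambient forcing p(t), which recovers monotonically to the
zero-load pressure within the 10 ms event.

**Bubble dynamics.** A 200 µm bubble, anchored in equilibrium at inception
(p_G0 = p(0) − P_v + 2S/R₀), obeys the Rayleigh–Plesset equation

    (P_v − p(t))/ρ + (p_G0/ρ)(R₀/R)^{3k} = R R̈ + 3/2 Ṙ² + 4ν Ṙ/R + 2S/(ρR)

with synovial-fluid properties ρ = 1015 kg/m³, µ = 0.4 Pa·s, S = 46.7 mN/m,
k = 1.3 (CO₂, adiabatic).  The equation is integrated in non-dimensional
form with an implicit stiff scheme (Radau, tolerances 10⁻⁷; BDF as
cross-check) over 0.01 s.

**Acoustics.** The radiated (monopole) pressure at r = 0.01 m in a medium of
density ρ_m = 1015 kg/m³ is P_a = ρ_m V̈ /(4πr) with V = 4/3 πR³; the wall
acceleration comes from backward differences of Ṙ.  The waveform is
resampled at 44 kHz, zero-padded to 1 s and Fourier-transformed; the
dominant frequency is the largest non-DC spectral line.  Peak levels are
reported in dB re 20 µPa.

## Worked example

```bash
knucklecrack simulate --out demo --wav crack.wav
```

prints (and writes to `demo/summary.json`):

```json
{
  "converged": true,
  "divergence_reason": null,
  "p0_pa": 23676.723597982258,
  "p_go_pa": 17643.723597982258,
  "min_p_amb_pa": 23676.723597982258,
  "min_p_film_pa": -387668.38398702553,
  "min_r_m": 0.0001292658495174997,
  "final_r_m": 0.0001292658495174997,
  "f_dominant_hz": 129.00000000000003,
  "peak_spl_db": 71.0284036100778,
  "peak_pa": 0.07119511177092497,
  "t_peak_s": 8.776965865362796e-05
}
```

Reading the numbers: the raw film pressure bottoms out at −388 kPa
(`min_p_film_pa`), so cavitation is triggered; the bubble is born in
equilibrium at 23.7 kPa ambient with 17.6 kPa of gas; the recovering
pressure squeezes it from 200 µm down to 129 µm (`min_r_m`) — a *partial*
collapse, so a microbubble persists after the sound.  The radiated waveform
peaks 0.088 ms after onset (`t_peak_s`) at 0.071 Pa and its spectrum is
dominated by 129 Hz — the audible "crack".  `crack.wav` contains the
rendered sound.

Sensitivity sweeps and the convergence limit:

```bash
knucklecrack sweep --param load_w --values 10,11,12,13,14 --out sweep.csv
knucklecrack limiting-load --w-lo 13 --w-hi 24
knucklecrack validate          # collapse/oscillation oracles, solver cross-checks
```

The dominant frequency rises monotonically with film load (86 Hz at 10 N to
171 Hz at 14 N here) and the coupled integration stops converging above
≈ 17 N for the mean anatomy.

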