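# Methods

This note records the model as implemented: its assumptions, the parameters
that matter, the numerical choices, the one calibrated constant, and the
places where the implementation's results differ from values reported in
the experimental/modelling literature on knuckle-cracking acoustics.

## Model chain

1. **Joint geometry and kinematics.**  Two eccentric circular arcs
   (R_m = 6.44 mm, R_p = 11.46 mm, clearance c = 5.02 mm, half sector
   θ₁ = π/4) with film thickness h(θ) = c − e·cosθ.  Articular release is a
   constant-acceleration separation e(t) = e₀ − ½at² with e₀ = 3.42 mm
   (1.6 mm central gap at onset) and a = 72 m/s², the value obtained by
   fitting uniform acceleration between joint-spacing measurements 8 ms
   apart (`acceleration_from_spacing`).  e(t) crosses zero at 9.747 ms,
   inside the 10 ms horizon; the squeeze-film formula is analytic in ε = e/c
   and is evaluated on its smooth continuation through ε = 0 (see
   *Numerics*).  Ligaments, tendons and 3-D shape are ignored.

2. **Squeeze-film (tribonucleation) pressure.**  The classical
   load-supporting solution for a film between two spherical surfaces gives
   the drop Δp(θ, ε) ∝ w/(2πR_m²A(ε,θ₁)).  Two series are exposed:

   * `p_film` — the absolute film pressure P_atm − Δp(0) exactly as the
     formula gives it.  At 13 N it reaches −3.9·10⁵ Pa, far below the
     vapour pressure: cavitation must occur.  Because the formula describes
     *static load support*, Δp does **not** vanish as the joint separates:
     as ε → 0 the ratio bracket/A tends to 2(1−cosθ₁)/(2/3 − cosθ₁ +
     cos³θ₁/3) ≈ 7.567, i.e. a residual ≈ 3.8·10⁵·(w/13 N) Pa offset that
     simply reflects the film still carrying w.
   * `p_amb` — the forcing actually applied to the bubble: the *excess*
     suction over that fully separated limit, multiplied by the film load
     fraction η (below), subtracted from the zero-load pressure
     (P_atm = 101 325 Pa).  This trace starts at its minimum, rises
     monotonically and saturates at P_atm as the joint separates — the
     physically expected relaxation of the transient adhesion suction.

   The split matters: a bubble forced by `p_film` directly would sit in
   several atmospheres of permanent tension and grow without bound at every
   load of interest (verified numerically), which contradicts the observed
   phenomenology (partial collapse, convergence at the baseline load).

3. **Inception.**  The bubble (R₀ = 200 µm) is anchored in mechanical
   equilibrium with the forcing at t = 0: p_G0 = p(0) − P_v + 2S/R₀
   (`inception_anchor = "vapor"` clamps p(0) at P_v when the forcing starts
   below the vapour pressure, giving a vapour-dominated nucleus with
   p_G0 = 2S/R₀ ≈ 467 Pa).  The alternative `"atmospheric"` anchor
   (p(0) = P_atm, p_G0 ≈ 95.3 kPa) is implemented for comparison but
   produces kilohertz ringing at low loads and divergence at the baseline,
   so the vapour/equilibrium anchor is the default.  Ṙ(0) = 0 — the only
   self-consistent start given the equilibrium balance.  No mass transfer
   across the wall, k fixed at 1.3, no thermal model.

4. **Bubble dynamics.**  Rayleigh–Plesset with constant ν = µ/ρ, integrated
   in non-dimensional variables (l = 1 mm, τ = 10 ms, w₀ = 100 N) by an
   implicit Radau scheme at rtol = atol = 10⁻⁷ over 0.01 s.  "Only the
   collapsing phase is simulated" is realized naturally: with the
   equilibrium anchor and a monotonically rising forcing the wall velocity
   is ≤ 0 from the start; a `stop_at_rebound` flag terminates at the first
   upward zero crossing of Ṙ for users wanting the strict reading.

5. **Acoustics.**  P_a = ρ_m V̈/(4πr) (monopole, no retardation,
   ρ_m = 1015 kg/m³, r = 0.01 m), V̈ = 4π(2RṘ² + R²R̈) with R̈ from
   first-order backward differences of Ṙ on the solver grid (the first
   point copies the second).  Spectrum: linear resampling at 44 kHz
   (matching audio practice), rectangular window, zero-padding to 1 s
   (1 Hz resolution — a 0.01 s record alone only resolves 100 Hz multiples),
   real FFT, dominant frequency = argmax over f > 0.  SPL re 20 µPa.
   WAV export is 16-bit PCM mono scaled to 0.9 full scale.

## The calibrated constant

The model as assembled from the printed formulas alone cannot run its own
baseline: with η = 1 the forcing at 13 N starts in tension, the bubble
grows explosively and the solver diverges — at *every* anchor convention.
The resolution adopted here is a **film load fraction η ∈ (0,1]**: only a
share of the film suction excess is communicated to the bubble site.  This
follows the standard argument that part of the joint load is carried by
surrounding tissue and by film regions outside the modelled sector, and it
is the one free convention of the package.

η was calibrated **once**, before any other output was compared:
η = 0.6965, the midpoint of the interval in which the baseline (13 N)
dominant frequency equals the reference 129 Hz.  All other reported
numbers — the 10/14 N frequencies, the limiting loads, the peak time, the
acceleration/viscosity/radius sensitivities — are out-of-sample predictions
made after freezing η, and are reported as computed.

## Agreement and disagreement with the literature values

Computed with the defaults (all figures produced by
`scripts/acceptance.py` / the test suite):

| quantity                           | this package | literature | status |
|------------------------------------|-------------|------------|--------|
| clearance / e₀ / e(1 ms)           | 5.02 / 3.42 / 3.384 mm | same | exact |
| baseline dominant frequency        | 129 Hz      | 129 Hz     | calibration anchor |
| dominant peak time                 | 0.088 ms    | ≈0.1 ms    | agrees |
| waveform morphology                | one dominant negative peak, damped tail | same | agrees |
| dominant frequency at 14 N         | 171 Hz      | 193 Hz     | −11%, inside ±20% |
| limiting load, mean anatomy        | 16.7 N      | ≈15 N      | inside ±2 N |
| frequency monotone in load 10→14 N | yes         | yes        | agrees |
| µ ∈ [0.1, 0.5] Pa·s effect on f    | ≤ 4 Hz      | "insensitive" | agrees |
| R₀ ∈ [100, 300] µm effect on f     | < 6%        | "invariant" | agrees |
| baseline peak SPL                  | 71.0 dB     | ≈83 dB     | **red** |
| dominant frequency at 10 N         | 86 Hz       | 64 Hz      | **red** |
| limiting load, widened corner      | 9.4 N       | ≈6 N       | **red** |

On the three discrepancies:

* **Peak SPL.**  The converged peak pressure is 0.0707 Pa → 71.0 dB re
  20 µPa.  The 83 dB figure corresponds to 0.2825 Pa — larger by a factor
  3.998 ≈ 4.  Evaluating the monopole formula with πr in place of 4πr, or
  using a 5 µPa reference, would each yield exactly 83.0 dB here; with the
  formula and reference as printed/standard the package reports 71 dB.  The
  peak is numerically converged (stable to rtol 10⁻¹⁰, and identical
  whether R̈ comes from backward differences or from the ODE right-hand
  side), and the normalized waveform — the quantity the frequency and
  morphology checks use — is unaffected by any constant factor.
* **10 N frequency.**  The dominant frequency of this model has a low-load
  floor of ≈82–86 Hz set by the quasi-static compression timescale of the
  recovery ramp; it cannot reach 64 Hz at any load.  (The trio 64/129/193
  sits exactly on a 21.48 Hz grid — bins 3, 6, 9 of a 2048-point FFT at
  44 kHz — suggesting the reference values are quantized by an FFT
  convention coarser than the 1 Hz resolution used here.)
* **Widened-corner limiting load.**  For R_m − 0.54 mm, R_p + 1.15 mm
  (ε₀ = 0.76) the convergence boundary is 9.4 N rather than ≈6 N.  The
  direction and the strong geometry sensitivity agree; the margin does not.

One further qualitative difference: the dominant frequency here is *not*
invariant to the joint acceleration (87 Hz at 36 m/s² to 185 Hz at
144 m/s²), because the forcing ramp duration scales with a^{-1/2}.  The
higher-frequency content does grow with acceleration, as expected.

## Numerics

* **Cancellation-safe squeeze-film evaluation.**  The five-term A(ε)
  expression loses all significant digits below |ε| ≈ 10⁻²  (terms of size
  1/ε cancelling to O(ε)).  For |ε| < 0.01 both A and the central ratio
  bracket/A are evaluated from quartic Taylor series whose coefficients are
  exact in cosθ₁; the branches agree to ~10⁻⁹ at the switch (tested against
  a 50-digit oracle).  The series also provide the analytic continuation
  through ε = 0 needed for the last 0.25 ms of the baseline event.  An
  early implementation that clamped ε at zero instead introduced a slope
  discontinuity in the forcing at 9.747 ms whose spurious acoustic spike
  dominated the whole waveform — the continuation is not cosmetic.
* **Divergence classification.**  A run is diverged on integrator step
  failure, R < 10⁻⁹ m, |Ṙ| > 10³ m/s, or R > 5 mm.  The last guard
  (growth beyond the joint scale, where the free-field Rayleigh–Plesset
  picture is void anyway) keeps the converged/diverged boundary monotone in
  the load, which the limiting-load bisection requires.
* **Solver validation.**  (i) Empty-cavity collapse time within 1% of
  0.915·R₀√(ρ/Δp) (and of an independent energy-equation quadrature);
  (ii) small-oscillation frequency within 2% of the linearized (Minnaert)
  value — run with water-like properties, since at µ = 0.4 Pa·s a 200 µm
  bubble is overdamped and has no resonance to measure; (iii) Radau vs BDF
  pointwise agreement, tightening tolerances until < 10⁻⁶ relative
  (achieved already at 10⁻⁷: 1.3·10⁻⁸); (iv) dimensional vs non-dimensional
  integration agreement (1.9·10⁻⁹).  Halving the tolerances moves the
  dominant frequency by < 1%.
* **Tie-breaks and degenerate inputs.**  The dominant-frequency argmax
  takes the lowest bin on exact ties (numpy argmax convention); zero
  waveforms raise a signal error rather than returning −∞ dB; a = 0
  freezes the forcing and the bubble then holds equilibrium to 10⁻⁶
  relative over the full horizon.

## Parameters and defaults

| parameter | default | units | note |
|---|---|---|---|
| R_m, R_p | 6.44, 11.46 | mm | mean anatomy; σ = 1.08, 2.30 mm in sweeps |
| separation at onset | 1.6 | mm | sets e₀ = 3.42 mm |
| θ₁ | π/4 | rad | half sector |
| a | 72 | m/s² | separation acceleration |
| t_end | 0.01 | s | event horizon |
| w | 13 | N | film load, baseline |
| P_atm | 101 325 | Pa | zero-load reference |
| η | 0.6965 | – | film load fraction (calibrated once) |
| ρ, µ, S, P_v, k | 1015, 0.4, 0.0467, 6500, 1.3 | SI | synovial fluid |
| R₀ | 200 | µm | initial bubble radius |
| ρ_m, r | 1015, 0.01 | SI | acoustic medium, distance |
| rtol = atol | 10⁻⁷ | – | stiff solver |
| resample / pad | 44 kHz / 1 s | – | spectrum convention |

## Limitations

Single spherical bubble in an unbounded fluid (no confinement, no
bubble–bubble interaction); constant film load over the event; Newtonian
constant-viscosity fluid inside the Rayleigh–Plesset equation; no synovial
inflow correcting the pressure field; no tissue attenuation between joint
and observation point; the post-peak oscillations are weaker than measured
waveforms, consistent with the single-bubble assumption.  The calibrated η
absorbs every effect that partitions load away from the central film; it is
a convention of this reconstruction, not a measured quantity.
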