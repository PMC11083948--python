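# Methods

This note records the physical model, the sequence and processing design
choices, and the numerical conventions behind `psychemrs`, in the spirit of
a simulator's methods appendix. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Spin model and conventions

Each metabolite is a set of independent proton subsystems of at most
8 coupled spins (Hilbert dimension ≤ 256). The rotating-frame Hamiltonian
is always the full isotropic (strong-coupling) form

    H = Σᵢ 2π νᵢ Iᵢ_z + Σ_{i<j} 2π J_ij (Iᵢ_x Iⱼ_x + Iᵢ_y Iⱼ_y + Iᵢ_z Iⱼ_z)

with νᵢ = (δᵢ − δ_carrier)·ν₀·10⁻⁶ plus any gradient-induced offset.
Second-order (roofing, multiplet-shift) effects are therefore present by
construction; the test suite checks line positions and intensities of an
AX pair against independent eigenbasis transition enumeration.

Fixed conventions, used everywhere and covered by direction tests:

- γ/2π = 42.5775 MHz/T; defaults B₀ = 7.0 T (ν₀ ≈ 298.04 MHz,
  1 ppm ≈ 298.04 Hz), carrier at 4.7 ppm (water); both overridable.
- Propagation ρ → exp(−iHt) ρ exp(+iHt). Hard pulse of phase φ rotates
  about (cos φ, sin φ, 0); a 90° pulse of phase x sends I_z to −I_y.
  Sequences excite with phase y so the detected signal starts at +I_x.
- Detection s(t) = Tr(ρ F₊), picking coherence order −1 of ρ; an
  uncoupled spin at offset +ν yields exp(+2πiνt) and appears at +ν Hz.
  The ppm axis is carrier + f/ν₀·10⁶ (downfield positive).
- Equilibrium is the high-temperature deviation operator Σᵢ Iᵢ_z. When
  subsystem signals are combined, each is weighted by 1/2ⁿ (the
  normalization of the full density operator) times a population weight,
  so equimolar metabolites give equal per-proton intensity regardless of
  subsystem size. Groups of magnetically equivalent *uncoupled* protons
  (Cho N(CH₃)₃, Cr CH₃/CH₂, NAA acetyl) are simulated as one spin with an
  integer weight — exact for uncoupled equivalence, and what keeps every
  bundled metabolite within the 8-spin cap.
- Relaxation is phenomenological: all pulses and delays are exactly
  unitary (trace, purity and Hermiticity conserved to 1e−10, property
  tested), and a mono-exponential T₂ envelope is applied at detection
  using the elapsed *transverse* time (t₁-dependent delays + t₂), so the
  reconstructed pure-shift FID decays as exp(−T/T₂) on the reconstructed
  time axis. Chirp durations are excluded from the envelope; T₁ enters
  only as the justification for assuming fresh equilibrium each ISIS
  transient. Lindblad dynamics, exchange and radiation damping are out of
  scope.

## 2. Saltire chirps

A saltire is the real-valued, equal-amplitude sum of a low→high and a
high→low linear frequency sweep. With the phase referenced to the sweep
centre the waveform is

    w(t) = A cos(πF(t − T/2)²/T + φ₀),

sampled at midpoints with dt resolving the fastest (F/2) modulation by
≥ 8 samples per cycle. On resonance all RF samples lie along x and
commute, so the net flip is exactly 2πA·dt·Σ cos Φ_k and the amplitude
calibration for a requested flip β is closed-form; an exact-propagation
oracle in the tests confirms a 10° saltire to better than 1°. The internal
phase φ₀ offsets both constituent sweeps at fixed amplitude and is used
for the 2-step phase cycle below. The time–bandwidth guard warns below
TB = 10 (defaults give TB = 150).

Shaped pulses propagate piecewise-constant. The public operation offers an
exact per-sample eigendecomposition and a symmetric split-step
(exp(−iH₀dt/2)·exp(−iH_RF dt)·exp(−iH₀dt/2) with cached
eigendecompositions, error O(dt³) per step); the sequence engine uses the
split-step, and the two agree to < 5·10⁻⁴ in propagator norm at 800 Hz
offset in the tests.

## 3. ISIS localization

The minimal complete scheme is the 2³ = 8 on/off patterns of three
slice-selective inversions with signs (−1)^(bits). Inversions are ideal
(the 8-scan sign bookkeeping, not pulse imperfection, is the object of
interest), so each pattern multiplies a cell's longitudinal state by ±1
and the signed sum is 8 inside the triple-slice intersection and exactly 0
outside — verified by brute force over all patterns and cells, and for
arbitrary random two-spin systems, not just singlets. Because localization
precedes excitation, the combination acts as a scalar weight on each
cell's subsequent (arbitrary) signal; the simulator exploits that
linearity but still executes the explicit eight-pattern loop. Slice
membership is a half-open box test (centre ± size/2, [min, max) per axis).

## 4. PRESS baseline

90° – te₁/2 – 180° – (te₁+te₂)/2 – 180° – te₂/2 – acquire. In the default
ideal-profile mode the slice-selective pulses act only on in-slice cells
and crusher pairs purge transverse coherence of any cell failing a slice
test, so only the voxel contributes; chemical shift is refocused at the
echo while J coupling evolves throughout TE. The closed-form consequences
— amplitude exp(−TE/T₂) for uncoupled spins, in-phase amplitude
cos(πJ·TE) and pure antiphase at TE = 1/(2J) for a weak AX pair, and
mixed-phase multiplets for a voxel spanning two compartments — are all
asserted in the tests. A "shaped" mode weights cells by a Bloch-simulated
3-lobe sinc inversion profile for realism studies; it is deliberately
simple and not part of the quantitative test surface.

## 5. The pure-shift element

Per t₁ increment: 8-pattern ISIS block → non-selective 90° → free t₁/2 →
saltire(β) under G₃ → hard 180° → saltire(β) under G₃ → free t₁/2 →
acquire. Coherence selection is realized by explicit integration over an
n_z-point sub-voxel z ensemble of gradient-induced phases (an ideal
CTP projection filter is available as a fast mode; the two agree on peak
positions in the tests).

**Pathway selection.** Writing the total coherence order during the first
t₁/2 as p₀ and between the chirps as p_a, dephasers of area ratio
1 : 3 : −1 (after the first t₁/2, after the 180°, after the second chirp)
give every pathway the phase u·z·(p₀ − 3p_a + 1). The only single-quantum
solution of p₀ − 3p_a + 1 = 0 is (p₀, p_a) = (−1, 0): the observed spin
stays at order −1 through both t₁/2 delays and is stored longitudinally
between the chirps (one first-order sin β transfer at each saltire
crossing — hence the textbook sin²β sensitivity), while the hard 180°
inverts its coupling partners. Chemical shift therefore evolves for the
full t₁ and J coupling refocuses: the interferogram ingredient. With the
ensemble z positions uniform and the base area set to u·Δz = 2π/n_z, every
unwanted integer pathway cancels *exactly* (geometric sum), up to
coherence orders ~n_z/3.

**Gradient balancing.** The stored pathway is transverse for exactly one
chirp duration T_p of G₃ exposure (time to the crossing in chirp 1 plus
the remainder of chirp 2), which the symmetric sequence does not refocus.
A balancing gradient of area −2π·G₃·T_p applied with the final dephaser
rephases it; without it the z ensemble destroys ~85% of the wanted signal.
The same exposure means the detected signal corresponds to evolution time
T + T_p: a constant, known time-origin shift, recorded as
`time_origin_s` in the pseudo-2D metadata and removed as an exact
first-order phase exp(−2πif·T_p) during processing. (No rearrangement of
delays or hard pulses within this chirp–180–chirp topology can refocus
both J and the T_p exposure; the two self-compensating alternatives
J-couple during the element instead.)

**Saltire phase cycle.** Storage via one sweep of chirp 1 and recovery via
the *opposite* sweep of chirp 2 ("mismatched pairing") carries a quadratic
z phase with an in-band stationary point that linear gradients cannot
dephase; it is the recoupling-artifact analogue of this element. A 2-step
cycle of the saltire internal phase (φ₀ = 0, π/2) leaves matched pairings
invariant while mismatched pairings acquire e^(∓2iφ₀) = ±1 and cancel.
The cycle is on by default (`saltire_phase_cycle = 2`).

**G₃ matching.** By default G₃ spreads (sweep − 2·margin) across the voxel
z extent with margin 2000 Hz, so every chemical shift in the ¹H metabolite
window (≥ 0.5 ppm, i.e. ≥ −1250 Hz from the water carrier) is swept well
inside the band at every z; edge-clipped crossings otherwise distort the
peaks nearest the band edge.

## 6. Chunk acquisition and reconstruction

The t₁ increment is locked to the chunk time, Δt₁ = 2τ. Two layouts:

- **half_first (default):** increment 0 contributes its first half-chunk
  (τ); for k ≥ 1 the post-element delay is shortened to t₁/2 − τ so the
  J echo falls at the chunk *centre* (t₂ = τ) and the chunk maps to
  reconstructed times [2τk − τ, 2τk + τ). Centring halves the maximum
  intra-chunk J phase error (±πJτ at the edges) and weakens chunking
  sidebands (at multiples of 1/(2τ) = 50 Hz at the defaults).
- **full:** every increment contributes its first full chunk, J echo at
  the chunk start.

In both layouts the chemical-shift phase of every stitched sample equals
its reconstructed time exactly, so for any J = 0 system the concatenated
FID reproduces a continuous acquisition of the same sequence to numerical
precision — the central correctness oracle of the processing chain (run
with the ideal CTP filter, which isolates the bookkeeping from
finite-ensemble selection residuals; those residuals are real physics,
sit at the few-percent level, and are bounded separately by the
peak-count tests).

Processing: exponential apodization (stated as added Lorentzian width),
zero-fill, FFT with fftshift, the exact time-origin first-order phase,
and zero-order phasing that makes the tallest magnitude peak real and
positive (after the time-origin correction all line centres share one
phase, so this is exact; an integral-maximizing estimator would
back-extrapolate to t = −T_p and mis-rotate by 2πνT_p). The first
time-domain point is half-weighted (standard DFT convention; disable for
Parseval checks). ppm referencing applies a constant carrier offset so a
chosen observed peak sits at its reference shift; it is idempotent.

## 7. Phantoms and the fixture library

Phantoms are ordered axis-aligned box compartments (later entries override
earlier where nested — bottles are boxes, since the localization math is
separable per axis) discretized on a deterministic grid (default 1 mm,
≥ 5 cells across the smallest 5 mm voxel). Fixtures are JSON spin-system
files; shifts printed for the emulated samples are pinned (Prop CH₃
0.98 / CH₂ 2.30; NAA acetyl 1.98; Cr N-CH₃ 3.00; Cho N(CH₃)₃ 3.16; mI H5
3.26 / H2 4.09; Tau N-CH₂ 3.22; Asp CH 3.86; GABA N-CH₂ 2.97), all other
shifts and every J value come from standard solution-NMR literature, noted
per fixture in `source_note`. Brain-phantom concentrations default to
equimolar and are config-overridable. Water is not simulated (suppression
is not modelled); a giant-singlet stress fixture exists but is in no
bundled phantom.

What the generator emulates — and does not: it produces noiseless (or
seeded-Gaussian-noise) signals from ideal hard/shaped pulses in a
perfectly homogeneous B₀ (a per-position offset field hook exists,
default off). Passing tests therefore demonstrate the *method* — exact
ISIS cancellation, multiplet collapse, J-refocusing, sensitivity scaling —
not robustness to B₀/B₁ inhomogeneity, motion, eddy currents, imperfect
inversions or scanner phase cycling. The printed experimental resolution
and SNR figures of real scanners depend on shim and hardware and are
deliberately not reproduction targets; the analysis module reproduces the
*methodology* (FWHM of selected peaks, height-over-noise-σ SNR with a
default 9–10 ppm noise window, per-site detection capability reports).

## 8. Default parameters

| parameter | default | why |
|---|---|---|
| B₀ / carrier | 7.0 T / 4.7 ppm | emulated scanner field; water-centred transmitter |
| β (saltire flip) | 15° | standard pure-shift compromise: sin²β ≈ 6.7% sensitivity vs decoupling purity |
| sweep | 10 kHz | covers G₃ spread + metabolite shift range with margin |
| chirp duration T_p | 15 ms | TB = 150; halves both the time-origin ripple (tails sampled at 1/T_p) and the intra-chirp J error πJT_p relative to longer chirps |
| τ (half-chunk) | 10 ms | J·2τ ≪ 1 for J ≤ 10 Hz; chunk = 80 points at dwell 0.25 ms |
| n_increments | 32 | 0.63 s reconstructed FID, ~1.6 Hz raw resolution |
| n_z | 16 | exact cancellation of unwanted integer pathways up to high order; ≥ 16 guard for ensemble statistics |
| sweep margin | 2 kHz | every metabolite offset swept inside the band at every z |
| dwell / points | 0.25 ms / 80 | 4 kHz spectral width; dwell divides 2τ exactly |
| T₂ (fallback) | 0.3 s | ~1 Hz natural linewidth, typical phantom scale |
| grid step | 1 mm | ≥ 5 cells across the smallest voxel |

All are config-exposed; none is taken from a measured experiment.

## 9. Known limitations

- Finite-ensemble coherence selection leaves few-percent residuals that
  depend weakly on n_z and gradient areas; the ideal CTP filter mode gives
  the artifact-free limit for oracles.
- The delayed time origin (one chirp duration) is corrected exactly at
  line centres but leaves a small dispersive ripple on line tails
  (~linewidth/Δf at offset Δf, falling with shorter chirps).
- Strongly coupled networks (myo-inositol) show genuine second-order
  singlet shifts of order J²/(2Δν); the pure-shift positions of such
  systems are not expected to equal the nominal shifts to within a bin.
- ISIS inversion imperfection, B₁ maps, STEAM/LASER, 2D extensions,
  non-uniform sampling and denoising are out of scope.
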