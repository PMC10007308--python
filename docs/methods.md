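# Methods

This note documents the physical models, parameter defaults, numerical
choices and known limitations of `thzleaf`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Optical model of the leaf

A leaf pixel is a three-component effective medium — liquid water, dry
plant matter (cellulose-like) and air — forming a single homogeneous
absorbing layer of thickness d on a perfect electric conductor (PEC, the
metal mounting platform; reflection −1 at the final interface). The
convention is exp(−iωt), so passive media have ε″ ≥ 0 and m = n + ik with
k ≥ 0.

**Water.** Double-Debye relative permittivity

ε(ω) = ε_∞ + (ε_s − ε_i)/(1 − iωτ₁) + (ε_i − ε_∞)/(1 − iωτ₂)

with defaults ε_s = 78.36, ε_i = 4.93, ε_∞ = 3.48, τ₁ = 8.24 ps,
τ₂ = 0.18 ps — a standard published-style parameterisation of liquid
water at room temperature. Bare double-Debye underestimates absorption
above ~2 THz, so a scalar `calib_scale` multiplies the extinction
coefficient k; `calibrate_absorption` sets it by least squares through
(f, α) anchors. Because α = 4πfk/c is linear in k, the solution is the
closed form s = Σα₀a / Σα₀², exact for a single anchor and idempotent
(always computed against the scale-1 base model). The default anchor is
α(2.71 THz) = 500 cm⁻¹. Side effect worth knowing: the scalar stretch
raises the calibrated α(1 THz) to ≈379 cm⁻¹, above typical literature
values (~220 cm⁻¹); frequency-dependent calibration is future work. The
nominal validity window of the relaxational form is 0.05–6 THz; it is
evaluated without error outside that window (the pipelines need the full
FFT grid, including f = 0, and the static/high-frequency limits are
useful checks), with the slow relaxation still contributing ~0.25% at
1 GHz.

**Dry matter.** Constant n = 1.5 and α = 10 cm⁻¹ × f/THz (equivalently, a
frequency-independent k ≈ 0.0239) — a weakly absorbing, dispersionless
stand-in for cellulose-dominated tissue.

**Mixing.** Linear volume-weighted complex refractive index,
m_eff = f_w m_w + f_d m_d + f_a, the simplest defensible effective-medium
rule for sub-wavelength composites. It is isolated behind
`effective_leaf_index`/`mix_index` so a Landau–Lifshitz–Looyenga rule can
be substituted later without touching the pipelines.

**Layered reflectivity.** `stack_reflectivity` implements the recursive
Rouard/transfer-matrix method for an arbitrary layer list at oblique
incidence, s or p polarization, over a PEC or free-space backing, with
the decaying branch of m·cosθ chosen per layer. The default TDS geometry
is s-polarized at 8°, where the s/p difference is below 1%. The test
suite checks it against an independent 30-term multiple-bounce (Airy
series) summation on random 1–3-layer stacks to <1e−6 relative, and
property-tests passivity (|r| ≤ 1).

For the single leaf-layer-on-PEC case the recursion reduces to
r = (r₀₁ − x)/(1 − r₀₁x) with x = e^{2iβ}; the *internal* (metal-backed,
double-transmitted) component is r_int = r − r₀₁. Note a physical subtlety
verified numerically: the full coherent |r| is **not** monotone in water
fraction — etalon fringes and the growth of the front Fresnel coefficient
with n_eff make |r| rise again at high water content — whereas |r_int| is
strictly decreasing in water fraction over the whole physical range. The
hydration-sensitive observable in both pipelines is therefore the
metal-backed return.

**Penetration depth.** Power 1/e depth δ = 1/α, reported in µm and capped
at 5000 µm for near-lossless media (display convenience; the cap is a
parameter).

## 2. The synthetic phantom

`generate_phantom` draws, as a pure function of (preset, shape, pitch,
seed): an elliptical blade with a wobbly margin; a vein skeleton (midrib
plus parallel secondaries for the bamboo-style preset or oblique branching
secondaries for the celtis-style preset); and smooth seeded noise fields.
Water fraction tapers from ~0.8 at vein cores to ~0.4 ± noise on the
lamina; dry matter is a constant 0.15 on-leaf; thickness is 200 µm ± 10%
smooth jitter, boosted up to ~2× at vein cores (real midribs are thicker
than lamina — and without the boost every vein pixel would cross the
−60 dB threshold during the fast drying phase, erasing the staged
blue-count decline the generator is meant to produce). Off-leaf pixels
are bare metal (zero thickness and fractions). Vein coverage lands in
[0.05, 0.30] of leaf pixels. An optional Gaussian thickness ridge
emulates a crease/curl; it is off by default.

**Drying law.** Continuous piecewise-exponential multiplier on the water
fraction with three stages: rate 0.06 min⁻¹ before 20 min (the plucked
leaf still transpiring: ~2/3 of mobile water lost), 0.0015 min⁻¹ until
120 min (stomata closed, marginal loss), 0.01 min⁻¹ afterwards (slow
cuticular decay), floored at 5% of initial water. Vein pixels divide all
rates by `vein_retention = 3` (water persists along veins). The 20/120 min
breakpoints are narrative defaults of the drying scenario being emulated,
not a fitted model; the staging *analysis* in the LFI pipeline makes no
use of them. The rates were chosen by forward analysis of the optics —
they place the late-scan lamina in the echo-dominated reflectivity regime
at 1 THz and spread vein threshold-crossings across all three stages —
and are documented here precisely because the generator's defaults define
the simulated study conditions.

What the phantom does **not** emulate: biophysical transpiration/stomatal
dynamics, species-accurate morphometry, 3-D internal structure, surface
roughness/scattering, water-vapor lines in the beam path. Tests passing on
the phantom show the *processing chains* are correct and the *contrast
mechanisms* behave as the physics dictates; they do not validate
biological rate constants.

## 3. TDS pipeline

**Pulse.** Derivative-of-Gaussian (typical photoconductive-antenna
emission), zero area, unit peak; the Gaussian width is root-found so the
Hilbert-envelope FWHM equals the configured 0.6 ps. Default window
30 ps @ 0.05 ps sampling.

**Noise.** Additive white Gaussian in the time domain; the level is set
so the mean rFFT noise-bin magnitude (Rayleigh mean σ√(Nπ)/2) sits
`dynamic_range_db` (default 90 dB) below the reference spectral amplitude
at 0.9 THz. `dynamic_range_db=None` gives noise-free synthesis.
Frequency-shaped noise is out of scope.

**Per-pixel synthesis.** Inverse rFFT of (reference spectrum × r(f)).
numpy's FFT synthesises exp(+iωt) while the optics use exp(−iωt), so r is
conjugated — otherwise echoes land at negative delay (a bug actually
caught by the echo-delay oracle test).

**Raster scan.** Row-major from the top row (serpentine as a flag); pixel
p is acquired at start + p·dwell with the phantom advanced to that time,
vein-aware. The default 80×90 @ 630 ms frame spans 4536 s — the leaf loses
most of its mobile water within one frame, producing the top-to-bottom
brightening gradient.

**Spectral images.** Tukey(α = 0.25) window over the full trace, rFFT,
nearest-bin sampling at the requested lines (bin recorded); amplitude
normalised per image to its max; phase unwrapped along frequency within
the band and referenced to a bare-metal pixel (identically zero there).
Phase is left unnormalised. An optional `gate="subsurface"` mode opens a
smoothstep gate 1 ps after the front-surface reflection before the FFT,
isolating the metal echo; the gated mode is for amplitude analysis only
(the bare-metal return itself arrives before the gate).

**Drying-gradient statistic.** `drying_gradient` is the bottom-10-rows
minus top-10-rows mean over leaf pixels. Because the phantom's random
water texture leaves a static top/bottom asymmetry of the same order as
small-dwell drift, the drying-induced gradient is measured as a
difference-in-differences (`drying_gradient_drift`): the statistic on the
drying scan minus the same statistic on a frozen scan of the same
phantom, both on sub-surface-gated 1 THz amplitude images. This is
positive for a drying leaf and shrinks monotonically with pixel dwell.

**Inverse model.** `recover_optical_depth` gates the metal echo at its
predicted delay 2nd·cosθ_int/c (Gaussian gate, halfwidth 1 ps), takes the
spectral amplitude ratio to an identically gated bare-metal reference and
corrects for the front-interface Fresnel transmission, recovering the
double-pass power optical depth α·2d/cosθ_int within a few percent on
noise-free uniform leaves (tested at 5%).

**Penetration surface.** δ(f, t) from the effective-medium α of the
spatially averaged composition at each time point; decreasing in f
in-band, non-decreasing in t under drying, and exactly 20 µm for pure
calibrated water at 2.71 THz.

## 4. LFI pipeline

**Signal model.** Steady-state excess-phase (Lang–Kobayashi steady state)
self-mixing: φ_s(t) = 4πLf(t)/c + arg r, with the linear intra-pulse sweep
f(t) from 2.71 THz spanning 600 MHz over 500 ns, L = 1.2 m (≈4.8 fringes),
effective feedback C_eff = C·|r| (default C = 0.3, Henry factor α_H = 3),
voltage ∝ |r|·cos(φ_fb) plus DC offset and optional noise. The equation is
solved by damped Newton after exact 2π-rebasing (C < 1, unique solution,
residual < 1e−10) or by continuation with nearest-root tracking along the
sweep axis (C ≥ 1, reproducing hysteresis jumps at branch folds; a
`return_multistable` flag marks the strongly multistable C ≥ 4.6 regime).
Transient laser dynamics and thermal drift are out of scope.

**Front-surface exclusion.** By default the field re-coupled into the
cavity is the metal-backed double-pass component r − r₀₁ only
(`include_front_reflection=False`). Rationale: a mirror-smooth wet leaf
front would reflect ≈ −9 dB relative to bare metal, making the observed
≥ 60 dB hydration contrast physically impossible; the deep contrast
requires the detected return to be dominated by the double-transmitted
path (the cuticle's specular term being scattered out of the return path
by curvature/roughness that the flat phantom does not otherwise model).
With this choice, wet veins sit 70–140 dB down and dry lamina ≈ 35 dB
down, bracketing the −60 dB threshold as observed.

**Field curvature.** The post-objective scan adds a quadratic phase
across the field (default 20 rad at the corner). It scrambles phase maps
but moves the recovered amplitude by ≲5e−4 relative — the quantitative
sense in which the scheme is "predominantly amplitude detecting". Note a
windowed-FFT peak estimator cannot be *exactly* phase-invariant when the
sweep holds a non-integer fringe count; the tests assert 1e−3.

**Amplitude recovery.** Mean removal, periodic (DFT-even) Hann window,
rFFT; the dominant non-DC bin and its larger neighbour give the
fractional offset via the Hann main-lobe closed form δ = (2ρ−1)/(1+ρ),
and the peak is rescaled by the main-lobe shape and coherent gain. Exact
(machine precision) for integer-bin cosines — the periodic Hann spectrum
of such a tone occupies exactly three bins — and <0.1% off-bin in
practice (asserted at 2%).

**Frames and statistics.** Within-frame drying is neglected (25 s frame
vs minutes-scale drying; the TDS pipeline, with its 75 min frames, models
it). `db_map` is 20·log₁₀(amplitude/frame max); the frame max is the
bare-metal region, matching a peak-referenced threshold. A global
reference would be a one-line change (divide by a fixed amplitude);
per-frame is the default. `blue_fraction` counts leaf-mask pixels at or
below the −60 dB threshold; `hydration_series` assembles the fraction
against frame times.

**Staging fit.** Continuous piecewise-linear least squares
y ~ 1 + t + relu(t−b₁) + relu(t−b₂), exhaustively over all admissible
breakpoint pairs on the frame-time grid (suffix-sum Gram matrices give
O(1) normal equations per pair; the whole 720-frame search takes
~0.1 s), ties toward earlier breakpoints, minimum segment length 3
frames. n_breaks ∈ {0, 1, 2}; the fit reports the improvement over a
single line and flags it non-significant below 1% of the total SS.
`synthesize_hydration_series` generates noise-free three-stage
piecewise-linear series for self-consistency tests; on the *simulated*
frame series (piecewise-exponential drying through a nonlinear optical
map) the early breakpoint is recovered at 20 min while the late, smooth
decay can place the second knee later than 120 min — an honest property
of fitting lines to curves, visible in the README example.

## 5. System metrics and report

Pixel pitch = extent/grid per axis; frame time = pixels × dwell (4536 s
TDS, 25 s LFI for the defaults). The Rayleigh resolvable feature is
1.22·λ·N with the nominal instrument-spec wavelength convention
λ[µm] = 300/f[THz] and a default effective f-number N = 4 — the unique
value consistent with the published 1464/732 µm pair at 1.0/2.0 THz. At
2.75 THz this yields 532 µm and at the LFI carrier 540 µm; the published
536 and 396 µm figures are not reproducible from 1.22·λ·N with any single
N (the LFI optics' effective aperture is not derivable from the stated
lens geometry), so the tool reports the configured-N values and the
discrepancy is documented here rather than forced. The Markdown report is
deterministic for fixed inputs (no timestamps) and embeds a config hash;
images are optional matplotlib PNGs.

## 6. Problem sizes used in the checks

The acceptance-style tests run scaled-down scenes chosen to exercise every
code path at comfortable margins: 40×45 TDS scans (three dwell settings),
a 64×64 uniform-leaf cube for the inverse model, 32×32 LFI frames with 128
samples/pulse (720-frame sequences), and 100 random stacks for the optics
oracle. The defaults in the config dataclasses remain the full-scale
instrument values (80×90 TDS, 500×500 LFI, 512 samples).

## 7. Known limitations

* Scalar water calibration distorts the low-frequency absorption (see §1).
* No rough-surface/scattering model; the front-surface exclusion in the
  LFI path is a stand-in for unmodelled non-specular loss.
* No anisotropic tissue optics, no frequency-dependent metal conductivity.
* The piecewise-linear staging model is this package's construction; the
  dehydration stages themselves are a generative assumption of the
  phantom, with breakpoints at 20/120 min as the emulated scenario.
* Phase images are metal-referenced and frequency-unwrapped but not
  normalised; no deconvolution or full material-parameter extraction.
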