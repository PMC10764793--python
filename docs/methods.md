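# Methods

This note documents the models, numerical choices and limitations of
`mwiphase`.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Optical model

Tissue is treated as dielectric spheres (index `n_sc`) in ground matter
(`n_g`).  Two relations ground the phantom and the interpretation of
phase maps:

- **Median refractive index** — `n_m = c_sc·n_sc + (1 − c_sc)·n_g`,
  affine in the scatterer volume concentration `c_sc ∈ [0, 1]`.
- **Scattering coefficient** —
  `µ_sc = 3.28 π r² V_S (2πr/λ)^0.37 (n_sc/n_g − 1)^2.09`.
  Units are fixed to µm for `r` and `λ` and µm⁻³ for `V_S`, making µ_sc
  come out in µm⁻¹; the relation states no units itself, and this is
  the only dimensionally self-consistent choice given the mixed powers.
  The non-integer exponent restricts the model to `n_sc ≥ n_g`;
  violating it raises an error rather than producing a complex/NaN
  result, since the model's context (scatterers denser than ground
  matter) makes the inverted case meaningless.
- **OPD → phase** — `φ = wrap(2π·ΔOPD/λ)`, the standard interferometric
  relation, wrapped to (−π, π].

`V_S` is derived from `c_sc` and the sphere volume when not given, so a
medium description cannot be internally inconsistent.

Wrap convention: `wrap(x) = π − mod(π − x, 2π)` keeps +π and maps −π to
+π, so every phase has a unique representative and `|wrap(a − b)| ∈
[0, π]` is well defined.  Both bounds are asserted on every emitted map.

## Phase extraction

The scene carries a spatial carrier fringe along the columns.  Each
line is demodulated by the analytic-signal construction (mean removal;
1-D DFT; zero strictly negative bins, double strictly positive bins,
keep DC and Nyquist; inverse DFT; phase = argument, envelope =
modulus).  This is exact for integer-cycle cosines and is the natural
reading of per-line phase profiles.  A full 2-D spectrum route with a
regularized (Wiener-style) deconvolution by the system transfer
function, `S·conj(R)/(|R|² + ε)`, is available as `phase_mode=
"fourier2d"`; with an ideal (identity) transfer function it reduces to
the analytic route.

Key numerical points:

- **Carrier cancellation.** The carrier frequency is common to all
  bands, so it cancels exactly in the inter-wavelength difference
  `Δφ = |wrap(φ_blue − φ_red)|`.  Classification therefore needs no
  carrier removal or unwrapping.  For per-band offset inspection,
  `remove_carrier` subtracts the known/estimated ramp.
- **Carrier estimation.** The dominant positive bin of the scene's
  mean-line spectrum.  A flat (matte) white strip carries no carrier,
  so the strip cannot anchor the frequency estimate.
- **White-strip phase anchor.** The per-band phase is referenced to the
  white strip *only when the strip itself carries a fringe* (strip
  envelope ≥ 10 % of the tissue envelope).  Demodulating a flat strip's
  residual noise would produce a random per-column phase and inject it
  into every image row; with a flat strip the anchor is identically
  zero and referencing is the identity.
- **Degenerate lines.** A perfectly constant line has no fluctuation to
  demodulate; its phase is defined as 0, its envelope as 0, the line is
  flagged, and a single warning reports the count.
- **Edge columns.** The outermost 2 % of columns per side are flagged
  unreliable (finite-support demodulation artifacts) and excluded from
  classifier training and scoring.

## Preprocessing

The display path follows the chain: white normalization → histogram
equalization → 256-level normalization → 3×3 moving average.  The
equalization maps each value to `floor(cdf·255 + 0.5)`; rounding is
half-up throughout; borders are reflect-padded (avoiding the dark halos
zero padding would produce).  The moving-average filter is the plain
window mean `(1/(n·m))·Σ NI` (the denoising "recovered image" filter).

The *phase* branch deliberately stops after white normalization plus
the optional moving average, staying in floating point: equalization is
a nonlinear intensity remap and 8-bit quantization alone injects on the
order of 1e-2 rad of phase noise, which would destroy quantitative
phase recovery.  Both branches are exposed through `PreprocessConfig`;
the order of the two middle display stages is configurable since either
order is defensible.

## Phantom

`render_phantom` produces, per band λ: a flat white strip at intensity
1.0; tissue `R(λ)·[1 + m·cos(2πf·x/N + φ(x, y, λ))]`; additive Gaussian
noise.  Defaults: 224×192 px, 128 bands at 380–1015 nm (5 nm step),
strip rows 0–32, carrier f = 8 cycles, modulation depth m = 0.5, noise
σ = 0.02 of full scale, one tumor ellipse with 56×44 px semi-axes at
depth 16 µm; media `n_g = 1.36`, `n_sc = 1.45`, `c_sc = 0.1` (normal)
vs `0.3` (tumor), i.e. Δn = 0.018 and a round-trip OPD of 0.576 µm
(≈2.4 rad of blue/red shift).  One seed drives all stochastic draws;
identical scenes render bit-identically.

- **Band reflectance** `R(λ) = exp(−k·µ_sc(λ)·λ_ref/λ)` with λ_ref =
  632 nm and `k` calibrated so R(632) ≈ 0.6 — a monotone map of the
  scattering coefficient in which shorter wavelengths attenuate faster.
  No absolute reflectance scale is claimed.
- **Depth visibility** `vis(λ, d) = exp(−max(0, d − L(λ))/τ)`,
  `L(λ) = 600·(λ/632)⁴ µm`, `τ = 50 µm`.  This is phenomenological: it
  reproduces the qualitative asymmetry that a tumor ~400 µm deep is
  fully visible at 632 nm (L ≈ 600 µm) yet retains <1 % contrast at
  446.6 nm (L ≈ 150 µm).  The exponent is a modeling choice, not a fit.
- **Diffusion-blurred footprint.** The tumor's optical phase footprint
  is its ellipse indicator blurred with a Gaussian PSF, σ = 10 px
  (≈400 µm at the 40 µm/px scale of the emulated instrument),
  representing lateral photon diffusion in diffuse reflectance.  The
  *truth mask* remains the hard ellipse (`truth == depth_map > 0`).
  This is not only physical but necessary for well-posedness: the
  fringe of a phase profile with swing Δφ occupies a sideband roughly
  Δφ times the profile bandwidth (the FM/Carson rule), and with an
  8-cycle carrier on 192 columns a hard-edged 2.4 rad step leaks across
  the opposite carrier lobe, corrupting demodulation by ~1e-2 rad even
  far from the edge.  With σ = 10 px the sidebands clear the lobe and
  interior recovery is accurate to a few 1e-4 rad.
- **Training sets** jitter tumor center (±8 px), semi-axes (±15 %) and
  depth (±10 %) per sample, resampling draws that would push a tumor's
  halo outside the tissue, and give each sample a fresh noise seed.

What the phantom does *not* emulate: speckle, camera noise beyond
additive Gaussian, spectrally structured illumination, absorption
chromophores, multi-layer tissue, or genuine volumetric light
transport.  Passing tests on the phantom therefore demonstrate the
correctness of the *computational* pipeline under its stated physics,
not clinical performance on real tissue.

## Classifier and evaluation

A single threshold on Δφ, chosen by exhaustive sweep over midpoints
between consecutive distinct pooled feature values (plus one candidate
below the minimum), maximizing Youden's J; ties resolve to the lowest
threshold, and between polarities to `tumor_above`.  A model with
J < 0.05 is flagged uninformative.  Classification is strictly
pixelwise (`dphi > threshold`), with no spatial postprocessing; ties at
the threshold classify as normal.

Evaluation counts TP/FP/TN/FN over non-excluded pixels (the white
strip, a one-row filter halo around it, and the flagged edge columns
are excluded from both training and scoring).  Sen, Spec and accuracy
follow the standard definitions; per-sample rows carry FN ratio =
100 − Sen and FP ratio = 100 − Spec exactly, and the report appends an
arithmetic-mean row to 3 decimals.  Zero denominators raise an explicit
error instead of returning NaN.

## Problem sizes and determinism

The bundled scenes are sized for seconds-scale runs: the default
224×192×128 cube renders in under a second and the full pipeline on it
takes about the same.  Test scenes use a two-band (445/630 nm) variant
where the spectral axis is irrelevant.  All randomness flows from
explicit seeds; reruns of the pipeline on the same inputs are
byte-identical.

## Known limitations

- Wrapped phase only: Δφ folds at π, so OPDs whose blue/red shift
  exceeds π alias downward; the default phantom keeps the plateau at
  ≈2.4 rad, safely below the fold.
- The analytic-signal route assumes a dominant carrier along one axis;
  scenes without a fringe (or with a purely vertical one) need the
  `carrier_axis` argument.
- The threshold classifier uses the Δφ feature alone; band intensities
  are deliberately not mixed in, keeping the decision interpretable.
- ENVI support covers the common text-header dialect (bil/bip/bsq,
  uint8/int16/uint16/float32) without georeferencing fields.
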