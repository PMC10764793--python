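# mwiphase

Multi-wavelength interference (MWI) phase imaging for hyperspectral
diffuse-reflectance cubes, with pixelwise tumor delineation.

## The problem

Intraoperative assessment of tumor margins (e.g. in breast-conserving
surgery) needs a fast, label-free way to tell malignant from normal
tissue over a whole resection surface.  Malignant tissue has a higher
refractive index than normal tissue, so light reflected from it
accumulates a different optical path.  A hyperspectral (HS) camera
records one grayscale image per wavelength band (~128 bands across
380–1050 nm); comparing the *phase* of the recorded intensity pattern at
a blue band (446.6 nm, superficial) and a red band (632 nm, deep) against
an in-scene white-paper reference turns that refractive-index contrast
into a per-pixel feature that a simple classifier can threshold.

`mwiphase` implements the full computational pipeline — preprocessing,
Fourier-domain phase extraction, inter-wavelength phase-shift mapping,
threshold training and Sen/Spec evaluation — together with a
physics-based synthetic phantom generator so everything is testable
end-to-end without access to clinical data.

## Method in brief

For each operating band the image is normalized against the white
reference and each line is demodulated with the analytic-signal
(Hilbert) construction: Fourier transform, zero negative frequencies,
double positive ones, inverse transform; the argument is the local
wrapped phase φ(x, y) ∈ (−π, π].  The classification feature is the
absolute inter-wavelength phase shift

    Δφ(x, y) = |wrap(φ_blue − φ_red)| ∈ [0, π],

in which the common spatial carrier cancels exactly, leaving the
tissue-induced optical-path difference 2·d·Δn (round trip at depth d,
index contrast Δn = n_m,tumor − n_m,normal).  The tissue optics behind
the phantom use the volume-weighted median index
n_m = c_sc·n_sc + (1 − c_sc)·n_g and the mono-disperse sphere scattering
law µ_sc = 3.28πr²V_S(2πr/λ)^0.37(n_sc/n_g − 1)^2.09.

A single threshold on Δφ is trained by exhaustive sweep maximizing
Youden's J = Sen + Spec − 1; evaluation reports per-sample sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy, with a mean row, in the
style of a per-specimen study table.

## Worked example

```python
import mwiphase as mw

scene = mw.default_scene(seed=42)          # 224x192 px, 128 bands, one tumor
phantom = mw.render_phantom(scene)
result = mw.run_pipeline(
    phantom.cube,
    reference_strip=scene.reference_strip,
    truth=phantom.truth,
)
print(f"bands used:      {result.actual_blue_nm:.1f} nm / {result.actual_red_nm:.1f} nm")
print(f"trained model:   dphi > {result.model.threshold:.3f} rad -> tumor "
      f"(Youden J = {result.model.youden_j:.3f})")
print(f"sensitivity:     {result.metrics.sen_pct:.2f} %")
print(f"specificity:     {result.metrics.spec_pct:.2f} %")
```

prints

```
bands used:      445.0 nm / 630.0 nm
trained model:   dphi > 1.066 rad -> tumor (Youden J = 0.993)
sensitivity:     99.73 %
specificity:     99.55 %
```

The 5-nm spectral grid selects 445/630 nm as the bands nearest the
446.6/632 nm targets.  The trained threshold (≈1.07 rad) sits midway up
the tumor's diffusion-blurred phase transition (plateau ≈2.4 rad), and
the classifier recovers the elliptical tumor against the known phantom
truth with Sen/Spec above 99 %.

The same flow is available from the shell:

```sh
mwiphase simulate --out sim/                                  # render the default scene
mwiphase run --cube sim/cube.raw --reference-strip 0:32 \
             --mask sim/truth.png --out run/                  # train + evaluate
mwiphase report run/metrics.csv                               # table with mean row
```

## Layout

- `mwiphase.hs_io` — ENVI cube and PNG mask I/O, band selection
- `mwiphase.tissue_optics` — mixture index, scattering law, OPD→phase
- `mwiphase.phantom` — synthetic scene generator with ground truth
- `mwiphase.preprocess` — white normalization, equalization, mean filter
- `mwiphase.phase_mwi` — analytic-signal demodulation, shift maps, stacks
- `mwiphase.classify_eval` — threshold training, confusion metrics, tables
- `mwiphase.pipeline` / `mwiphase.cli` — end-to-end orchestration

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
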