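# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `mre_ela`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Wave model and sign conventions

A harmonic scalar signal `s(t) = A cos(ωt + θ)` is represented by the complex
amplitude `U = A e^{iθ}`, i.e. `s(t) = Re[U e^{+iωt}]`. The temporal DFT in
`waves.temporal_harmonic` uses the kernel `e^{−iω t_j}` with normalisation
`2/n`, so that convention is exact at the sample level: a pure cosine of
amplitude A and phase θ maps to `A e^{iθ}` to machine precision (verified for
random draws).

Under this convention a plane shear wave propagating toward increasing ξ in a
homogeneous viscoelastic medium with complex shear modulus `G* = G′ + iG″` is

    U(ξ) = A e^{−ikξ},   k = ω √(ρ/G*)  (principal branch)

The principal square root has `Re k > 0` and `Im k ≤ 0` for `G″ ≥ 0`, so the
wave decays away from the source, and the Helmholtz quotient
`−ρω²U/∇²U = ρω²/k² = G*` returns the true modulus **with the correct sign of
the loss modulus**. This consistency between simulator, extraction and
inversion is the load-bearing convention of the package; the round-trip test
on the noise-free phantom checks it end to end.

Image geometry: axis 0 is the row direction with row 0 at the **top** of the
field of view; "bottom-to-top" propagation therefore means decreasing row
index, and in the spatial-frequency plane (cycles/m, `numpy.fft.fftfreq`
layout) a wave travelling toward unit direction **d** occupies the half-plane
`κ·d < 0`.

## Synthetic data: what it emulates, what it does not

`synthetic.simulate_wave_series` produces matched ±MSG wrapped phase series:
displacement encoded as `±g·u(x,t)` (encoding gain g, default 2 rad at unit
amplitude so that wrapping is actually exercised), plus a static low-order 2D
polynomial background phase (random coefficients, default scale 0.5 rad),
Gaussian phase noise per image (default sd 0.05 rad), eight temporal offsets
over one vibration period, 128×128 over a 25 mm field of view at 900 Hz.
Reflections are modelled as a counter-propagating wave re-entering from the
far edge with relative amplitude `reflection_coefficient`.

Deliberate simplifications:

* plane-wave superposition, not a full viscoelastic FEM/FDTD solve; no mode
  conversion, no compression-wave contribution, no geometric spreading;
* two-region phantoms are piecewise constant and do **not** enforce
  displacement/stress continuity at the junction; recovery tests therefore
  exclude a 3-pixel band either side of the boundary;
* density is fixed at 1000 kg/m³ (soft-tissue convention) and the
  phase-per-displacement constant is arbitrary — the inversion is invariant
  to any complex rescaling of the field, which the tests check bit-exactly;
* no RARE readout simulation, B1 inhomogeneity, or motion artifacts.

Passing tests on this generator therefore demonstrate correctness of the
processing chain under its own forward model, not robustness to every
artifact of real acquisitions.

The cohort generator draws per-animal `|G*| = baseline + slope·score + noise`
(defaults: 3200 Pa baseline, −300 Pa per score point, 150 Pa noise, 15
diseased / 7 control animals, scores in 0.5 steps) with a stable loss angle,
faster posterior softening, fibronectin fold-change coupled to softening, and
contrast-uptake metrics independent of stiffness — the qualitative structure
of a neuroinflammation cohort, not a fit to any dataset.

## Processing chain

Order: phase difference → spatial unwrap → temporal first harmonic →
Butterworth band-pass → directional filter → Helmholtz inversion → ROI
summaries. The `ComplexWaveField.provenance` list records the applied stages
append-only, and tests assert the order.

* **Phase difference**: `(pos − neg)` rewrapped to (−π, π]. Cancels static
  phase exactly and doubles motion encoding.
* **Unwrapping**: reliability-sorted 2D unwrap (scikit-image) per temporal
  frame. Any global 2π·m frame offset is irrelevant: it lands in DFT bin 0,
  which the harmonic extraction discards.
* **Band-pass**: radial Butterworth,
  `H(k) = [1 − 1/(1+(k/k_low)^{2n})]·[1/(1+(k/k_high)^{2n})]`, order 3,
  defaults `k_low = 0` (high-pass off), `k_high = 2000` cycles/m. |H| ≤ 1, so
  spectral energy never increases. The high-pass is off by default for a
  measured reason: with loss angles around 0.3 the wave's spectral peak
  (≈ 520 cycles/m for 3 kPa at 900 Hz) is broadened by the attenuation rate
  (≈ 80 cycles/m), and removing low-k components — even just DC — leaves a
  smooth residual that decays more slowly than the wave itself, biasing the
  deep, low-amplitude part of the image by several percent. Statics are
  already cancelled by the ±MSG subtraction, so the high-pass buys nothing by
  default; it remains available in the config for data with residual trends.
* **Directional filter**: half-plane `κ·d < 0` with a raised-cosine
  transition of width 400 cycles/m across the dividing line (well below the
  ≈ 520 cycles/m carrier, so a forward wave is untouched and a reflected one
  suppressed below 1% away from the image border).
* **Mirror extension**: both spectral filters operate on an even (mirror)
  extension of the field, doubling each axis. The plain periodic FFT sees a
  large value jump between the source edge and the opposite, fully attenuated
  edge; its leakage contaminated ROI means by 10–22% in round-trip
  experiments. Mirror extension removes the value jump (a derivative kink
  remains), confining distortion to a border band of roughly 16 pixels, which
  the validity mask and mask erosion handle. Field-level comparisons in the
  tests therefore use a 16-pixel interior margin.

## Inversion and summaries

* **Laplacian**: 5-point stencil, nearest-edge padding; the outermost pixel
  ring is always invalid.
* **Validity mask**: invalid where `|∇²U|` falls below
  `threshold × median(|∇²U|)` over the support (default threshold 3), capped
  at half the 99.5th percentile so uniform-amplitude fields are never
  rejected wholesale. The threshold is deliberately above 1: in attenuating
  media most of the image sits at the noise floor, where the quotient yields
  small moduli with random phase; including such pixels dilutes ROI means
  toward zero. Three times the floor is a Rose-criterion-style detectability
  cut.
* **Stencil-bias correction** (optional, off by default to match a plain
  Helmholtz inversion): the discrete second difference returns
  `−(2−2cos kh)/h²` instead of `−k²`, overestimating G* by
  `(kh)²/(2−2cos kh)` (≈ 1.033 at 10 pixels per wavelength). The correction
  iterates the complex factor from the local wavenumber estimate; it is exact
  for axis-aligned propagation. With it the noise-free phantom round trip is
  accurate to < 1%; without, the stencil bias (plus small filter residuals)
  keeps the error near 4%.
* **Averaging**: complex G* is averaged over `ROI ∩ valid` (after a 2-pixel
  ROI erosion against stencil edge effects), and G′, G″, |G*|, φ are derived
  from the single complex mean, keeping the four scalars mutually consistent.
  Averaging per-pixel |G*| instead is available (`averaging="magnitude"`) as
  a sensitivity check; it is the larger of the two whenever pixel phases
  disagree.
* **ROI split**: exact binary partition of the brain mask at the junction,
  accepting either a straight-line index or an arbitrary boolean anterior
  mask (anatomical boundary); no pixel is lost or duplicated.
* **Map precision**: modulus maps are stored as complex64. Single precision
  is ample for the physical range (10²–10⁵ Pa) and makes the quotient
  exactly invariant to rescaling of the input field at the stored precision.

## T1 mapping

Two-parameter saturation-recovery model `S(TR) = S0(1 − e^{−TR/T1})`, fitted
voxelwise by bounded nonlinear least squares on the magnitude signal
(initialisation: S0 from the longest TR, T1 from the log-linearised first two
points; accepted range 1–10000 ms). A three-parameter variant with a constant
offset is available behind the `model` flag. No Rician bias correction: the
intended regime is high SNR. Default TR array: 230, 460, 1061, 1485, 2080,
3080, 7500 ms.

Accuracy: the noise-free round trip recovers T1 to < 0.1%. At SNR 50
(noise sd = S0/50) the Cramér–Rao bound for this model and TR array puts the
per-voxel estimator sd at 4.6–5.6% of T1 across 800–2500 ms, and the fit
operates at that bound (median absolute per-voxel error ≈ 3–4%); the
ensemble median T1 over 200 voxels is accurate to well under 2%. Both the
per-voxel scatter and the ensemble accuracy are reported by the acceptance
script, since no estimator can beat the bound on the former.

delta-T1 averages the masked T1 per slice, then across slices unweighted
(each slice counts once), and subtracts post-contrast from pre-contrast:
positive values mean gadolinium uptake. SI% applies
`(post − pre)/pre × 100` to across-slice mean signal intensities. The two are
independent metrics (7-TR mapping vs. T1-weighted signal), kept separate.

## Statistics

Two-sided p-values throughout; no multiple-testing correction by default
(optional Benjamini–Hochberg column). Spearman uses midranks for ties and an
exact permutation p for n ≤ 9 — full enumeration of the n! rank pairings,
validated against an independent brute-force oracle — and the
t-approximation with n−2 df above. Pearson uses the t-transform with n−2 df.
Symptomatic-only filtering means score > 0. ΔΔCT centres per-sample
`ΔCT = CT_target − CT_reference` on the arithmetic control-group mean (Livak
convention) before `fold = 2^−ΔΔCT`.

## Degenerate inputs and tie-breaks

Zero-variance correlation inputs, empty ROI∩valid intersections, empty
control groups, missing reference CTs (reported with the sample id), empty
per-slice masks (reported with the slice index), non-increasing TR arrays,
mismatched ±MSG geometry, and sub-Nyquist simulation wavelengths (< 4 pixels)
all raise `ValueError` before any computation. Flat T1 recovery curves are
flagged unfit rather than raising. Wrapping is exactly idempotent: in-range
values are returned bit-identically.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at the
native acquisition geometry (128×128 single slice): 10-seed replicates for
noisy recovery and filter-benefit experiments, 200 voxels per T1 value for
noisy T1 recovery, 100 random draws for the exact-p and harmonic-extraction
oracles, and 500 cohort replicates of 15 diseased + 7 control animals for the
direction-of-effect experiment. The full suite completes in well under a
minute on one CPU.

## Known limitations

* 2D inversion of a scalar field: through-plane wave components and the
  compression-wave contribution are ignored (no curl decomposition), as in
  any single-slice Helmholtz pipeline.
* Single-frequency acquisition: no rheological model (springpot, Maxwell) is
  fitted; G* is reported at the drive frequency only.
* The directional filter assumes one dominant propagation direction; fields
  with oblique multi-path illumination would need the four direction variants
  combined.
* The stencil-bias correction assumes axis-aligned propagation; for oblique
  waves it removes only part of the bias.
* Regional summaries depend on the validity mask; in very low-SNR regimes
  the mask, not the inversion, limits accuracy.
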