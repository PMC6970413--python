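# mre-ela

Magnetic resonance elastography (MRE) analysis for sagittal mouse-brain
acquisitions, from raw ±MSG phase-image series to regional viscoelastic
summaries, together with the companion GBCA-MRI and molecular readouts used in
neuroinflammation studies: saturation-recovery T1 mapping (delta-T1, SI%),
2^−ΔΔCT relative gene expression, and score–stiffness correlation analyses.

It is written for experimental neuroimaging groups who acquire single-slice
MRE in rodent models (e.g. experimental autoimmune encephalomyelitis, EAE, the
mouse model of multiple sclerosis) and want a tested, reproducible inversion
chain plus the downstream statistics — and for anyone who needs a synthetic
shear-wave phantom with exactly known viscoelastic ground truth to validate an
inversion pipeline offline.

## The model

An external driver vibrates the skull at frequency *f* (default 900 Hz); the
resulting harmonic shear displacement is encoded into MR signal phase by a
motion-sensitizing gradient (MSG) whose sign is alternated, so that the phase
difference of the two acquisitions cancels static phase and doubles the motion
encoding. After spatial unwrapping, the complex wave image *U(x, y)* at the
drive frequency is extracted by temporal Fourier transformation of the eight
phase offsets, denoised with a radial Butterworth band-pass, and cleaned of
reflections with a directional filter that keeps only the spectral half-plane
of waves propagating bottom-to-top in the sagittal slice.

Assuming local homogeneity, the field obeys the Helmholtz equation
`ρ ω² U + G* ∇²U = 0`, so the complex shear modulus is recovered
algebraically per pixel:

    G* = −ρ ω² U / ∇²U ,      ω = 2π f,  ρ = 1000 kg/m³

From the ROI-averaged complex modulus the package reports the four standard
viscoelastic descriptors: storage modulus `G′ = Re G*` (elasticity), loss
modulus `G″ = Im G*` (viscosity), magnitude `|G*|`, and the loss factor
(phase angle) `φ = arctan(G″/G′)`. The brain mask is split at the
cerebrum/cerebellum junction into anterior and posterior ROIs.

Companion metrics: voxelwise `S(TR) = S0 (1 − e^(−TR/T1))` fits over a
variable-TR series give whole-brain pre/post-contrast T1 means and
`delta-T1 = mean T1(pre) − mean T1(post)`;
`SI% = (SI_post − SI_pre)/SI_pre × 100` summarises T1-weighted signal change;
gene expression is quantified by `2^−ΔΔCT` against an 18s reference and a
control group; score–stiffness associations use Spearman rank correlation
(exact permutation p for n ≤ 9), imaging–imaging and imaging–expression
associations use Pearson correlation.

Because no in-vivo data ships with the package, the `synthetic` module
forward-simulates every input with ground truth attached: damped plane shear
waves `U(ξ) = A e^(−ikξ)` with complex wavenumber `k = ω √(ρ/G*)`, reflected
wave contamination, wrapped ±MSG phase encoding with noise and a static
polynomial background, saturation-recovery series, and cohort tables with a
prescribed negative stiffness–score slope.

## Worked example

```python
from mre_ela import Elastography, simulate_two_region_phantom
from mre_ela.synthetic import WaveSimConfig

cfg = WaveSimConfig(noise_sd=0.05, junction_col=64, seed=7)
pos, neg, truth = simulate_two_region_phantom(4000 + 1200j, 2800 + 900j, cfg)
result = Elastography(pos, neg).fit()
print(result.summary())
```

prints

```
MR elastography reconstruction
==============================
drive frequency : 900.0 Hz
density         : 1000 kg/m^3
valid pixels    : 2887
stages          : temporal_harmonic -> butterworth_bandpass(k_low=0.0,k_high=2000.0,order=3) -> directional_filter(bottom_to_top,taper=400.0)

   region    g_prime g_doubleprime      g_abs     phi  n_pixels
    whole     3388.4         963.6     3522.8  0.2771      2717
 anterior     4065.1        1147.7     4224.0  0.2752      1328
posterior     2888.1         859.7     3013.3  0.2893      1246

moduli in Pa; phi in radians
```

The phantom's true regional magnitudes are |G*| = 4176 Pa (anterior) and
2941 Pa (posterior): with 0.05 rad of phase noise the chain recovers both
within a few percent, and the softer posterior region — the configuration
that mimics cerebellar softening during neuroinflammation — is correctly
ranked below the anterior one. `result.elastogram` holds the per-pixel maps,
`result.plot("g_abs")` displays them.

The same pipeline runs from the shell:

```sh
mre-ela run-all --config config.yaml --out results/
mre-ela simulate | reconstruct | t1map | correlate   # individual stages
```

writing phase series, elastogram maps (NIfTI), ROI summaries, a simulated
cohort table and the correlation report (CSV), each with provenance sidecars
(config hash, seed, stage list).

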