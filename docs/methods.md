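# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `tissuescan`, and what the test suite does and does not
demonstrate.

## Spectral calibration

Raw counts are dark-subtracted and normalised against a diffuse reflectance
standard: `R(λ) = R_nom · (S − D)/(W − D)` with a 20% Spectralon panel as
the normaliser (`R_nom = 0.20`). The lamp spectrum and detector response
cancel in the ratio, so reflectance is instrument-independent. Negative
post-subtraction channels (detector noise below dark) are clipped to zero
and counted in the spectrum metadata; clipping keeps every downstream
nonnegativity constraint valid. The working band is 350–700 nm at 2 nm
pitch — the acquisition band and spectral resolution of the instrument
class — and resampling is plain linear interpolation with no extrapolation
and no smoothing, adequate because tissue spectra are smooth at 2 nm.

## Diffuse reflectance forward model

The probe collects diffusely reflected light over an effective disc of
radius `r_c` centred on the delivery fiber. Starting from the diffusion
dipole (source at depth `z0`, negative image at `z0 + 4AD` above the
extrapolated boundary; `A ≈ 3.25` is the internal-reflection parameter for
a relative index of 1.4 at the tissue–glass interface), integrating the
radially resolved reflectance over the disc gives the closed form

```
R = (μs′/μt′) · ½ [ e^(−μeff z0) + e^(−μeff zb)
                    − z0 e^(−μeff r1)/r1 − zb e^(−μeff r2)/r2 ]
```

with `μt′ = μa + μs′`, `r1 = √(z0² + r_c²)`, `r2 = √(zb² + r_c²)`.
We use the absorption-independent diffusion convention `D = 1/(3 μs′)`,
hence `z0 = 1/μs′`, `zb = z0 + 4AD` and `μeff = √(3 μa μs′)`. With this
convention absorption enters only through the albedo prefactor and `μeff`,
which makes `R` strictly decreasing in `μa` for every `μs′` — the
behaviour a reflectance probe actually shows, and a property the test
suite asserts on a grid. (With `z0 = 1/μt′` the closed form is spuriously
non-monotone at low scattering because adding absorber moves the source
toward the surface.) A unit test checks the closed form against an
independent numerical quadrature of the radial dipole profile to 1e−12.

`r_c` (default 0.5 mm, consistent with a sub-millimetre excitation spot) is
the one free geometry constant. It is not derived ab initio; `calibrate_probe`
sets it by 1-D least squares against phantoms of known optical properties,
mirroring how such instruments are calibrated in practice, and the same
geometry is then reused for every fit of a scan.

## Inverse DRS fit

Bounded nonlinear least squares (scipy `least_squares`, trf) over
`(A, B, C, c_hb, c_bcar)` with bounds `A, C, c_hb, c_bcar ∈ [0, 10]`,
`B ∈ [0, 4]` — a deliberately generous physiological envelope. The loss is
plain least squares on reflectance with uniform weights; the fit band
defaults to 370–700 nm (the 350–370 nm edge carries little lamp output)
while data retain the full band. The residual surface has local minima in
`B`, so the fit restarts from `B ∈ {0.5, 1.5, 3.0}` with the amplitude
seeded by inverting the red-end (≥630 nm) reflectance where absorption is
weakest; the lowest-cost start wins. A start whose residual RMS is already
below 2% of the mean reflectance ends the search early — later starts
cannot materially improve a fit at the noise floor — which keeps pixel-wise
mapping fast without harming noiseless recovery (measured max relative
error over 100 random draws: ~1e−9). Tolerances are 1e−10 (step and cost),
500 function evaluations per start, and the fitter contains no randomness:
identical inputs give bitwise-identical results. Non-convergence and
degenerate inputs return `fit_ok=False` rather than raising, so one bad
pixel never aborts a map.

## Intrinsic fluorescence

Measured fluorescence is modelled as the intrinsic emission multiplied by a
photon-migration distortion. Fluorescence photons traverse roughly half an
excitation path and half an emission path, so the correction uses the
geometric mean of the diffuse attenuation ratios

```
T(λm) = √[ (R(μa_x, μs′_x)/R(0, μs′_x)) · (R(μa(λm), μs′(λm))/R(0, μs′(λm))) ]
```

evaluated from the *fitted* DRS model — at the 355 nm excitation the model
is evaluated by interpolation on the working grid rather than from the raw
350 nm data edge, which carries little signal. The forward simulator and
the extractor share this one function, so `extract(forward(x)) = x` holds
to machine precision by construction and correctness is enforced by
round-trip tests rather than transcription of any particular published
variant. The substantive claim the tests check is absorption invariance:
across phantoms spanning 0.3–3.8 mg/mL blood Hb at fixed furan content,
raw fluorescence per unit fluorophore changes by >100% RMS while the
extracted intrinsic spectra agree to ~1%.

Decomposition of IFS is nonnegative least squares onto named basis shapes
(collagen and NADH for tissue, furan for phantoms). A rank-deficient basis
is flagged but still returns the NNLS solution so maps stay renderable.
For basis discovery, MCR-ALS alternates NNLS on weights and shapes with
unit-area renormalisation of shapes each sweep (a pure rescaling absorbed
by the weights); initial shapes are picked deterministically by greatest
dissimilarity (largest-norm spectrum, then greedy largest-residual). The
objective is non-increasing by construction. Like all bilinear
nonnegative factorisations, MCR is only unique up to rotation unless the
components have selective channels; the recovery test therefore uses
well-separated shapes and pure samples.

## Scan assembly and diagnosis

Cubes are row-major with pixel centres at `origin + (i+0.5)·pitch`.
Assembly infers the grid by rounding positions to lattice indices
(positions more than a quarter pitch off-lattice are errors), rejects
duplicates and masks missing cells. The two probes are mounted a fixed
7.5 mm apart, so the fluorescence cube's stage coordinates are shifted by
exactly `round(offset/pitch)` pixels (an error if the offset is not within
0.1 px of an integer shift — resample instead); registration is pure
integer re-indexing and cropping, never interpolation of spectra.

Pixel-wise processing is DRS fit → IFS extraction → NNLS, producing seven
maps (A, B, C, Hb, β-carotene, collagen, NADH); failures are masked and
counted, and the pipeline is order-independent over pixels. Spectral
slices use nearest-channel selection, matching how single-wavelength maps
are normally quoted. No spatial smoothing is applied to maps.

The tissue mask drops pixels whose broadband DRS intensity is below 5%
(configurable) of the in-scene Spectralon level — the principled handling
of inter-tissue gaps and plate background that otherwise masquerade as
lesions. The diagnostic boundary is logistic maximum likelihood on
standardized (β-carotene, collagen) features with a tiny ridge (1e−6) on a
per-sample mean objective: the problem is convex and deterministic,
duplicating a dataset changes nothing, and perfectly separable training
data yield finite (capped) coefficients with a `separable` flag. The
default boundary is trained at run time on a labelled synthetic scan since
no published coefficients exist; fixed coefficients can be injected via
config. Class cut is the probability-0.5 boundary.

The 10–90% edge response normalises a profile to [0, 1] (making it
invariant to intensity scaling), requires a unique 50% crossing (multi-edge
profiles are rejected with the candidate positions listed), and locates
the 10% and 90% crossings by linear interpolation. For a Gaussian PSF of
width σ the expected distance is 2.563σ, which the tests verify to 2%.

## Synthetic data

The generators are fully deterministic under their seeds and reuse the same
forward models the fitter inverts — round-trip recovery is therefore a
genuine end-to-end test of the inverse pipeline, not a tautology about
shared code paths (noise, averaging, per-droplet geometry and the fit all
intervene).

* **Phantom plates.** Intralipid maps linearly to Mie scattering,
  `A = 1.0 mm⁻¹ per %` at 500 nm with `B = 1.0`, plus a small Rayleigh
  term `C = 0.05 mm⁻¹ per %` representing the sub-wavelength tail of the
  droplet size distribution; the small nonzero `C` keeps all three
  scattering parameters identifiable in stability analyses. Hb (or blood,
  modelled as its Hb content only) sets absorption; furan emission scales
  linearly with concentration (weight 1 per µg/mL). Droplets are 1 cm
  circles on a 12 mm lattice over a dark (2% reflectance) background with
  10% and 20% Spectralon squares in scene. The 15-value dilution series
  defaults to log-spaced Hb in 0.1–4.0 mg/mL — a declared fixture choice,
  since only the ordering of the original series is known.
* **Resolution targets.** A dot lattice is rendered at 10 µm
  supersampling, blurred by a Gaussian PSF and box-averaged to the scan
  pitch; the associated edge profile is the exact Gaussian-smoothed step.
* **Two-tissue scans.** Left half normal, right half cancer, with circular
  cancer foci (defaults: 1 mm and 3 mm) embedded in the normal side. The
  seven parameters are drawn per pixel from class Gaussians whose means
  honour the observed contrast directions — higher A, C, β-carotene, NADH
  in normal tissue; higher B, Hb, collagen in cancer — with effect sizes
  of roughly 1.5–2.5 pooled SD; the distributions are versioned in the
  source. The construction enforces the directions by design; what the
  end-to-end tests verify is that the *fitting pipeline preserves* them
  through noise, forward modelling and inversion, with 99%-level
  significance, 100% detection of 3 mm foci and ≥95% per-pixel
  specificity over 20 seeds. The default scan is 20 × 20 mm at 0.5 mm
  pitch (1600 pixels) — small enough to fit full pixel-wise fits of many
  replicate scans in routine test runs while keeping the 1 mm and 3 mm
  foci at 2 and 6 pixels across.
* **Noise.** Default 1% multiplicative Gaussian plus a small additive
  floor (1e−4) and no wavelength jitter, all seeded.

The chromophore/fluorophore library ships synthetic parametric
(Gaussian-mixture) stand-ins, labelled as such in the data files: the Hb
extinction reproduces oxy-Hb's Soret band (~415 nm), the broad inter-band
absorption through 450–520 nm, the Q bands (542/577 nm) and the
near-transparent red at realistic per-(mg/mL) magnitudes; β-carotene
absorbs in the blue-green; collagen, NADH and furan emission shapes are
unit-area Gaussians peaking at 400, 460 and 422 nm. Measured spectra can
be dropped in via a user library directory. Oxygen saturation is not
modelled — a single effective Hb spectrum matches the one-parameter Hb fit.

## What the synthetic studies do not show

The simulator draws parameters from smooth class distributions and
generates data from the same physical model family the fitter assumes;
real tissue adds model mismatch (layered structure, other absorbers,
probe-contact variation, specular artefacts), spatial correlation, and
class overlap far beyond two Gaussians. Passing tests therefore validate
the numerical correctness and internal consistency of the pipeline and its
statistical machinery, not clinical diagnostic performance. Hardware
concerns (wavelength calibration, stray light, detector linearity, stage
motion) are out of scope.

## Known limitations

* The diffusion closed form is a single-geometry approximation with one
  effective radius; at very low scattering or very high absorption the
  diffusion approximation itself degrades.
* The fluorescence correction is exact only because simulator and
  extractor share it; against a different distortion physics the
  absorption-invariance property, not exactness, is the meaningful check.
* MCR-ALS inherits the rotational ambiguity of nonnegative factorisation.
* Extraction amplifies noise at wavelengths where attenuation is severe
  (deep Soret band at high Hb); coefficients from band-integrating NNLS
  are far more robust there than single-channel IFS values.
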