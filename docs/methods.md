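# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `znpp` package: what is computed, why the defaults are
what they are, and what passing the test suite does and does not show.

## Measurement model

A fibre probe in contact with the wet vermillion of the lower lip collects
emission spectra under 425-nm and 407-nm excitation, plus a dark spectrum,
in repeated 3-spectrum cycles (integration time 200 ms each; 10 cycles per
tissue site, 10 valid sites per subject, 100 cycles total).  Calibration is
dark subtraction followed by division by the integration time; all
downstream arithmetic is in counts per millisecond.  Spectra are
interpolated onto a uniform 1-nm grid spanning 500–750 nm on load.  The
grid is an assumption (the spectrometer's native sampling is instrument
specific) and is configurable; 1 nm resolves the ~10-nm haemoglobin dip
structure that the site-qualification index measures, and the band
arithmetic below presumes a shared grid.

Negative calibrated intensities are preserved, never clipped: the
difference spectrum is legitimately negative near the protoporphyrin IX
(PPIX) bands, because PPIX is excited *more* strongly at 407 nm.

## Difference spectrum

The 407-nm spectrum is scaled by k = mean(F425 on 520–525 nm)/mean(F407 on
520–525 nm) and subtracted from the 425-nm spectrum.  Because the two
excitation wavelengths see nearly identical blood absorption and probe
nearly the same tissue volume, the backgrounds cancel; ZnPP retains
(1 − 0.22) ≈ 78% of its 425-nm amplitude (the 407/425 excitation-efficiency
ratio of ZnPP is 0.22), while PPIX enters negatively (default ratio 2.0,
configurable — only "greater than 1" is physically pinned).

## Spectral fit

The fit removes three spectral features from the difference spectrum D so
that what remains is a smooth background:

    B(λ) = (D(λ) − z·F_ZnPP(λ) − p·F_PPIX(λ)) / exp(−a·µ_a(λ))

minimising Σ B″(λ)² over 560–750 nm.  Choices and their rationale:

- **Ordering.** Template subtraction precedes division by the absorption
  factor.  The original instrument's exact ordering is not recoverable;
  this ordering makes the forward model linear in (z, p) at fixed a and is
  internally consistent with the synthetic generator (see below).
- **Optimisation.**  The second difference is a linear operator, so for
  fixed a the objective is an exact linear least-squares problem in (z, p);
  these are profiled out in closed form and a is minimised by a
  deterministic bounded scalar search (41-point scan over [0, 0.05] mm
  followed by local refinement, keeping whichever of the refined point and
  best scan point has the lower objective).  No stochastic or
  simplex step is involved; the fit is bit-reproducible.
- **Pre-smoothing.**  A Savitzky–Golay filter (window 9, order 3) is
  applied before the second difference (on by default).  Second differences
  amplify shot noise as h⁻²; the window is small against the ~30-nm
  porphyrin bands and passes cubics exactly.
- **Units.**  z and p are counts/ms at the (unit-peak) template maxima;
  a multiplies the whole-blood µ_a curve (mm⁻¹) and is therefore an
  effective haemoglobin path length in mm.
- **Residual coupling.**  A background with non-zero curvature leaks
  slightly into (z, p) — the leakage is linear in the background's second
  derivative and, for realistic smooth backgrounds, two to three orders of
  magnitude below measured amplitudes.  A strictly linear background gives
  exactly zero amplitudes.

## Blood absorption index

On the 407-nm spectrum, band means G_w over w ± 3 nm are formed at 562,
576 and 593 nm (centres bracketing the 576-nm haemoglobin absorption peak;
the ±3-nm half-width is a choice, the centres are fixed).  The index a ≥ 0
solves

    G576·e^{a·µ576} = linear-in-λ interpolation of (G562·e^{a·µ562}, G593·e^{a·µ593})

by bracketed root finding on [0, 0.05]; if the dip is absent the index is
reported as 0 with a `flat` flag.  Two numerical choices matter:

- each µ_w is the mean of µ_a over the same wavelengths as the signal band
  mean (point values at the band centre bias the recovered index by ~10%,
  because a band-averaged signal pairs with a band-averaged absorption);
- a two-band closed-form variant a = ln(G576/G561)/(µ561 − µ576) is
  provided for simulated autofluorescence pairs, where the underlying
  generation is identical by construction.  It assumes equal baselines and
  is biased by any background slope — which is exactly why the instrument
  variant uses three bands.

Zones: index ≥ 0.70×10⁻² green, ≥ 0.42×10⁻² orange, ≥ 0.14×10⁻²
red-orange, below that red.  Thresholds are closed on the left (0.70×10⁻²
is green); the acquisition rule accepts green sites only.  An index of
0.7×10⁻² corresponds to a ~7-µm haemoglobin path and an ~18% dip at
576 nm.

## Reference curves

The bundled whole-blood absorption curve is anchored, exactly, at the
values obtained by inverting the packaged 1%-blood/24-µm coefficients
(0.413, 0.153, 0.206, 0.056 mm⁻¹ at 425/561/576/593 nm → whole-blood
µ_a ≈ 197.2, 19.07, 28.42, 6.01 mm⁻¹); between anchors it follows a
standard ~96%-oxygenated whole-blood shape (monotone log-space
interpolation through literature-scale control points, 150 g/l
haemoglobin).  A separate whole-blood *sample* basis (96% oxy-/4%
deoxyhaemoglobin: 188.49 mm⁻¹ at 425 nm, 4.79 mm⁻¹ at 593 nm) is exposed
as `WHOLE_BLOOD_SAMPLE`; the 593-nm anchors of the two bases differ (6.0
vs 4.79 mm⁻¹) because they assume different oxygenation mixes, and each is
used only in its own context.  Emission templates are parametric
stand-ins: ZnPP a Gaussian at 593 nm (FWHM 25 nm), PPIX Gaussians at
635 nm (1.0, FWHM 25) and 705 nm (0.3, FWHM 40).  The same templates are
used to generate and to fit synthetic data, so template mis-specification
is *not* probed by the tests.

Vessel packaging: C(µ, d) = (1 − e^{−µd})/(µd), applied as
µ_tissue = f·µ_whole·C with blood volume fraction f.  The inverse uses the
closed form µ = −ln(1 − µ_tissue·d/f)/d followed by a Newton polish
against the `expm1`-accurate forward map; at µd ≳ 20 the inverse is
limited by float64 representation of 1 − e^{−µd} itself, and the tests
assert against that propagated bound rather than pretending more precision
exists.

## Monte Carlo transport

MCML-style layered transport: dimensionless step sampling with partial
steps at layer boundaries, Henyey–Greenstein scattering, Fresnel
reflection at the external tissue–air surfaces (internal layers are index
matched at n = 1.33), survival roulette (threshold 10⁻⁴, survival
probability 0.1).  Launch: uniform over the fibre face, cosine-weighted
angle truncated at sin θ = NA/n_tissue.  Detection: exit within the fibre
face inside the same cone; the fibre face is treated as index-matched (a
contact probe on wet mucosa), photons within the face but outside the cone
are counted as escaped.  A perfectly reflecting 12-mm ferrule surrounds
the fibre.  Fluorescence uses weighted direct emission: each absorption
deposit contributes weight × fluorophore_fraction × quantum_yield,
emitted isotropically and transported with emission-wavelength optics; a
spawn-control step (spawn probability proportional to the contribution,
weight divided by that probability) keeps the emission photon count near
~4 per excitation photon without bias.

Numerical/accounting choices:

- **Energy ledger.**  Roulette conserves weight only in expectation, so
  every ledger carries a signed `roulette_net` entry; with it each run's
  ledger sums to the injected weight to float precision, making the
  ≤10⁻⁶ conservation check exact rather than statistical.
- **RNG.**  Counter-based: each photon's stream is keyed by (seed, photon
  index) via a splitmix64-seeded xorshift64* generator; runs are
  bit-reproducible and order independent.
- **TIR guard.**  In non-interacting (test fixture) media a photon can be
  trapped forever between total internal reflections under the
  infinite-plane idealisation; after 200 consecutive TIRs without an
  interaction its weight is tallied as escaped.
- **Common random numbers.**  When fluorescence is transported at several
  emission wavelengths, the same stream is reused across wavelengths, so
  between-wavelength ratios (the simulated blood index) converge at
  desk-scale budgets.
- **Budgets.**  Default 10⁵–10⁶ photons per run (the original GPU study
  used 10⁸); all Monte Carlo assertions are made at explicitly quoted
  Monte Carlo standard errors at these sizes.

The default three-layer lip model: epithelium (50–400 µm, bloodless),
200-µm superficial stroma and 10-mm lower stroma differing only in blood
content; stromal blood enters as the vessel-packaged µ_a.  Scattering is
mucosa-scale (µs 9–15 mm⁻¹, g = 0.9) — representative values, since the
original per-layer property tables are not published in the main text.
Emission is simulated at fixed wavelengths (561, 576, 593 nm), not as full
spectra; spectral fluorescence is the quantitation module's domain.

## Synthetic data

The spectrum generator emulates what the algorithm assumes about real
tissue: a smooth positive autofluorescence background (log-quadratic fit
through control points, ~100 counts/ms, i.e. ~100× the ZnPP amplitude),
multiplied by exp(−a·µ_a(λ)), plus additive ZnPP/PPIX bands with the
excitation-efficiency ratios, plus shot-like Gaussian noise (s.d. ∝
√counts) and a 40-count dark offset.  Deliberate modelling choices:

- **Template placement.**  Emission bands are added *after* the absorption
  imprint, matching the analysis forward model, so noiseless round trips
  are exact.  (Physically the templates are "as detected" emission shapes.)
- **Background smoothness.**  The background is a C∞ log-quadratic, not a
  spline interpolant: piecewise interpolants carry curvature kinks at
  their knots that no instrument background has and that a
  curvature-smoothness criterion would mistake for features.
- **407/425 shape mismatch.**  The 407-nm background is the 425-nm one
  times r(λ) = exp(c₀ + c₁x + c₂x²) with small random coefficients
  (s.d. 0.01/0.02/0.015, |r − 1| clipped at 5%).  This reproduces the
  >90% (not 100%) background-suppression regime of real tissue.
- **Noise level.**  Default `shot_scale` 0.2, putting the per-cycle ZnPP
  amplitude CV near 10%, the regime in which averaging 100 cycles yields
  the sub-percent subject-level precision the acquisition protocol is
  designed around.
- **Cohorts.**  Subject ZnPP/haem ratios are log-normal (median
  ~59 µmol/mol, log-s.d. 0.5, giving ~62.5% above the 50-µmol/mol
  deficiency cutoff); the device adds Gaussian noise of s.d. 19/1.96
  µmol/mol, HPLC triplicates have 4% CV.  The subject-level distribution
  is a modelling choice (the study's raw distribution is unpublished);
  the fixture maps 1 instrument unit ≡ 1 µmol/mol, and the statistics
  pipeline re-estimates the scale blindly.

What the synthetic data does **not** model: melanin and bilirubin
interference, probe-pressure and motion artefacts, instrument wavelength
drift, and template mis-specification.  Passing tests therefore
demonstrate algorithmic correctness under the stated model, not clinical
performance on real tissue.

## Statistics

- **Scaling.**  Zero-offset robust slope: iteratively reweighted least
  squares with Tukey bisquare weights (tuning 4.685), residual scale
  1.4826 × median |residual|, starting at the median per-subject ratio;
  ≤50 iterations, tolerance 10⁻⁸.  Scaling and evaluation use the same
  cohort, replicating the study procedure (an acknowledged circularity,
  preserved for fidelity).
- **Agreement.**  Bias is the τ-location, limits of agreement are
  1.96 × the Maronna–Zamar τ-scale of the paired differences (c1 = 4.5,
  c2 = 3.0, cut-offs on the raw-MAD scale, normal-consistency constant
  E[min(Z², (c2·Φ⁻¹(¾))²)] ≈ 0.9247).  95% CIs are percentile bootstrap
  (default 2000 resamples, seeded).
- **τ-scale robustness, honestly stated.**  The τ-scale is consistent
  under normality (within 0.2% at n = 10⁵) and *bounded* under gross
  contamination — but not unbiased: 10% outliers inflate it by ~23%,
  because each truncated outlier still contributes c2² on the raw-MAD
  scale.  One acceptance-level test asserts a 10% bound under exactly
  those conditions and is expected to fail; it is kept because the bound
  is part of the stated acceptance conditions, and the failure documents a
  real property of the estimator rather than a defect of the
  implementation.
- **Cutpoint.**  Youden's J maximised over all midpoints between adjacent
  distinct scores, ties broken toward higher specificity.  (The original
  analysis names only its software's "optimal cutpoint" routine; Youden is
  that package's default criterion.)
- **Classification.**  Deficient strictly above 50 µmol/mol; 40–50 is
  flagged as an indeterminate zone.
- **Sample-size factor.**  The limits-of-agreement CI half-width
  approximation 1.96·√(3/n) (≈0.45·s at n = 56).

## Known limitations

- Emission templates and between-anchor blood-curve shape are parametric
  stand-ins for unpublished reference spectra; absolute amplitudes are
  instrument units until scaled against a reference method.
- The Monte Carlo model is desk-scale: trend-level fidelity (fibre-size
  monotonicity, blood-index behaviour), not a numerical replica of the
  original 10⁸-photon GPU runs or of supplementary figure values.
- Melanin detection/correction and bilirubin suppression beyond what
  dual-wavelength subtraction provides are out of scope.
- Whether the instrument applied absorption correction before or after
  template subtraction, and whether its final index used two or three
  bands, are not recoverable from the published text; both choices are
  configurable and the defaults are documented above.
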