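# Methods

This note documents the models implemented in `conespot`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Stimulation optics and proportion L

The retinal light field of a stimulus is computed as a unit-integral square
indicator (partial-pixel coverage at the edges) convolved with a
diffraction-limited point-spread function for a circular pupil. The PSF
amplitude is the radial pupil integral

U(θ) = 2 ∫₀¹ exp(i·φ₀ρ²) J₀(πDθρ/λ) ρ dρ,  φ₀ = π·ΔD·a²/λ,

evaluated by 400-node Gauss–Legendre quadrature on a fine radial grid and
interpolated onto the 2-D raster; PSF = |U|², volume-normalized. Defocus is
modeled as the quadratic pupil wavefront W(r) = ΔD·r²/2. Defaults: pupil
6.5 mm, residual defocus 0.05 D applied identically at both wavelengths,
stimulus 2.25 arcmin square at 543 or 680 nm.

Cone apertures are untruncated unit-volume 2-D Gaussians with FWHM
0.59 arcmin (the Gaussian tail beyond 4σ carries negligible mass; the
per-cone integration window extends 4σ). Per cone, the count contribution is
`scale · ∫ field·G_cone`. The light field itself is kept at unit integral,
and the high-level entry points pass `scale = stimulus area`: that way a
cone fully covered by the stimulus counts ~1, the total stimulated-cone
count approximates (local density × stimulus area) ≈ 4–5 cones for the
default geometry, and proportion L — a ratio — is unaffected by the choice.

Unclassified cones are excluded from n_L and n_M; the reported
`prop_L_range` assigns their full aperture mass to L (upper bound) or M
(lower bound). Ties in the nearest-S-cone search are broken by lowest cone
index. Cone spacing is the mean edge length of the Delaunay triangulation
over unique edges; note that on a finite patch the convex-hull boundary
contributes a few longer edges, so the mean for a perfect lattice slightly
exceeds the lattice constant unless the patch is hull-free (e.g. a hexagonal
neighborhood).

Numerics: grid pitch defaults to 0.025 arcmin; halving it changes prop_L by
< 10⁻³ (verified by test). `StimulationKernel` precomputes
(field ∗ aperture) once so that repeated queries reduce to bilinear
interpolation at cone–center displacements; it agrees with the direct
computation to ~10⁻⁴ and with a photon-sampling Monte Carlo oracle to <1%.

## Cone fundamentals

Corneal quantal sensitivity per class:
S(λ) = [1 − 10^(−d·A(λ))] · 10^(−D_lens(λ) − MPOD·T_mac(λ)), with axial
density d = specific density (0.015 OD/µm default) × outer-segment length ×
(1 − bleached fraction). Steady-state bleaching is I/(I + I₀) with
half-bleach constant I₀ = 10^6.4 isomerizations/s; computing I from a
background spectrum is out of scope — callers supply a rate or fraction.

The pigment absorbance template A(λ) is the closed-form Govardovskii A1
nomogram, parameterized directly by λmax (α- and β-bands, peak-normalized).
Lens density is a parametric age-scaled template (OD 1.7 at 400 nm for a
32-year standard eye, exponential decay with 45-nm scale, linear 2%/year
age scaling) and the macular template is a two-Gaussian shape peaking at
460 nm; both are deliberately simple smooth approximations and both are
configurable with user-supplied spectra. Their precision is immaterial to
the detection model because both filters are essentially zero at 543 and
680 nm, where only sensitivity *ratios* enter.

Peak macular density at an eccentric locus inverts the field-size-averaged
density function D(·) over the annulus spanned by the stimulus:
MPOD = −log₁₀[(10^(−D(2e₂))e₂² − 10^(−D(2e₁))e₁²)/(e₂² − e₁²)], with
e₂ − e₁ equal to the stimulus diameter centered on the tested eccentricity,
assuming radial symmetry.

Primaries are treated as monochromatic by default; Gaussian-bandwidth
integration (FWHM ~13.5/14.9 nm) is available via `primary_fwhm` and shifts
excitations by a few percent. The normalization convention of the
fundamentals cancels in the sensitivity-ratio model, so no convention is
imposed.

## Additive detection model

Predicted S680/S543 at a site is a rational function of p_L (see README).
RMSE between predictions and observations is computed on the linear ratio
scale by default (`scale="log10"` available); the λmax sweep default grid is
550–570 nm at 0.1 nm with the three common L-pigment variants (555.5,
558.9, 563.4 nm) exposed as `PLAUSIBLE_L_LAMBDA_MAX`. The unequal-weight
variant multiplies M-cone excitations by w (default 1.5) and reports the
percent RMSE change per candidate λmax. Observed ratios carry point p_L
from classified cones, with the unclassified-range kept as metadata.

## Threshold pipeline

Trials are kept only if the worst-frame |dx| and |dy| delivery errors are
both ≤ 0.75 arcmin (inclusive); missing offsets reject the trial but count
in the denominator. The psychometric model is
P(seen|I) = γ + (1−γ−λ)(1 − exp(−(I/scale)^β)), fitted by maximum
likelihood on log₁₀ intensity (Nelder–Mead with multiple starts); the
reported threshold α is the intensity at 50% seen. Defaults γ = 0 (yes/no
detection on a blank-capable background) and λ = 0.01, both configurable.
The two (or more) interleaved staircases of a condition are pooled into one
fit, and random-probe trials are included — they are valid psychometric
data. Degenerate conditions (all seen, none seen, single intensity) are
signaled, not silently estimated. Spearman correlations use permutation
p-values (10⁴ seeded shuffles) because per-subject site counts are small.

## Color-naming analysis

Expected-response labeling, threshold-multiple intensities, heterogeneity
H = 1 − |p_L − 0.5|/0.5, and S-cone distance in cone-spacing units feed the
random-intercept logistic model. Heterogeneity uses the delivery-realized
per-trial p_L when available, otherwise the site value. Non-expected
chromatic reports (rare by construction) are excluded from the modeled
table and available for audit. S-cone distance enters raw (unstandardized).

The GLMM is fitted by Laplace maximum likelihood: an inner penalized
Newton solve for (β, u) and an outer Nelder–Mead over the log random-effect
SDs (floored at 10⁻⁴, so zero-variance data land on the boundary
gracefully). Wald covariance for β is the β-block of the inverse joint
Hessian, which propagates random-intercept uncertainty into the intercept's
CI. The implementation matches `lme4::glmer` (nAGQ = 1) on fixed effects,
log-likelihood, variances, and standard errors (oracle test). Model
comparisons: mixed vs fixed-only logistic (Δdf = 2) and full vs
no-heterogeneity (Δdf = 1), each reporting the LR statistic, ΔAIC, and a χ²
p-value — the boundary-null caveat for variance components applies to the
first comparison and is documented rather than corrected. The pseudo-R² is
an adjusted McFadden statistic, 1 − (ll − k)/ll₀.

With only two levels per grouping factor the variance components are
fragile; the package reports them and flags boundary fits instead of taking
a position on the random-vs-fixed debate. The fixed-effects check (slopes
within 1% of a plain logistic fit when generative variances are zero) is a
test-suite invariant.

## Synthetic-data generator

What it emulates: triangular-lattice mosaics with positional jitter
(default SD = 0.1 × spacing, spacing 1.1 arcmin ≈ 2° eccentricity, giving
~4–5 cones per stimulus); i.i.d. cone-type assignment with configurable
L/(L+M) (defaults 1.47/2.47 and 3.66/4.66 for the two emulated subjects),
5% S cones, 2% unclassified; thresholds following the additive model with a
site-level log₁₀-noise component shared between wavelengths (SD 0.08,
cancels in ratios) plus independent per-wavelength noise (SD 0.05, sets the
ratio scatter); interleaved QUEST-like staircases (grid posterior over
log₁₀ threshold, next trial at the posterior mean, starts at 25%/75% of the
maximum intensity, 25 trials each, 20% uniform-intensity probes); Gaussian
per-frame delivery jitter (SD 0.08 arcmin, i.i.d. across the three frames —
the frame-to-frame correlation structure of real tracking errors is
unknown, so independence is assumed); and a color-naming generator sharing
the GLMM's logistic form with generative coefficients
(−2.5, ln 2.94, ln 5.51, 0) and a fixed 0.5% non-expected-response rate.
"100 trials per condition" study totals correspond to four 25-trial
staircases (two repeats of the paired-staircase block).

The maximum intensity is set to 50× the predicted balanced-site threshold,
so thresholds are a small fraction of the ceiling and probes are
effectively suprathreshold, as in the emulated sessions.

What it does not emulate: spatial clumping of cone types (assignment is
i.i.d.; real primate mosaics are patchier, so real local p_L distributions
are wider than the generator's), eye-movement traces and microsaccades
(delivery errors are light-tailed Gaussians, so simulated inclusion rates
are near 1 rather than ~85%), rod/melanopsin intrusion, classification
errors, and criterion drift. Passing tests therefore demonstrate the
correctness and statistical power of the *pipeline* under the stated
generative model, not the biological variability of real observers.

Random intercepts in recovery simulations are recentered to sum to zero per
factor: with two-level factors the realized intercept mean is otherwise
confounded with β₀, and recentering keeps the fixed intercept identified in
every simulated dataset.

Seeding: one master seed per session; each trial draws from a child stream
keyed by (session seed, site, wavelength, staircase, trial), so results are
reproducible under re-ordering.

## Monte Carlo site sampling

Random stimulus centers are drawn uniformly over the mosaic interior minus
a margin of half the stimulus footprint plus 2 arcmin of PSF tail; sites
with no classified L/M aperture mass are redrawn (impossible at realistic
densities). Histograms use eight equal-width p_L bins over [0, 1]; 10,000
iterations by default. Because sites are i.i.d. within and across
iterations, predicate counts are binomial — the test suite exploits this as
a closed-form oracle for `tail_probability`.

## Problem sizes used in the test suite

Recovery and power studies run at the emulated study scale: 32 and 26 sites
per observer, 100 trials per condition, ~5,500 seen trials for GLMM
recovery (100 replicates), 100 replicates for λmax recovery and
rank-correlation power, 200 replicate Weibull fits, 20 configurations ×
10⁵ photons for the optics oracle, and 3,000-iteration Monte Carlo runs for
the sampler checks.

## Known limitations

- The lens/macular templates are smooth stand-ins, not individually
  calibrated filter spectra; replace them with measured spectra for any
  quantitative use below ~500 nm.
- The QUEST-like staircase fixes slope, guess, and lapse; it is an
  intensity-placement engine, not a full multi-parameter Bayesian
  procedure.
- The GLMM's two-level grouping factors make variance components barely
  identified; interpret them qualitatively.
- Isomerization-rate computation from a background spectrum (for the
  bleaching correction) is intentionally out of scope.
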