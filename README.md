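# conespot

Cone-resolved small-spot psychophysics: simulation and analysis of how the
detection and color naming of tiny monochromatic flashes depend on the local
L/M cone topography of the retina.

## The problem

Adaptive-optics ophthalmoscopes can deliver aberration-corrected, retinally
stabilized stimuli a few arcmin across to patches of retina where the
spectral type (L, M, or S) of every cone is known. At that scale a flash is
sampled by only ~4–5 cones, so perception should depend on exactly *which*
cones are hit. Two questions follow:

1. **Detection.** Does sensitivity to long-wavelength (680 nm) light,
   normalized by sensitivity to mid-wavelength (543 nm) light, grow with the
   local proportion of L cones — and is the relationship explained by a
   mechanism that simply sums L and M excitations?
2. **Appearance.** Are flashes more likely to look chromatic (red/green
   rather than achromatic) when they land on a spectrally balanced patch of
   mosaic, and does proximity to S cones matter?

`conespot` implements the full analysis chain for both questions, plus a
synthetic-data generator that stands in for human observers, so every stage
is testable end to end.

## The models

**Proportion L.** The retinal light distribution of a square stimulus is its
shape convolved with a diffraction-limited PSF (6.5-mm pupil, residual
defocus as a quadratic pupil phase). Each cone aperture is a unit-volume 2-D
Gaussian (FWHM 0.59 arcmin). The aperture-weighted count of stimulated cones
of class c is Σ_c ∫ field·G_c, and

&nbsp;&nbsp;&nbsp;&nbsp;p_L = n_L / (n_L + n_M)

with a min/max range when unclassified cones sit under the stimulus.

**Additive detection model.** With subject-specific quantal cone
fundamentals (lens and macular pre-filtering, λmax-positioned pigment
template, self-screening with bleaching-corrected axial density), the
predicted sensitivity ratio at a site is

&nbsp;&nbsp;&nbsp;&nbsp;S680/S543 = (p_L·L680 + w(1−p_L)·M680) / (p_L·L543 + w(1−p_L)·M543)

where Lλ, Mλ are excitations per corneal quantum and w is an optional M-cone
weight (default 1). Sweeping the L-pigment λmax and comparing RMSE against
observed ratios selects the best-fitting pigment variant.

**Color naming.** Each seen trial is labeled by whether the report matched
the large-field hue of the wavelength ("red" at 680 nm, "green" at 543 nm).
With heterogeneity H = 1 − |p_L − 0.5|/0.5,

&nbsp;&nbsp;&nbsp;&nbsp;logit π = β₀ + β₁·log₂(intensity/threshold) + β₂·H + β₃·(S-cone distance) + b_subject + b_wavelength

is fitted by Laplace maximum likelihood (random-intercept logistic GLMM,
implemented in `conespot.glmm` and cross-checked against `lme4::glmer`).

## Worked example

Simulate an observer, fit thresholds, and test the topography–sensitivity
link:

```python
import numpy as np
from conespot import synthetic_data as sd
from conespot import threshold_pipeline as tp

mosaic = sd.generate_mosaic(sd.MosaicSpec(seed=1))          # 6400 cones, L/(L+M) ~ 0.60
observer = sd.ObserverSpec()
trials, sites = sd.simulate_session(mosaic, observer, sd.SessionSpec(n_locations=10, seed=2))

included, rate = tp.inclusion_filter(trials)                 # delivery-quality filter
estimates = tp.fit_thresholds(included)                      # Weibull, 50% seen
ratios = tp.sensitivity_ratio(estimates, sites.rename(columns={"prop_L_680": "prop_L"}))
rho, p = tp.rank_correlation(ratios["prop_L"], ratios["ratio"], seed=0)
print(f"Spearman rho = {rho:.2f}, permutation p = {p:.4f}")
```

Output:

```
Spearman rho = 0.72, permutation p = 0.0251
```

i.e. at 10 sites the 680/543 sensitivity ratio already rises significantly
with the local L-cone proportion. Fitting the color-naming model to a
two-observer simulation (~3900 seen trials, generative odds ratio 2.94 per
intensity doubling and a null S-cone effect) returns:

```
                  coef     se      p   odds  odds_lo  odds_hi
intercept       -2.293  0.441  0.000  0.101    0.043    0.239
log2_intensity   1.082  0.035  0.000  2.951    2.754    3.162
heterogeneity    1.540  0.174  0.000  4.664    3.319    6.556
s_cone_distance -0.069  0.058  0.239  0.934    0.833    1.047
```

— the intensity odds factor is recovered (2.95 vs 2.94), spectral balance
multiplies the odds of a chromatic report about 4.7-fold, and S-cone
proximity is correctly flagged as a null effect.

A CLI wraps the same steps:

```bash
conespot simulate --config sim.yaml --out run/
conespot thresholds --trials run/trials.csv --out run/estimates.csv
conespot fit-additive --sites run/ratios.csv --sweep 550:570:0.1 --out run/fit.json
conespot site-mc --mosaic run/mosaic.csv --n-sites 32 --out run/mc.json
```

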