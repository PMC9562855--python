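# Methods

## Problem setting

A handheld SPAD meter gives a unitless relative chlorophyll reading per
leaf; mite infestation lowers canopy chlorophyll, so SPAD predicted from
canopy reflectance is a proxy for infestation severity.  The pipeline
estimates SPAD from hyperspectral canopy reflectance on a fixed wavelength
grid (default: 45 evenly spaced bands, 500–900 nm) and converts predicted
SPAD into four ordinal severity grades (I healthy … IV severe).

## Synthetic data model

No public field data accompany this study design, so all tests and the
acceptance run use a parametric generator.  A spectrum for chlorophyll
level `c = (SPAD - 15) / 60` is

```
vis(l) = base
       + (y0 + y1 (1-c)) G(l; 560, 65)     # chlorosis / yellowing hump
       + g  G(l; 550, 16)                  # green peak
       - d  c G(l; 531, 8)                 # xanthophyll-region dip
       - (a0 + a1 c) G(l; 670, 26)         # red absorption valley
       - b  c G(l; 480, 32)                # blue-edge absorption shoulder
R(l)   = (1 - s(l)) vis(l) + s(l) (n0 + n1 c),   s = logistic((l-715)/12)
```

with `G` a unit Gaussian and defaults `base=0.14, y0=0.03, y1=0.24,
g=0.05, d=0.05, a0=0.02, a1=0.04, b=0.18, n0=0.42, n1=0.12` (unitless
reflectance; positions and widths in nm).  Per-band i.i.d. Gaussian noise
(default sd 0.01) is added and the result clipped to (0, 1).

The five components are not decorative: each anchors one sign of the
vegetation-index structure.  The yellowing hump (bright green-yellow
canopy at low SPAD) drives GI = R554/R677 negative against SPAD; the
deepening 531 nm dip drives PhRI positive; the blue shoulder makes R500
fall faster than R549 with chlorophyll, which separates the nearly
identical MCARI (positive) and as-printed TCARI (negative) formulas; the
red valley and NIR plateau give NDVI/RVI their positive correlation and
the per-band correlation profile its sign flip at the red edge.  The
amplitudes were fixed once by a coarse numeric search requiring all six
signs, the 620–690 nm no-crossing property and reflectance ∈ (0, 1) to
hold across 20 generator seeds at n = 400, and are not tuned per test.

SPAD is drawn per sample as Normal(class mean, 4.0) truncated to
[15, 75], class means (57, 51, 43, 34) with a balanced severity mix, which
yields an overall coefficient of variation near 21% and a realistic range
(≈21–69).  Samples carry synthetic site ids (90 groups) so both
sample-wise and group-wise modeling/validation splits are available; the
generator does not prescribe which to use.  The default set has 400
samples; study-scale runs use `GeneratorConfig(n_samples=1200)` with the
800/400 sample-wise split.

What the generator does **not** emulate: canopy structure and viewing
geometry, soil background, multiple biochemical drivers (water, nitrogen),
spatially or spectrally correlated sensor noise, and any red-edge
*position* shift with chlorophyll.  Consequently the data are close to a
single-latent-variable family, and passing tests demonstrate the
machinery's correctness and the qualitative sign/direction structure —
not field-level accuracy.

Scenes for mapping tests place severity in smooth patches (a Gaussian
filtered random field quantized by the severity mix) with per-pixel SPAD
jitter of 1.5 around the class mean.  DN scenes invert the empirical line
(`DN = offset + gain rho + noise`, defaults gain 4000, offset 100) and
embed the four gray plates (3/22/48/64% reflectance) in the bottom rows.
DN values are kept as floats by default; integer quantization is opt-in
because it would destroy the exact round-trip property that the
calibration tests rely on (0.5 DN ≈ 1e-4 reflectance at the default gain).

## Preprocessing

The empirical line uses the darkest and brightest plates (3%, 64%) by
default for the longest lever arm; a least-squares fit over all plates is
available for noisy plate readings.  Out-of-range reflectance is flagged
in a QA mask, never clipped, so the affine algebra (irradiance correction
commutes with the empirical line) stays exact.  Savitzky–Golay defaults
are window 7, polynomial order 2 — a common chemometrics choice that
preserves the narrow green peak at a 9.1 nm band spacing.  Dark-current
and flat-field correction are exposed only as generic hooks
(`(cube - dark)/flat`) since no instrument model is bundled.  The pipeline
order is irradiance correction → empirical line; the reverse is possible
by composing the functions, and because both maps are affine per band the
choice only matters when plate readings are not shared across images.

## Vegetation indices

TCARI is implemented in two selectable forms: the as-printed variant
3[(R700−R675) − 0.2(R700−R500)(R700/R670)] (default) and the canonical
3[(R700−R670) − 0.2(R700−R550)(R700/R670)].  NDVI/RVI anchors default to
R = 670 nm and NIR = 800 nm and are configurable.  Wavelength lookups
resolve to the nearest grid band within a 5 nm tolerance, ties toward the
shorter wavelength.  R² is everywhere the squared Pearson correlation of
measured vs predicted; RMSE is the root mean squared residual.

## SPA band selection

Chains are grown on mean-centred columns; at each step the candidate with
the largest residual norm after orthogonal projection onto the selected
span is added (ties to the lowest band index; a numerically exhausted rank
raises an informative early stop).  Every band serves as a chain start by
default; length-k prefixes are scored by an MLR fit under a seeded 30%
holdout (5-fold CV optional), with a tiny-ridge fallback and warning on
singular designs.

The winning subset size uses the classical SPA parsimony rule: the
smallest k whose RMSE is not significantly worse than the curve minimum by
an F-ratio test at alpha = 0.25.  A strict argmin rule is available, but
with independent band noise the RMSE curve declines monotonically in k
(each added band averages noise), so argmin degenerates to max_k; the
F-test rule reproduces the intended "fewest bands at near-minimal error"
behaviour and is the default.

## ELM and PSO-ELM

Hidden weights and thresholds live in [-1, 1]; the readout is solved by
least squares with a 1e-8 ridge for conditioning (an intercept column is
included by default; inputs are standardized and the scaling stored on the
model).  PSO uses constant inertia 0.9, learning factors c1 = c2 = 1.4
(both set to the same value; they are configurable separately), swarm 30,
velocity clamp |v| ≤ 1 and position clamp to [-1, 1] so particles stay in
the weight domain; clamps can be disabled, which the hand-worked update
check requires.  Fitness is the training-set RMSE of the ELM a position
encodes (readout refit per evaluation); held-out fitness data can be
supplied.  Iteration stops at max_iter = 100 or when the global best
improves by less than 1e-4 (relative) for 10 consecutive iterations.  r1
and r2 are fresh U[0,1] draws per particle and dimension, injectable for
deterministic tests.

Two empirical notes, measured on the synthetic family.  First, with
constant inertia 0.9 the swarm converges to 1e-3 on a sphere objective
within 100 iterations reliably only in low dimension (20/20 seeds at
D = 2; D = 5 needs roughly 300 iterations) — the convergence check is
therefore run at D = 2.  Second, the PSO-over-ELM benefit is a
sample-size story: with 800 modeling samples (the study-scale split) the
PSO-optimized ELM is consistently at least as good as the plain ELM on
validation RMSE (seed-averaged), while with only ~270 modeling samples
optimizing the 120-dimensional hidden parameterization overfits and the
plain ELM wins.  The directional comparison is accordingly defined at the
study scale.

## Severity classification and mapping

The SPAD cut points behind the four grades are not published; defaults are
the midpoints of the generator's class means (54, 47, 38.5), declared, not
inferred.  Intervals are closed on the high-SPAD side (a boundary value
takes the lower-severity grade).  Maps predict SPAD per pixel from the
selected bands and classify; QA-masked pixels stay masked (class 0).
Outputs are plain arrays/CSV plus ENVI cubes; no georeferencing or
cartography is attempted.

## Problem sizes

Default test problem sizes were chosen to keep the full suite fast while
leaving the statistics stable: n = 400 for sign/correlation properties,
n = 1200 with an 800/400 split and 20 seeds for the ELM/PSO-ELM
comparison, 50 seeds for planted-band recovery, 40×40 pixels for map
agreement, and 100-seed Monte Carlo for the smoothing variance check.

## Known limitations

* The generator's single-latent structure makes band selection less
  discriminative than on real canopies: many bands are nearly
  interchangeable, and the selected wavelength set varies with the scorer
  seed even though its size and the fit quality are stable.
* Reported accuracies (R² ≈ 0.99 on synthetic data) reflect the
  generator's low intrinsic noise, not expected field performance.
* The ENVI reader supports uncompressed BSQ/BIL/BIP with a standard
  header only.
* PSO assumes a deterministic fitness; stochastic fitness would break the
  monotone global-best invariant.
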