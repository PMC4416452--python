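# Methods

This note records the models, conventions and design choices behind
`isoleaf`, in the order the inference chain runs.

## Spectral data model

Spectra live on the 1-nm integer export grid of a field spectroradiometer
(350–2500 nm, 2151 bands). Ingestion accepts only this grid; resampling
from the instrument's native 1.4/2-nm sampling is out of scope because the
instrument's own export already interpolates. Reflectance values above 1
(specular glare) are admitted with a warning rather than clipped — clipping
would bias the SNV statistics. All wavelength ranges in the package are
inclusive on both ends.

Every spectrum carries a processing-state tag
(`raw → jump_corrected → snv → first_derivative`) and each preprocessing
operator checks the incoming state, so the chain cannot run out of order or
twice.

## Preprocessing

**Splice (jump) correction.** The three detectors meet at 1000|1001 nm
(VNIR|SWIR1) and 1800|1801 nm (SWIR1|SWIR2). The correction is a per-sample
single-ratio multiplicative rescaling: the VNIR segment is multiplied by
r(1001)/r(1000) and the SWIR2 segment by r(1800)/r(1801), leaving SWIR1
(the most stable detector) bit-identical and the spectrum continuous at
both splices. Published interpolation-based variants need parameters that
are not reproducible from their description; the single-ratio convention is
exact, invertible and testable. Zero reflectance at a splice band is an
error; factors outside [0.5, 2] trigger a suspect-spectrum warning.

**SNV.** Per-spectrum standardization to mean 0 and *sample* SD 1
(divisor n − 1; consistent with the chemometric convention and with the
identity snv([0, 1, 2]) = [−1, 0, 1]). SNV is computed over the full
measured axis before any range restriction, matching the operator order of
the chain. Constant spectra are an error.

**Savitzky–Golay first derivative.** Window 2·4 + 1 = 9 points, local
polynomial order 2, derivative scaled per nm (divided by the grid step) so
values are grid-independent. The four bands at each edge, where no full
window exists, are dropped rather than filled by polynomial extrapolation —
extrapolated values would be fabricated data entering the regression. On
any polynomial of degree ≤ 2 the interior output equals the analytic
derivative to machine precision; this is asserted in the tests.

**Model range.** 400–1800 nm inclusive (1401 bands on the full grid before
derivative edge loss). The SWIR2 (1801–2500 nm) is dropped because its
noise level under a halogen source makes it useless for calibration; the
ultraviolet-adjacent 350–399 nm region is similarly excluded.

## PLS1 core

X and y are autoscaled (mean-centered, scaled by 1/SD with divisor n − 1);
the scaling parameters are model state, estimated on the fitting partition
only and applied to any new data — the precondition for honest
cross-validation. For a single response the NIPALS weight vector has the
closed form w = Xᵀy/‖Xᵀy‖ per deflation step, algebraically identical to
the converged iterative NIPALS inner loop; factors are extracted by
deflating X (and y) after each step. Factors whose score energy falls below
10⁻¹² of the initial X sum of squares are truncated with a warning.

The rotation R = W(PᵀW)⁻¹ (built by the standard recursion; PᵀW is unit
upper triangular) gives the coefficient path for every truncated factor
count in one pass, which the cross-validation exploits. Coefficients are
back-transformed to raw units for reporting and for the jackknife test, so
submodels with different fold scalings are comparable.

**Explained variance** per factor is SSₐ = qₐ²·tₐᵀtₐ on the scaled metric,
reported as a percentage of the scaled response sum of squares.

**VIP.** VIPⱼ = √(p · Σₐ SSₐ wₐⱼ² / Σₐ SSₐ) with unit-norm weight columns.
The mean of squared VIPs is exactly 1 by construction; this identity is an
acceptance target. The exact normalization used by commercial chemometrics
suites is not verifiable; the definition above is the published one this
package fixes.

## Validation

**Cross-validation.** 10-fold with random, near-equal segments (sizes
differ by at most 1), reproducible under a seed. Every fold re-estimates
autoscaling on its training remainder; a held-out sample's response value
can therefore never influence its own prediction (a mutation test asserts
this). The factor count A\* is the first local minimum of RMSE_cv(A); a
monotone curve returns the largest count tried, with a warning.

**Model statistics.** Slope/offset from regressing predicted on measured;
R²_cal = 1 − SSres/SStot; R²_cv = 1 − PRESS/SStot (the squared-correlation
variant is carried alongside since published tables rarely disambiguate);
RMSE_cv also expressed as a percentage of the measured range.

**Influential-outlier screen.** A sample is flagged when its leverage in
factor-score space exceeds 3(A+1)/n *and* its studentized calibration
residual exceeds 2.5 in magnitude, with at most 5 % of samples flagged per
pass (ranked by residual). These thresholds quantify the qualitative rule
"strongly influences the model but is not well described by it"; all three
are configurable. Removal is logged, never silent.

## Wavelength selection

**Martens' uncertainty test.** With one coefficient vector per CV submodel,
the jackknife variance of coefficient j is s²ⱼ = (k−1)/k·Σₘ(bⱼ⁽ᵐ⁾ − bⱼ)²
and tⱼ = |bⱼ|/sⱼ is referred to a t distribution with k − 1 df (two-sided,
α = 0.05). Degenerate cases: zero spread with zero coefficient → not
significant; zero spread with nonzero coefficient → significant. Measured
on pure noise (60 × 100, 50 replicates) the false-positive rate is ≈ 0.046,
i.e. the test holds its nominal level.

**Iterated elimination.** Loop: cross-validate → pick A\* → fit the
full-data model → test coefficients → drop non-significant wavelengths →
re-validate. The reduced model is accepted iff its RMSE_cv is no worse than
the current one within a 10⁻³ relative tolerance (the reduced model always
has fewer variables, so ties go to parsimony); otherwise the pass is
rejected and the loop stops. CV segments are re-randomized each pass from a
deterministic seed sequence, so whole traces reproduce exactly. Hard cap:
10 passes (observed: 1–4). Selection is an index mask; input spectra are
never mutated.

**Selection-aware reporting (cross-model validation).** Re-validating a
wavelength subset that was chosen using all samples understates the error:
on data with *no* isotope signal the naive post-selection CV reports
R²_cv ≈ 0.3 — pure selection bias, since ~5 % of 1401 noise wavelengths
pass any α = 0.05 test by chance and re-validating those chance picks on
the same samples flatters them. The pipeline therefore reports CV
statistics from an outer 10-fold CV in which the *entire* elimination is
re-run inside each training fold before the fold's held-out samples are
predicted. Under this honest estimate the no-signal control yields
R²_cv ≤ 0 while realistic signal strengths still yield R²_cv ≈ 0.6–0.8.
`RunConfig(cv_strategy="naive")` restores the naive estimate for
comparison. The structural report fields (factor count, retained
wavelengths, iteration count, VIP table) always come from the full-data
elimination.

## The simulator

The generator's goal is controllability with the statistical structure of
the two study designs — not radiative-transfer realism (no PROSPECT).

**Spectra.** A stylized baseline (visible floor, red-edge sigmoid, NIR
plateau scaled mildly by SLA, smooth SWIR decay) is multiplied by Gaussian
absorption features: five chlorophyll bands (430–678 nm) whose depth grows
with N content, nine N-bond features (910–1770 nm, literature-anchored
centers) with a weaker N response, and five water bands (970–1930 nm)
driven by gravimetric water content. Per-sample detector-splice distortions
(log-normal, σ = 0.02) and heteroscedastic Gaussian noise (SWIR2 eight-fold
elevated, emulating a weak halogen source) are applied last.

**The isotope effect** acts on feature *width*: each iso-sensitive feature's
σ changes by 0.5 % per ‰ δ¹⁵N (a depth-mode switch exists). Width rather
than depth follows the hypothesis that ¹⁵N substitution alters the shape of
absorption bands of N-containing bonds rather than their area. Every
species expresses the effect at all 14 chlorophyll + N-bond features, but
with a species-specific *sign pattern* per band (pairwise pattern
correlations near zero to mildly negative). The physical picture: species
partition newly assimilated labeled N into different compound pools
(photosynthetic protein vs. chlorophyll), shifting band shapes in
species-specific directions. Two consequences match the target phenomena:
the same spectral regions are important in every species, yet a pooled
across-species model largely cancels the signal and fails within species
while species-specific models succeed.

**Greenhouse design.** 16 + 12 + 11 plants of three species; treatments
0/10/20 ‰ allocated near-evenly at random (the smallest species gets 0/20
only); per plant 3 young + 3 mature + 3 drought-stressed leaves (351
samples). δ¹⁵N = species baseline + treatment × leaf-type uptake
(0.80/0.75/0.50 for young/stressed/mature; 0 for mature leaves of the
sclerophyllous species — the labeling failure that forces their exclusion)
+ leaf noise (SD 0.7 ‰), spanning ~19 ‰ within species. N%, GWC and SLA
are drawn independently of treatment, so within-species rank correlations
with δ¹⁵N stay below |r| ≈ 0.1 — verified by `check_covariate_independence`,
the generator's acceptance gate. Drought multiplies GWC by 0.7. A
per-species `noise_scale` (1.3/1.8/1.0) reflects measurement repeatability
differences between leaf surfaces (pubescence, cuticle, leaf size vs. probe
optics) and spreads model quality across the realistic range.

**Field design.** 40 samples along 0–30 m of distance to an N₂-fixer
canopy; δ¹⁵N is a two-endmember mix of the −12 ‰ background and the 0 ‰
fixed-N signal with mixing fraction 0.8·exp(−d/8 m) plus 0.4 ‰ noise
(range −12 … −2.4 ‰). N% follows the same mixing fraction with independent
noise sized for a target correlation of ~0.78, then is mapped affinely onto
0.47–0.96 % (exact printed bounds; affine maps preserve the Pearson
correlation). Field-model skill therefore flows largely through the δ–N
covariation — deliberately, since that is the interpretive ambiguity the
labeling design exists to resolve.

**Isotope bookkeeping.** `delta_after_label_addition` converts δ to ¹⁵N
atom fraction via the AIR ratio (0.0036765, the standard value), sums heavy
and total N over pool and additions, and converts back — exact mixing, no
linearization. The worked example uses a pool of 14.8 mmol N per litre of
nutrient solution (an assumption; the solution's N concentration is not
printed anywhere), under which the published per-10-‰ recipe (0.274 µmol
98 % KNO₃ + 0.145 µmol 95 % (NH₄)₂SO₄, two N per formula unit) yields
+10.03 ‰.

**Calibration of defaults.** Effect sizes and noise levels were calibrated
once so the chain's recovery behavior sits inside the realistic regime —
species-specific R²_cv roughly 0.6–0.8 with RMSE_cv at 13–26 % of the
response range, no-signal controls at R²_cv ≤ 0 — and then frozen. They are
study conditions, not tuning knobs.

**What passing tests do and do not show.** The simulator's features are
additive-in-log Gaussians with linear trait responses and uncorrelated
band noise; real leaf spectra have correlated noise, continuum-level
structure, specular and geometry effects, and nonlinear trait couplings.
Passing recovery tests therefore demonstrates that the *chain* is correct
and honest (no leakage, no selection self-deception, correct formulas),
not that real-leaf δ¹⁵N retrieval at these accuracies is guaranteed.

## Numerical conventions and degenerate inputs

- SD divisor n − 1 everywhere (SNV, autoscaling, statistics).
- Zero-variance X columns get zero weight and coefficient, with a warning.
- Rank exhaustion truncates the factor sequence with a warning.
- Jackknife zero-spread cases resolved by the coefficient's own value.
- All randomness flows through explicit seeds; per-iteration and per-fold
  seeds derive deterministically from the master seed, so every trace and
  report reproduces bit-for-bit.
- Problem sizes in the test and acceptance suites (e.g. one species of
  ~100 samples, 10 seeds for medians, 50 replicates for error rates) were
  chosen as the smallest sets that make the distributional assertions
  stable.

## Known limitations

- The elimination loop evaluates candidate models with re-randomized CV
  segments; with a fixed-segment variant, acceptance decisions can differ
  near ties (the sensitivity is documented by the reproducibility tests,
  which pin the re-randomized behavior).
- The outlier screen runs once, before elimination; a per-iteration screen
  is configurable but not default.
- The pooled model's split is stratified by species to prevent degenerate
  draws at small n; a fully unstratified split can drop a species from the
  training set.
- `predict` does not extrapolate gracefully far outside the calibration
  trait space (no applicability-domain check).
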