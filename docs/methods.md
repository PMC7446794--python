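# Methods

This note records the models, parameter choices and numerical conventions
behind `ramscreen`, and what validation on synthetic cohorts does and does
not establish.

## Spectral preprocessing

A raw scan is a vector of intensities on a strictly increasing wavenumber
grid (cm⁻¹). The processing chain applies, in order:

1. **Truncation** to the fingerprint region, half-open `[400, 1800)` cm⁻¹.
   The half-open convention makes a 1 cm⁻¹ integer grid yield exactly
   1,400 points, the dimensionality quoted for this class of screen.
2. **Baseline correction.** Urine fluorescence produces a broad background
   well approximated by a low-order polynomial. The fit is a Goldindec-
   style iterative asymmetric procedure: the input is smoothed, a degree-3
   polynomial is fitted, points rising more than a threshold *s* above the
   running baseline are treated as Raman peaks and have their pull capped
   (the target is clipped at baseline + *s*; a truncated-quadratic loss in
   iteratively-reweighted form), and the fit repeats until the relative
   coefficient change drops below `tol = 1e-6` or `max_iter = 100`.
   The threshold is found by one-dimensional bisection so that the
   fraction of peak-like points matches the configured *estimated peak
   ratio* (0.5 by default); the fraction is monotone non-increasing in
   *s*, so bisection is exact. Defaults: polynomial order 3, peak ratio
   0.5, smoothing window 5 — the standard parameterization for this
   pipeline. Non-convergence sets a flag on the result instead of raising,
   since a slightly unconverged baseline is still usable downstream.
   - *Smoothing kernel.* The pre-fit smoother is Savitzky–Golay of the
     baseline's own polynomial order. This is deliberate: a moving average
     maps a cubic to a *shifted* cubic, which would bias the fitted
     baseline away from a polynomial input; SavGol of matching order
     reproduces any degree-≤3 trend exactly, so a peak-free polynomial
     spectrum is corrected to zero at machine precision.
   - The polynomial basis is orthonormalized (QR of the Vandermonde on a
     normalized abscissa), so each inner iteration is a single projection
     and the fit is numerically stable on 1,400-point grids.
3. **Vector normalization** to unit Euclidean norm, removing scan-to-scan
   intensity scale (laser power, focus, integration time).
4. **Replicate averaging**: the pointwise mean of a specimen's scans,
   taken *after* normalization so each scan contributes equal weight.
   TPD analyses skip this stage and work on unaveraged scans.

Preprocessing uses no cross-specimen statistics, so it cannot leak
information between cross-validation folds.

## PCA and DAPC

PCA is the SVD of the column-mean-centred spectra matrix; at most
`n_spectra − 1` components exist. Loadings columns are orthonormal and the
sign of each component is fixed by making its largest-magnitude element
positive, so models are bit-reproducible across linear-algebra backends.
Explained-variance fractions are `sᵢ²/Σs²`.

DAPC fits canonical variates on the top `n_pcs` PC scores: the generalized
symmetric eigenproblem of the between-class scatter against the pooled
within-class scatter, the latter ridge-regularized by `1e-8 × trace` on
the diagonal so near-singular folds remain solvable. Canonical axes are
scaled to unit pooled within-class variance, which makes nearest-centroid
distance in canonical space a Mahalanobis distance. There are
`min(n_classes − 1, n_pcs)` canonicals and class priors are uniform
(no prevalence weighting). PC scores are not standardized before the
discriminant fit — the spectra are already unit-norm, so score scale is
meaningful; this is exposed as the natural place for a config switch if a
correlation-style variant is ever wanted.

Classification ties break deterministically toward the earliest class in a
declared reference order (default: negative classes, then controls, then
the positive class): a screening tie should fail toward gold-standard
follow-up rather than toward a positive call.

## Leave-one-out screening evaluation

The unit of cross-validation is the specimen (replicate scans are averaged
first). For each fold the PCA and DAPC are refit from scratch on the
remaining specimens and the held-out spectrum is classified as an unknown.
Confusion counts pool every non-positive, non-control class as negative;
control specimens (e.g. the Surine™ synthetic-urine standard) participate
in model fitting as their own class but are excluded from the binary
counts, matching how published screening tables are internally consistent
only without the control. If holding a specimen out leaves its class with
a single member, that class is dropped from the fold's training set (a
one-member class has no within-class scatter).

Metrics are computed at full precision and rounded to one decimal only for
reporting; a zero denominator yields NaN, never zero. Multi-class studies
are evaluated one-vs-rest by choosing each class in turn as
`positive_class`.

`find_confusion_matrix` exhaustively enumerates integer confusion matrices
with given class totals whose five rounded metrics match printed values —
the tool used to reconstruct worked examples from published tables. With
17 positives / 39 negatives the printed row (80.4, 82.4, 79.5, 63.6, 91.2)
identifies the unique matrix (TP=14, FP=8, FN=3, TN=31); likewise
(4, 2, 13, 93) on 17/95 and (10, 25, 7, 126) on 17/151.

## TPD

`TPD_u = Σᵢ₌₁..₄ f(P_u,i − P_ref,i)` over the top four PC scores of each
unaveraged scan, with `f = |·|` (`abs_sum`, default) or `f = (·)²`
(`sq_sum`). Both variants are exposed because the distance admits either
reading and published uses are reconcilable with the per-component
absolute deviation; every output records which variant produced it. The
reference score vector is the mean over the reference specimen's scans
(default reference: the Surine control; in stability studies, the
time-zero measurement). TPD is invariant to the PCA sign convention only
when sample and reference are scored in the same model, which the API
enforces by construction. Group comparisons are classical one-way ANOVA
(`scipy.stats.f_oneway`) and Tukey HSD (`scipy.stats.tukey_hsd`) on
full-precision TPD values, with group labels taken from metadata.

## Wavenumber contributions and band assignment

For PCA space, the weight of wavenumber *w* on component *j* is the
loading element; for DAPC space it is the loadings row composed with the
canonical coefficient column (the canonical axis expressed in wavenumber
space). The contribution is `|weight| / Σ|weight| × 100` per component —
an absolute-weight share, our stated convention — so contributions are
non-negative and sum to 100% per component. Shifts surpassing 0.3%
(configurable) count as signature members and are annotated from a
band table of biological Raman assignments (phosphatidylinositol 576;
nucleic acids 721/827/1340; collagen-type protein 817/981/1065/1127/1340;
aromatic amino acids 827/1004; cholesterol/fatty acids 702/1297;
monosaccharides 846; glycogen 1048; carotenoids 1417/1518 cm⁻¹), matching
within ±5 cm⁻¹. The *direction* of change (increase vs decrease in
disease) is deliberately not reported: sign conventions make it
model-dependent, and reference levels for disease have not been
established.

## Synthetic cohorts

The generator emulates the acquisition structure of a two-arm urine
study: a 1 cm⁻¹ grid over 100–3,000 cm⁻¹; 17 BCA-positive and 39
BCA-negative specimens by default (the urology-clinic composition); 10
scans per specimen. Each specimen draws a cubic fluorescence baseline
(coefficients uniform in ranges giving backgrounds a few hundred a.u.,
large against peak heights of 6–80 a.u., as in real urine fluorescence),
log-normal per-peak height jitter (σ = 0.1) and per-scan additive Gaussian
noise (SD 1 a.u., roughly 1% of the strongest band). The default band set
places the dominant urine bands (urea near 1002 cm⁻¹, creatinine, uric
acid, the C–H stretch region) plus the fifteen signature bands listed
above; a subset of signature bands (576, 721, 1004, 1048, 1340 cm⁻¹)
carries a ×1.3 height effect in the positive class. Line shapes are
Gaussian — adequate for testing the pipeline, though real Raman bands are
Lorentzian/Voigt. One explicitly seeded `numpy` generator drives the whole
cohort; the truth table retains baseline coefficients and realized heights
so baseline- and signature-recovery tests have non-circular ground truth.

What passing on these cohorts shows: the pipeline recovers known
baselines, finds planted class effects at the right wavenumbers, scores at
chance when no effect exists, and its arithmetic matches published worked
examples. What it does not show: performance on real patient spectra,
whose inter-specimen variation (diet, hydration, comorbidity, instrument
drift) is far richer than log-normal peak jitter.

## Validation design notes

- **Chance-level check.** Leave-one-out folds within one cohort share
  almost all training data, so per-cohort null accuracy is heavily
  overdispersed relative to binomial (SD ≈ 11 percentage points for 40
  specimens). The chance-level check therefore pools 50 replicate cohorts
  (2,000 held-out specimens), bringing the Monte-Carlo error to ≈1.6
  points against the ±5-point band.
- **Problem sizes.** Routine tests use 6–15 specimens per class and 1–3
  scans; the chance-level and separation checks use the full 20/20 × 10
  design. These sizes make the whole suite run in a few minutes while
  keeping every check on the full-resolution 1,400-point grid.
- **Degenerate inputs.** All-zero spectra cannot be normalized (error);
  constant spectra have a flat baseline fitted exactly; a fully degenerate
  within-class scatter is handled by the ridge plus a scale-safe distance
  computation in classification.
- **Known limitations.** JCAMP-DX support is single-block `##XYDATA`
  only. The Goldindec threshold search assumes the peak-fraction curve is
  monotone in the threshold, which holds for the clipped-target iteration
  used here. No cosmic-ray despiking or wavelength calibration is
  included. ROC/AUC analysis and k-fold schemes other than leave-one-out
  are out of scope.
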