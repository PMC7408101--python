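# Methods

## Models

**PLS (single response).** NIPALS with X-deflation only: per component,
w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, b_f = tᵀy/tᵀt, then X ← X − tpᵀ.
With a single response the inner NIPALS loop converges in one pass, scores
are mutually orthogonal, and the sequential inner coefficients coincide with
the joint least-squares regression of y on T. The fitted model stores T, P,
W, b, both residual terms and the preprocessing statistics; new samples are
projected with T_new = X_pre W (PᵀW)⁻¹. For F = min(I−1, J) on full-rank
data the prediction equals ordinary least squares, which the tests use as an
equivalence oracle.

**OPLS (single response).** One predictive component plus K orthogonal
components: w ∝ Xᵀy; per orthogonal round, w_orth ∝ p − (wᵀp)w from the
current loading p, the orthogonal component t_orth = X w_orth is removed,
and the predictive component is fitted on the filtered X. Every orthogonal
score has exactly zero covariance with y (enforced by construction, checked
to 1e−10 in tests). K = 0 reduces exactly to one-component PLS, and the
predictions of OPLS with K orthogonal components are identical to those of
(K+1)-component PLS — OPLS reorganizes the same subspace for display, it
does not add predictive power. Config-level "F components" for OPLS-DA
therefore means 1 predictive + (F−1) orthogonal, and the calibrated OPLS-DA
score plot is t_pred against the first orthogonal score.

**Preprocessing.** Modes `none`, `center` (default) and `autoscale`
(unit variance, ddof = 1). Statistics are estimated from the training rows
only and reapplied verbatim to new rows; inside cross-validation they are
re-estimated per fold from the retained rows, so no information about
held-out samples ever enters a fold model. The response is mean-centered
whenever the mode is not `none`. Columns with zero variance make autoscaling
an error rather than a silent division guard.

**Discriminant use.** Two classes, dummy coded {0, 1} in sorted label
order; predictions are thresholded at the 0.5 midpoint with ties to the
lower code. R² = 1 − SS_res/SS_tot on the calibration samples;
Q² = 1 − PRESS/SS with PRESS pooled over folds (or the test set) and the
denominator taken around the full calibration mean — the standard PRESS
convention, adopted because fold-local means make Q² depend on fold sizes.

## Cross-validated scores with rotation correction

The latent basis of a bilinear model is arbitrary up to rotation and sign,
so score matrices from different cross-validation segments are not directly
comparable. The procedure:

1. Fit the overall model on all calibration rows; its loadings P_full are
   the target frame.
2. Per segment, refit on the retained rows and find the F×F matrix R that
   maps the segment loadings toward the target: oblique (default)
   R = P_seg⁺ P_full, the least-squares minimizer; or orthogonal R = UVᵀ
   from the SVD of P_segᵀP_full.
3. Project the held-out rows through the segment model and counter-rotate
   their scores by T (Rᵀ)⁻¹.
4. Write each counter-rotated row into the validated score matrix at the
   sample's position; pool the held-out predictions for Q²(CV).

The counter-rotation is defined by the requirement that the reconstruction
is invariant: T_rot (P_seg R)ᵀ = T P_segᵀ exactly, which for orthogonal R
reduces to T R. This contract (rather than a convention choice) fixes the
oblique counter-rotation uniquely and is asserted at 1e−10 in the tests.
Rotation acts on the full loading matrix at once, one F×F matrix, not per
component, and the target is always the overall calibration model. Folds
default to stratified random 10-fold (class ratio within one sample per
fold, seeded); a contiguous-blocks scheme is available. `mode="none"`
disables the rotation and exists only to demonstrate the fold-frame sign
inconsistencies that rotation repairs.

## The simulation design

Each dataset is exactly rank two, X = t₁p₁ᵀ + t₂p₂ᵀ, 2000 samples × 360
variables, no additive noise. Classes are assigned first (balanced 50/50);
t₁ is class-conditionally Gaussian with means ±class_sep/2 and SD 1, t₂ is
N(0, 1) independent of class. p₁ has 10 uniform(0, 1) entries at random
positions and 350 exact zeros; p₂ has uniform(0, 1) entries everywhere, so
the class-relevant signal is a small fraction (~3% at the defaults) of the
total variance. Every 50th sample (1-based positions 1, 51, 101, …) forms
the 40×360 calibration set; the other 1960 are the test set. Score
distributions and `class_sep = 1.0` are this package's reconstruction of a
design that is described structurally but not distributionally; the default
separation is chosen so the two classes visibly overlap on score 1, and all
generator settings are exposed in `SimConfig`.

What the generator does *not* emulate: measurement noise, so every dataset
is exactly rank two. This has a consequence worth understanding. For
exactly rank-2 data, any 2-component PLS prediction is algebraically the
ordinary least-squares fit of y on the two latent coordinates, and every
cross-validation fold recovers the same two-dimensional latent plane
exactly. Two things follow at the 40-sample calibration size: (a) the
achievable R² − Q² optimism is that of a 2-covariate regression, roughly
0.1 at these settings, not the dramatic gaps seen in noisy high-dimensional
data; and (b) rotated cross-validated scores nearly coincide with
calibrated scores (the fold models barely differ), so the cross-validated
score plot degrades only mildly here, while the *test-set* score plot shows
the full honest overlap. Passing the simulation tests therefore
demonstrates the machinery's correctness and the direction of every effect
(calibrated separation exceeds cross-validated separation in ~95% of
repetitions; the R²−Q² gap shrinks monotonically as the calibration set
grows; Q²(CV) tracks Q²(test)), but the magnitude of score-plot
deterioration on real, noisy data — where fold models genuinely differ — is
larger than this noiseless design can produce.

## The repeated study

`run_simulation_study` repeats draw → split → fit → validate, with
repetition k seeded by `(master·1000003 + k) mod (2³¹−1)` so runs are
reproducible and parallelizable. Per repetition it records R², Q²(CV),
Q²(test) and a separation statistic for each score-plot variant. The
separation statistic is the squared distance between class means over the
pooled within-class variance in the plotted (≤2-D) score plane; it is
deliberately not affine-invariant, since the question is what a given plot
shows. The full protocol is 500 repetitions; the default here and in the
acceptance script is 100, with 20 at the large-calibration condition and 50
at the null condition, sizes at which the medians are stable to well within
the thresholds being tested. `run_external_study` applies the same records
schema to a user-supplied matrix with repeated balanced random
calibration/test splits (surplus test samples of the larger class are
discarded at random to keep the test set balanced).

## Numerical choices

- Component nullity: a score with norm < 1e−12·‖X_pre‖ aborts the fit with
  the 1-based component index.
- Sign convention: each weight vector's largest-magnitude entry is made
  positive (deterministic across platforms); scores/loadings follow.
- Projection uses (PᵀW)⁻¹ with a condition-number guard at 1e12;
  counter-rotation refuses rotation matrices with condition number > 1e8.
- Oblique Procrustes requires full column rank of the segment loadings
  (error names the deficient column count); a zero singular value in the
  orthogonal problem yields a warning and a `degenerate` flag, returning
  the SVD solution.
- Ties in classification go to the lower-coded class; label levels are
  sorted for a deterministic encoding.

## Known limitations

Two classes only; single-response PLS (no PLS2, no kernel or missing-data
variants); exactly one OPLS predictive component; rotation-corrected
cross-validated scores are provided for PLS models, not OPLS; no
permutation testing or component-number selection — the component count is
a user decision, as it is in the workflows this package audits.
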