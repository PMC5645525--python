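# Methods

This note records the models, estimators, numerical choices and known
limitations of `dynfc`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Post-processing chain

Applied per component time course, in fixed order:

1. **Detrending**: OLS residual of a cubic polynomial (with intercept) in
   the time index. The time index is standardized before building the
   Vandermonde matrix purely for conditioning; the fitted span is
   unchanged.
2. **Nuisance regression**: OLS residual on [intercept, 6 rigid-motion
   parameters, their backward differences (leading row zero)].
   Rank-deficient designs fall back to the pseudoinverse with a warning.
3. **Despiking**: residuals from a window-7 running median (nearest-edge
   padding) are left alone inside ±c₁·(1.4826·MAD) and compressed by a
   tanh map saturating at c₂·(1.4826·MAD) outside it (c₁ = 2.5,
   c₂ = 4.0). This is a fully specified, testable stand-in for AFNI
   3dDespike's bounded spike compression; a constant residual profile
   (MAD = 0) passes through unchanged.
4. **Low-pass**: zero-phase (forward–backward) order-4 Butterworth at
   0.15 Hz. At TR = 3 s the Nyquist frequency is 0.1667 Hz, so this cutoff
   sits near the band edge; results are therefore mildly sensitive to
   filter design, which is why the order and zero-phase choice are pinned
   here.

**Framewise displacement** is Power's form — Σ|Δtranslation| +
r·Σ|Δrotation| with r = 50 mm — chosen over rotation-matrix variants
because it is computable from a 6-parameter file alone without convention
ambiguity.

## Dynamic FC

Signals are demeaned, Hilbert transformed, and each unordered pair's
synchronization series is d(t) = |wrap(Δφ)|/π. The linear map in |Δφ| is
the simplest one with the required endpoint semantics (0 = synchrony,
1 = anti-phase); (1 − cos Δφ)/2 satisfies them too and would compress the
mid-range, but is not the default. No edge trimming is applied by default
(`trim` parameter available); the Hilbert transform is taken on the full
series.

## Hurst exponent by corrected R/S

For window length n the series is cut into d = ⌊T/n⌋ consecutive
non-overlapping subseries (head-aligned, remainder discarded). Per
subseries: demean, cumulate, range of cumulative sums, rescaled by the
subseries **sample (n−1) SD**; (R/S)ₙ is the mean over subseries.
Constant subseries are skipped with a warning; an all-constant series is
a hard error.

The small-sample null expectation is the Anis–Lloyd form with Weron's
finite-sample factor,

E[(R/S)ₙ] = ((n−0.5)/n) · Γ((n−1)/2)/(√π Γ(n/2)) · Σᵢ₌₁ⁿ⁻¹ √((n−i)/i),

switching to the Stirling form (nπ/2)^(−1/2) above n = 340 (the two agree
to <0.3% at the switch). Monte Carlo confirms this formula matches the
ddof = 1 convention used for the statistic to <0.3% for n ≥ 8, so the
statistic and its correction are mutually consistent.

The corrected estimate is the OLS slope of
log[(R/S)ₙ − E[(R/S)ₙ] + √(πn/2)] on log n: the additive shift removes
the null's finite-sample curvature, so white noise regresses to
Ĥ ≈ 0.5 even at T = 170 (where the raw log–log slope is biased to ≈0.60).
Windows whose corrected statistic is non-positive are dropped with a
warning; fewer than 4 usable windows is an estimation error. The raw
regression is retained as `corrected=False`.

Window grid: geometric, ratio 1.25, from 8 to ⌊T/2⌋, deduplicated — a
standard even-log-spacing choice; the source protocol does not state its
grid.

Known bias: corrected R/S attenuates high exponents at short lengths
(mean Ĥ ≈ 0.70 for fGn with H = 0.8 at T = 512, ≈0.64 at H = 0.7; the
null is unbiased). The test suite freezes bands measured from this
estimator–generator pair rather than nominal values.

## Feature table, selection, classification

2 × 946 temporal features (plus optionally 946 static-FC features),
type-major ordering. Kendall τ-b is computed in the tie-corrected form
(C − D)/√((n₀ − Tₓ)(n₀ − Tᵧ)); with ±1 labels all discordances live in
cross-group pairs, which is what the vectorized implementation counts.
Ties in |τ| break by ascending feature index. Hurst and variance features
are z-scored with training-fold statistics; static FC is already on the
Fisher-z scale and passes through. The classifier is scikit-learn's
`LinearSVC` with its LIBLINEAR defaults (L2-regularized squared-hinge
dual, C = 1, fitted intercept); whether the original LIBLINEAR run used
L1- or L2-loss is not recoverable, and the boundary difference is minor.

The per-type k is chosen by maximizing LOOCV accuracy over k = 1..k_max,
coordinate-wise (each type scanned once with the others at their current
best) — the joint 400³ grid is infeasible and per-type optima reported in
this literature suggest coordinate behaviour. Two caveats are inherent to
this protocol and reproduced deliberately: the k is tuned on the same
outer LOOCV that is reported (optimistic bias; use `loocv` at fixed k for
an unbiased estimate), and under a label-permutation null, LOOCV with
nested selection is *anti-learning* (the held-out label always opposes
the training majority that drove selection), so single-permutation
accuracies scatter widely and asymmetrically below 0.5 while their mean
stays near chance.

## Activation patterns

Per fold, A = cov(X)·W/var(S) on the z-scored selected training matrix
(the model's actual input space), scattered to full length with zeros at
unselected features; sample (n−1) covariances throughout. Standard
activation value = mean |A| over folds (zeros included). Component score
= sum of standard activation values over incident features, separately
per feature type; *important* ⇔ score ≥ mean + 2·SD (n−1). A flat score
profile flags nothing (the rule hunts outliers, and a flat profile has
none). Both effect-sign exports are provided — the signed fold-mean of A
and the sign of the patient-minus-control group mean of the raw feature —
since which of the two a published effect-direction figure encodes is
generally ambiguous.

## Synthetic cohorts

Defaults emulate the target study design: 27 patients + 25 controls,
44 components, 170 volumes at TR = 3 s, carrier band 0.03–0.10 Hz,
20 planted pairs all incident to 4 designated disease components (two
labelled cerebellar, two default-mode in the bundled annotation; the
per-network component counts are a plausible stand-in, used for labelling
only). Planted effect sizes are **calibration choices** — none are
published for this contrast: coupling-weight Hurst exponent 0.50
(control) vs 0.70 (patient) and variance 0.015 vs 0.030, i.e. patients'
coupling is more persistent and about twice as variable. They were fixed
once, during generator design, at the weakest level that transfers
reliably through the Hilbert-phase map (see below), and are not
re-tuned.

**Connectivity series**: standardized exact fGn (circulant-embedding /
Davies–Harte synthesis, exact for all H ∈ (0,1)), squashed by the
logistic map, then affinely rescaled about 0.5 so the sample variance
hits the target exactly. The squashing is monotone, so the rank-based
temporal structure — and empirically the R/S exponent (recovery MAE
≤ 0.07 at length 512) — survives.

**Signal level** (`generate_cohort`): components are band-limited
Gaussian oscillations plus white noise (σ = 0.2). Each disease component
owns one band-limited drive; for each of its planted pairs the drive
enters both ends with gain 2.5 × weight w(t) = 1 − c(t), and the
partner's own signal is attenuated as (1 − w)², so high-weight moments
are drive-dominated. Weaker couplings (additive drives without
attenuation, or per-pair independent drives, which dilute a hub hosting
five pairs) measurably fail to transfer the planted structure (per-pair
Cohen's d < 0.3).

**What the signal-level cohort does not emulate**: scanner artifacts,
head motion, ICA estimation error, non-stationary carrier spectra — and,
importantly, *non-transitive* coupling: because phase synchrony is
transitive, partners locking to a common hub drive develop genuinely
group-different mutual synchronization. The set of group-different
connections in signal space is therefore strictly larger than the
planted pair list, and component-activation rankings correctly include
partner components. A green end-to-end classification test on this
cohort establishes that planted temporal structure is detectable; it
does not (and cannot) establish sharp localization to the designated
components.

**Connection level** (`generate_connectivity_cohort`): synchronization
series are synthesized directly per pair — background pairs at
(H = 0.5, var = 0.015), planted pairs at the group values — with
per-subject heterogeneity (H jittered with SD 0.05; variance jittered
lognormally with CV 0.25, clipped to the reachable range with
deterministic back-off). Here the ground truth is sharp, and this is the
cohort used to validate activation-pattern localization: the four
planted components rank 1–4 of 44 in 10/10 seeds for both feature types,
and are exactly the set flagged by the mean + 2 SD rule.

## Operating points used in the shipped checks

- End-to-end accuracy: grid search with k ≤ 50 (runtime-scaled; the full
  1..400 grid is available via `k_max`). Measured 0.90–0.96 across seeds
  1–3 of the default signal-level world.
- Activation analysis: LOOCV at fixed k = 20 per type — the planted-pair
  count, ≈2% of features. The accuracy-maximizing k on a near-separable
  cohort collapses to a handful of features and cannot cover four hubs;
  a fixed generous k matches how activation analyses are run at their
  published operating points.

## Limitations

- The corrected R/S estimator's high-H attenuation means absolute H
  values at T = 170 are biased toward 0.5; group *contrasts* survive.
- `loocv_nested` (inner LOOCV chooses k per outer fold) gives the
  unbiased counterpart of the outer-tuned protocol but is quadratically
  expensive; the shipped pipeline defaults to the outer-tuned protocol
  for fidelity, bias documented above.
- The 0.15 Hz cutoff at TR = 3 s sits close to Nyquist; filter-design
  sensitivity is flagged, not resolved.
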