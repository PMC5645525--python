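# dynfc

Temporal features of phase-synchronization dynamic functional connectivity
(dFC), with nested cross-validated classification and activation-pattern
localization — plus a synthetic-cohort generator so the entire chain runs
and is testable without any imaging data.

## The problem

Resting-state fMRI studies of adolescent generalized anxiety disorder (and
of psychiatric cohorts generally) increasingly ask whether the *temporal
dynamics* of functional connectivity — not just its time-averaged level —
carry diagnostic information. The approach implemented here:

1. **Dynamic FC.** Each ICA component time course is cleaned (polynomial
   detrending, motion-parameter regression, despiking, 0.15 Hz low-pass)
   and Hilbert transformed. For components *i, j* the dynamic connectivity
   is the normalized instantaneous phase difference

   d(t) = |wrap(φᵢ(t) − φⱼ(t))| / π ∈ [0, 1],

   0 meaning perfect synchronization and 1 anti-synchronization. With 44
   components there are C(44, 2) = 946 pair series per subject.

2. **Temporal features.** Each d(t) series is summarized by its **Hurst
   exponent** H — estimated by rescaled-range (R/S) analysis,
   (R/S)ₙ ~ c·nᴴ, with the Anis–Lloyd/Weron small-sample correction
   (essential at 170 time points) — and its **unbiased variance**. The
   Fisher-z static correlation is a third, conventional feature type.

3. **Classification.** Features are ranked per type by |Kendall τ-b|
   against the diagnosis, the top *k* per type are z-scored and fed to a
   linear SVM (C = 1), all inside leave-one-out cross-validation so the
   held-out subject never influences selection, normalization or training.
   *k* is chosen by grid search over LOOCV accuracy.

4. **Localization.** Fold-wise weights **W** are converted to activation
   patterns **A** = cov(**X**)·**W**·cov(**S**)⁻¹ (the generative-direction
   transform; suppressor features with large weights but no label
   association get A ≈ 0). The mean of |A| across folds is a feature's
   *standard activation value*; summing over a component's incident
   connections scores components, those ≥ mean + 2 SD are *important*, and
   features selected in every fold are *consensus connections*.

Because the cohorts such studies use are rarely deposited, the package
ships a generator (`dynfc.synthetic`) that plants group differences in the
(H, variance) of coupling series on a chosen set of component pairs —
either at the signal level (narrowband oscillations sharing time-varying
drives, run through the whole pipeline) or directly at the connection
level (exactly controlled ground truth).

## Worked example

```python
import dynfc

tsset, truth = dynfc.generate_cohort(dynfc.SyntheticSpec(seed=7))
table = dynfc.build_feature_table(
    dynfc.dynamic_fc_tensor(dynfc.postprocess_cohort(tsset))
)
gs = dynfc.grid_search_k(table, types=("hurst", "variance"), k_max=50)
print(gs.best_k, gs.best_cv.metrics)
```

prints (seed 7):

```
{'hurst': 1, 'variance': 10}
accuracy 0.9808, sensitivity 1.0000, specificity 0.9600, AUC 0.9970
```

meaning: with 1 Hurst + 10 variance features selected per fold, 51 of the
52 synthetic subjects are classified correctly, and the decision values
rank patients above controls almost perfectly. On ground-truth-controlled
connection-level cohorts the activation analysis ranks the four planted
disease components 1–4 of 44 for both feature types
(`examples/05_activation_patterns.py`). The `examples/` directory walks
through every stage with one short script each.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default 52-subject synthetic cohort from the seed, runs
the full pipeline (post-processing → dynamic FC → temporal features →
nested-LOOCV grid search with k ≤ 50 → activation analysis), prints the
cross-validated metrics, and writes the target report to `--out`.
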