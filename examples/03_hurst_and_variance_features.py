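"""Estimate temporal features of dynamic FC: corrected Hurst exponent and
unbiased variance.

The Hurst exponent is estimated by rescaled-range (R/S) analysis with the
Anis-Lloyd/Weron small-sample correction: H = 0.5 means a memoryless
coupling series, H > 0.5 persistent (slowly wandering) coupling.  The
demo first shows the estimator recovering known exponents from exact
fractional Gaussian noise, then builds the full subject x feature table.
"""

import numpy as np

import dynfc

rng = np.random.default_rng(0)
print("Hurst recovery from exact fGn (length 512, 50 replicates each):")
for h in (0.3, 0.5, 0.7):
    est = [dynfc.hurst_corrected(dynfc.generate_fgn(h, 512, rng)).h for _ in range(50)]
    print(f"  true H = {h}: estimated {np.mean(est):.3f} +/- {np.std(est):.3f}")

tsset, truth = dynfc.generate_cohort(dynfc.SyntheticSpec(seed=7))
tensor = dynfc.dynamic_fc_tensor(dynfc.postprocess_cohort(tsset))
table = dynfc.build_feature_table(tensor)
print(f"\nfeature table: {table.n_subjects} subjects x {table.n_features} features "
      f"({', '.join(table.types)}; {tensor.n_pairs} pairs per type)")

lookup = {tuple(p): k for k, p in enumerate(tensor.pairs.tolist())}
pidx = np.array([lookup[p] for p in truth.planted_pairs])
lab = table.labels
for ftype in ("hurst", "variance"):
    idx = table.type_indices(ftype)[pidx]
    diff = table.values[lab == 1][:, idx].mean() - table.values[lab == -1][:, idx].mean()
    print(f"  planted-pair group difference in {ftype}: {diff:+.4f} "
          "(patients' coupling is more persistent and more variable)")
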