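"""Simulate a synthetic resting-state cohort with planted connectivity effects.

Builds the default world -- 27 patients and 25 controls, 44 ICA component
time courses of 170 volumes at TR = 3 s -- in which 20 component pairs,
all incident to four designated "disease" components, carry group
differences in the Hurst exponent (0.70 vs 0.50) and variance (0.030 vs
0.015) of their time-varying coupling.
"""

import numpy as np

import dynfc

spec = dynfc.SyntheticSpec(seed=7)
tsset, truth = dynfc.generate_cohort(spec)

print(f"cohort: {tsset.n_subjects} subjects x {tsset.n_components} components "
      f"x {tsset.n_timepoints} time points (TR = {tsset.tr} s)")
print(f"patients: {(tsset.labels == 1).sum()}, controls: {(tsset.labels == -1).sum()}")
print(f"planted pairs: {len(truth.planted_pairs)}, "
      f"disease components: {truth.disease_components}")

# the planted coupling-weight series realize the requested group variances
v_pat = truth.coupling_series[tsset.labels == 1].var(axis=-1, ddof=1).mean()
v_ctl = truth.coupling_series[tsset.labels == -1].var(axis=-1, ddof=1).mean()
print(f"mean coupling variance: patients {v_pat:.4f} vs controls {v_ctl:.4f} "
      "(patients' coupling fluctuates about twice as much)")

# write to disk in the plain-text exchange layout (one TSV per subject)
dynfc.io.write_cohort(tsset, "scratch/example_cohort", truth=truth)
print("written to scratch/example_cohort/ (TSV per subject + labels.csv + ground_truth.json)")
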