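"""Demographic-style group comparisons and metric arithmetic from summaries.

Welch's t is computed directly from printed group summaries (mean, SD, n)
-- the form used for cohort demographic tables -- and classification
metrics are reproduced from confusion counts alone.
"""

import dynfc

# state anxiety: patients (43.56 +/- 8.61, n=27) vs controls (39.12 +/- 6.96, n=25)
sai = dynfc.welch_t(dynfc.GroupSummary(43.56, 8.61, 27),
                    dynfc.GroupSummary(39.12, 6.96, 25))
print(f"state anxiety: t = {sai.t:.2f} (df = {sai.df:.1f}, p = {sai.p:.3f}) "
      "-- patients score significantly higher")

iq = dynfc.welch_t(dynfc.GroupSummary(102.67, 7.55, 27),
                   dynfc.GroupSummary(105.72, 9.20, 25))
print(f"IQ:            t = {iq.t:.2f} (df = {iq.df:.1f}, p = {iq.p:.3f}) "
      "-- groups are IQ-matched")

# metrics from confusion counts: 25/27 patients, 21/25 controls correct
m = dynfc.evaluate_counts(tp=25, fn=2, tn=21, fp=4)
print(f"\nconfusion TP=25 FN=2 TN=21 FP=4 ->")
print(f"  sensitivity {m.sensitivity:.2%}, specificity {m.specificity:.2%}, "
      f"accuracy {m.accuracy:.2%}")
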