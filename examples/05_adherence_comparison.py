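"""Do patients who received their top-ranked therapy fare better?

Builds a two-group cohort in which receivers of the top-ranked therapy have
exactly half the relapse rate of non-receivers, with sicker patients
steered away from it (confounding).  Propensity-score ATE weights rebalance
the groups before a weighted negative-binomial GLM with a log-duration
offset estimates the group effect.
"""

import numpy as np

from dmtrank import compare, simulate

cohort = simulate.generate_adherence_cohort(4000, confounded=True, seed=3)
received = cohort["took_dmt_star"].to_numpy()

naive = compare.weighted_outcome_glm(cohort, np.ones(len(cohort)), received, "relapse")
prop = compare.estimate_weights(cohort, received, method="gbm", seed=0)
weighted = compare.weighted_outcome_glm(cohort, prop.weights, received, "relapse")

print(f"true group effect (log rate ratio): {-np.log(2):.3f}")
print(f"naive slope:    {naive.slope:+.3f}  (confounded)")
print(f"weighted slope: {weighted.slope:+.3f}  (p = {weighted.p_value:.4f})")
print("\ncovariate balance (absolute standardized mean differences):")
print(prop.smd_before.round(3).rename("before").to_frame()
      .assign(after=prop.smd_after.round(3)).to_string())
# A negative slope means lower disease activity among receivers; weighting
# moves the estimate from the confounded value toward the planted -0.693
# and pushes every SMD below the conventional 0.1 balance threshold.
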