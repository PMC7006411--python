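"""Fit the hierarchical Bayesian relapse model and rank the six therapies.

Fits the predictive negative-binomial model (site random intercepts,
log-exposure offset, weakly informative priors) by ensemble MCMC, then
produces six counterfactual predictions per patient — one per DMT, with
site effects zeroed — and ranks therapies by predicted relapse count.
"""

from dmtrank import compare, glm, simulate

cycles, _, truth = simulate.generate_registry(
    simulate.SimConfig(n_patients=800, n_sites=8, seed=5)
)

spec = glm.ModelSpec(response="relapse", complexity="predictive")
fit = glm.fit(
    spec, cycles,
    mcmc=glm.MCMCConfig(chains=2, warmup=400, post=200, draws=400, seed=0),
)
print(f"fitted {len(fit.columns)} fixed effects over {len(fit.site_levels)} sites; "
      f"max R-hat {max(fit.rhat.values()):.3f}")
import numpy as np

disp = fit.flat("dispersion")
lo, hi = np.percentile(disp, [2.5, 97.5])
print(f"NB dispersion: posterior mean {disp.mean():.2f}, 95% CI [{lo:.2f}, {hi:.2f}] "
      f"(generator used {truth.dispersion}; wide at this sample size)")

summaries = glm.predict_all_dmts(fit, cycles.head(5))
ranking = compare.rank_therapies(summaries, "relapse")
print("\npredicted mean relapses per DMT (first 5 patients):")
print(summaries.round(3).to_string())
print("\ntop-ranked therapy per patient:")
print(ranking[["dmt_star", "predicted_best", "second_margin"]].round(3).to_string())
# dmt_star minimizes the predicted relapse count at the patient's own
# exposure; second_margin is the gap to the runner-up (small = near tie).
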