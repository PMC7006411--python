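"""Generate a synthetic multi-site RRMS registry and build the analysis cohort.

Draws therapy cycles with known ground truth, applies the data-quality and
inclusion filters, and prints the filter accounting plus a train/test split.
"""

from dmtrank import cohort, simulate

config = simulate.SimConfig(n_patients=2000, n_sites=25, seed=11)
cycles, trajectories, truth = simulate.generate_registry(config)
print(f"simulated {len(cycles)} therapy cycles over {config.n_sites} sites")
print(f"mean on-therapy relapses: {cycles['n_relapses'].mean():.2f}; "
      f"CDP rate: {cycles['cdp'].mean():.2%}")

# corrupt a few rows so the filters have something to do: a missing
# predictor, an implausible relapse rate, minors, and very high EDSS
cycles.loc[cycles.index[:5], "gender"] = float("nan")
cycles.loc[cycles.index[5:8], "n_relapses"] = 20
cycles.loc[cycles.index[5:8], "index_duration"] = 0.8
cycles.loc[cycles.index[8:12], "age"] = 16.0
cycles.loc[cycles.index[12:15], "edss_baseline"] = 7.0

filtered, quality = cohort.apply_quality_criteria(cycles)
filtered, inclusion = cohort.apply_inclusion_criteria(filtered, rng_seed=1)
print("\nquality filter removals:", dict(quality.removed))
print("inclusion filter removals:", dict(inclusion.removed))

train, test = cohort.split_test(filtered, fraction=0.1, rng_seed=2)
print(f"\ncohort: {len(filtered)} cycles -> {len(train)} development / "
      f"{len(test)} test")
# Each removal count names the criterion that excluded those cycles; the
# split holds out 10% of patients for final validation.
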