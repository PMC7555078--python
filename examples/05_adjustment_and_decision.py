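"""Compare TBV-adjustment techniques and run the four-step decision rule.

The same group question is asked of one region under four adjustments
(none / linear covariate / linear interaction / allometric interaction) on
an identical subject set; then a full pipeline run combines the CFA
invariance tests with the mixed models into per-region decisions.
"""

from neuroallometry import (RunConfig, compare_effects, compute_derived,
                            default_config, generate_cohort, run_pipeline,
                            run_adjustment_suite)

cfg = default_config(seed=7)
cfg.sex_ratio = (1.0, 1.0)
cfg.tbv_group_shift = 0.04    # +1 SD TBV in the ASD group, no regional effect
cohort = compute_derived(generate_cohort(cfg)[0])

tab = compare_effects(run_adjustment_suite(cohort, "left_accumbens"))
cols = ["technique", "effect", "beta", "p_fdr", "significant"]
print(tab[cols].to_string(index=False))
# Without any TBV adjustment the group term is spuriously significant
# (it only reflects the TBV shift); all three adjusted techniques agree
# there is no regional group difference.

run = RunConfig(seed=7, out_dir="scratch/example_run", subsamples={})
bundle = run_pipeline(run)
print("\npipeline stages:", bundle.manifest["stages"])
calls = [r for r in bundle.decisions if r.final_call == "group_difference"]
print(f"four-step group-difference calls on a null cohort: {len(calls)}")
# On a null cohort the conjunction of the four criteria should call none.
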