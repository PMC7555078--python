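"""Mixed-effects group comparison with site random intercepts and FDR.

The standardized model z(log10 V) ~ group + z(log10 TBV) + group:z(log10
TBV) + (1 | site) separates a volumetric group difference (group term) from
an allometric scaling difference (interaction term).  Sensitivity variants
drop flagged outliers/comorbid subjects and add a medication covariate.
"""

from neuroallometry import (compute_derived, default_config, flag_outliers,
                            generate_cohort, inject_group_difference,
                            sensitivity_suite)
from neuroallometry.lmem import LMEMSpec
from neuroallometry.simulate import delta_alpha_for_standardized_gap

cfg = default_config(seed=7)
cfg.sex_ratio = (1.0, 1.0)
cfg.n_per_group = (137, 123)
gap = delta_alpha_for_standardized_gap(cfg, "right_hippocampus", -0.25)
cfg = inject_group_difference(cfg, "right_hippocampus", gap,
                              anchor_log10_tbv=cfg.tbv_log10_mean["male"])
cohort = flag_outliers(compute_derived(generate_cohort(cfg)[0]))

spec = LMEMSpec(response="right_hippocampus",
                fixed_terms=("group", "log_tbv", "group:log_tbv"))
for variant, res in sensitivity_suite(spec, cohort).items():
    row = res.term("group:log_tbv")
    print(f"{variant:22s} n={res.meta['n']:3d}  "
          f"group x log10(TBV): beta = {row['beta']:+.2f} "
          f"(se {row['se']:.2f}), p_fdr = {row['p_fdr']:.3f}")
# The interaction beta should sit near the injected -0.25 in every variant:
# a scaling group difference that survives outlier/comorbidity removal.
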