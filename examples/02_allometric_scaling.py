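"""Fit per-region power laws and classify their scaling against TBV.

For each regional volume V and total brain volume TBV the model is
log10(V) = intercept + alpha * log10(TBV); alpha < 1 means the region grows
more slowly than the whole brain (hypoallometry), alpha > 1 faster
(hyperallometry).  Classification uses the 95% CI against 1.
"""

from neuroallometry import (compute_derived, default_config, generate_cohort,
                            scaling_table)

cfg = default_config(seed=7)
cfg.n_per_group = (2000, 2000)   # large draw for tight CIs
cohort = compute_derived(generate_cohort(cfg)[0])

tab = scaling_table(cohort, groups=("control",))
print(tab[["region", "alpha", "ci_low", "ci_high", "p_isometry",
           "classification"]].to_string(index=False))
# White matter scales faster than TBV (alpha ~ 1.15), the cortices scale
# proportionally (alpha ~ 1), and subcortical structures scale more slowly
# (alpha 0.6-0.9) — the canonical scaling pattern for these volumes.
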