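"""Four total-brain-volume adjustment techniques, fitted on identical data.

The same group-difference question is asked of one regional volume under:

  (a) ``none``                  z(raw volume) ~ group
  (b) ``covariate``             z(raw volume) ~ group + z(TBV)
  (c) ``linear_interaction``    z(raw volume) ~ group * z(TBV)
  (d) ``allometric_interaction`` z(log10 volume) ~ group * z(log10 TBV)

all with a scanner-site random intercept and an identical subject set, so
any divergence in the group effect is attributable to the adjustment alone.
Omitting TBV (a) confounds regional and global differences; the covariate
approach (b) assumes a linear, group-common volume-TBV relationship and can
over- or under-correct for hypo-/hyperallometric regions; (c) allows the
linear relationship to differ by group; (d) is the allometric adjustment on
the log-log scale where the power law is linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .lmem import LMEMSpec, fit_lmem

TECHNIQUES = ("none", "covariate", "linear_interaction",
              "allometric_interaction")

_SPEC_TEMPLATES = {
    "none": ("rawz", ("group",)),
    "covariate": ("rawz", ("group", "tbv")),
    "linear_interaction": ("rawz", ("group", "tbv", "group:tbv")),
    "allometric_interaction": ("log10z", ("group", "log_tbv",
                                          "group:log_tbv")),
}


@dataclass
class AdjustmentSuiteResult:
    region: str
    results: dict                      # technique -> LMEMResult
    subject_ids: tuple[str, ...]       # identical across techniques
    extra_terms: tuple[str, ...] = ()
    status: dict = field(default_factory=dict)   # technique -> ok/error

    @property
    def complete(self) -> bool:
        return all(v == "ok" for v in self.status.values())


def run_adjustment_suite(cohort: CohortTable, region: str,
                         extra_terms=(), data_filter: str = "full"
                         ) -> AdjustmentSuiteResult:
    """Fit all four techniques for one region on one shared subject set."""
    if region not in cohort.regions:
        raise KeyError(f"unknown region: {region!r}")
    extra_terms = tuple(extra_terms)

    # the shared subject set: complete cases on the most demanding variable
    # union (the filters are shared too, applied once up front)
    probe = LMEMSpec(response=region, response_scale="log10z",
                     fixed_terms=("group", "log_tbv", "tbv") + extra_terms,
                     data_filter=data_filter)
    from .lmem import build_model_frame
    ids = tuple(build_model_frame(probe, cohort)["subject_id"])
    sub = cohort.subset(cohort.df["subject_id"].isin(ids))

    results, status = {}, {}
    for tech in TECHNIQUES:
        scale, terms = _SPEC_TEMPLATES[tech]
        spec = LMEMSpec(response=region, response_scale=scale,
                        fixed_terms=terms + extra_terms, data_filter="full")
        try:
            results[tech] = fit_lmem(spec, sub)
            status[tech] = "ok"
        except (ValueError, np.linalg.LinAlgError) as exc:
            status[tech] = f"failed: {exc}"
    return AdjustmentSuiteResult(region=region, results=results,
                                 subject_ids=ids, extra_terms=extra_terms,
                                 status=status)


def compare_effects(suite: AdjustmentSuiteResult) -> pd.DataFrame:
    """Wide comparison table of the group terms across techniques.

    One row per (technique, effect), with standardized beta, Cohen's d,
    an FDR significance flag, and the ratio of each technique's group beta
    to the allometric-adjustment group beta.
    """
    rows = []
    ref_beta = None
    if suite.status.get("allometric_interaction") == "ok":
        ref_beta = float(suite.results["allometric_interaction"]
                         .term("group")["beta"])
    for tech in TECHNIQUES:
        if suite.status.get(tech) != "ok":
            rows.append({"technique": tech, "effect": "group",
                         "status": suite.status.get(tech, "missing")})
            continue
        res = suite.results[tech]
        effects = ["group"]
        if tech == "linear_interaction":
            effects.append("group:tbv")
        elif tech == "allometric_interaction":
            effects.append("group:log_tbv")
        for eff in effects:
            row = res.term(eff)
            entry = {
                "technique": tech, "effect": eff, "status": "ok",
                "beta": float(row["beta"]), "se": float(row["se"]),
                "p": float(row["p"]), "p_fdr": float(row["p_fdr"]),
                "d": float(row["d"]),
                "significant": bool(row["p_fdr"] < 0.05),
            }
            if eff == "group" and ref_beta not in (None, 0.0):
                entry["beta_ratio_vs_allometric"] = entry["beta"] / ref_beta
            rows.append(entry)
    df = pd.DataFrame(rows)
    # flag techniques whose group-term significance disagrees with the others
    if "significant" in df.columns:
        grp = df[df["effect"] == "group"].dropna(subset=["significant"])
        if len(grp) > 1:
            majority = grp["significant"].mode().iloc[0]
            df["discordant"] = False
            mask = (df["effect"] == "group") & (df["significant"] != majority)
            df.loc[mask, "discordant"] = True
    return df
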