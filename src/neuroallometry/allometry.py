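"""Per-region, per-group allometric (power-law) scaling fits.

The allometric model is log10(V_i) = intercept + alpha * log10(TBV) + error,
fitted by OLS within each diagnostic group.  ``alpha`` is the allometric
exponent: alpha = 1 is isometry (the region grows proportionally with TBV),
alpha < 1 hypoallometry, alpha > 1 hyperallometry.  Departure from isometry
is tested with a Wald chi-square test of H0: alpha = 1; the 95% CI uses the
t distribution on the residual degrees of freedom.

Optional covariate sets match the sensitivity analyses of the scaling
tables: age, sex, their interaction, medication, and fixed site dummies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.formula.api as smf
from scipy import stats

from .cohort import CohortTable

#: covariate vocabulary -> formula fragment
_COVARIATE_TERMS = {
    "age": "age_c",
    "sex": "C(sex)",
    "age:sex": "age_c:C(sex)",
    "medication": "C(medication)",
    "site": "C(site)",
}


@dataclass
class ScalingFit:
    region: str
    group: str
    alpha: float
    alpha_se: float
    ci95: tuple[float, float]
    intercept: float
    isometry_test: tuple[float, float]   # (Wald statistic, p-value)
    n: int
    covariates: tuple[str, ...]
    degenerate: bool = False             # zero residual variance


def fit_scaling(cohort: CohortTable, region: str, group: str,
                covariates=()) -> ScalingFit:
    """OLS of log10(region volume) on log10(TBV) within one group."""
    if not cohort.has_derived:
        raise ValueError("compute_derived must be called before fit_scaling")
    if region not in cohort.regions:
        raise KeyError(f"unknown region: {region!r}")
    sub = cohort.group_frame(group)
    if len(sub) < 10:
        raise ValueError(f"group {group!r} has fewer than 10 subjects")
    data = sub.copy()
    data["age_c"] = data["age"] - data["age"].mean()
    terms = ["log10_tbv"]
    for c in covariates:
        if c not in _COVARIATE_TERMS:
            raise ValueError(f"unknown covariate: {c!r}")
        for var in ("sex", "medication", "site"):
            if var in c and data[var].nunique() < 2:
                raise np.linalg.LinAlgError(
                    f"rank-deficient design: covariate {c!r} is constant in "
                    f"the {group!r} subsample")
        terms.append(_COVARIATE_TERMS[c])
    formula = f"log10_{region} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for {region!r}/{group!r} with "
            f"covariates {tuple(covariates)!r}")
    res = model.fit()
    alpha = float(res.params["log10_tbv"])
    se = float(res.bse["log10_tbv"])
    dof = int(res.df_resid)
    tcrit = stats.t.ppf(0.975, dof)
    ci = (alpha - tcrit * se, alpha + tcrit * se)
    fit = ScalingFit(region=region, group=group, alpha=alpha, alpha_se=se,
                     ci95=ci, intercept=float(res.params["Intercept"]),
                     isometry_test=(np.nan, np.nan), n=int(res.nobs),
                     covariates=tuple(covariates),
                     degenerate=not np.isfinite(se) or se < 1e-12)
    fit.isometry_test = test_isometry(fit)
    return fit


def test_isometry(fit: ScalingFit) -> tuple[float, float]:
    """Wald test of H0: alpha = 1; statistic ((alpha-1)/se)^2 ~ chi2(1)."""
    if fit.alpha_se < 1e-12 or not np.isfinite(fit.alpha_se):
        if np.isclose(fit.alpha, 1.0, atol=1e-9):
            return (0.0, 1.0)
        warnings.warn(f"degenerate fit for {fit.region}/{fit.group}: "
                      "zero slope SE with alpha != 1")
        return (np.inf, 0.0)
    stat = float(((fit.alpha - 1.0) / fit.alpha_se) ** 2)
    return (stat, float(stats.chi2.sf(stat, 1)))


def classify_scaling(fit: ScalingFit) -> str:
    """hyper if CI excludes 1 from above, hypo from below, else isometric."""
    lo, hi = fit.ci95
    if lo > 1.0:
        return "hyperallometric"
    if hi < 1.0:
        return "hypoallometric"
    return "isometric"


def scaling_table(cohort: CohortTable, regions=None, groups=("control", "asd"),
                  covariates=()):
    """Tidy per-region, per-group scaling table (one row per fit)."""
    import pandas as pd

    regions = list(regions) if regions is not None else [
        r for r in cohort.regions if r != "total_gray_matter"]
    rows = []
    for region in regions:
        for group in groups:
            f = fit_scaling(cohort, region, group, covariates)
            rows.append({
                "region": region, "group": group, "n": f.n,
                "alpha": f.alpha, "se": f.alpha_se,
                "ci_low": f.ci95[0], "ci_high": f.ci95[1],
                "p_isometry": f.isometry_test[1],
                "classification": classify_scaling(f),
                "covariate_set": "+".join(covariates) or "none",
            })
    return pd.DataFrame(rows)
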