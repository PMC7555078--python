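"""Linear mixed-effects group models with scanner-site random intercepts.

Each model regresses a standardized regional volume (z of log10 volume, or z
of the raw volume for unadjusted/linear-adjustment analyses) on fixed
effects built from {group, log10(TBV), TBV, age, age^2, sex, FSIQ,
hemisphere, medication, ADOS total} with a scanner-site random intercept
(plus a subject random intercept when hemisphere enters as a within-subject
factor).  Continuous predictors are centered and scaled; two-level factors
are coded 1/2 (1: control, 2: ASD; 1: male; 1: left) and centered, so a
positive group coefficient means the ASD value is larger.  Reported betas
are therefore standardized effect sizes comparable with the CFA's.

A significant group-by-log10(TBV) interaction indicates an allometric
scaling difference between groups; a significant group main effect a
volumetric difference.  Fixed-effect p-values are Wald normal-approximation
tests, FDR-adjusted (Benjamini-Hochberg) within each model.  Cohen's d is
derived from the Wald statistic as d = 2 t / sqrt(nu) with nu the residual
degrees of freedom.

Sensitivity variants refit the same model (a) on the full table, (b) minus
flagged outliers and comorbid subjects, and (c) additionally with a
medication covariate; severity models replace the group effect by the
z-scored total ADOS score within the ASD group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable, any_outlier_mask

#: variables permitted in fixed-effect terms
MODEL_VARIABLES = ("group", "log_tbv", "tbv", "age", "age2", "sex", "fsiq",
                   "hemisphere", "medication", "ados")


@dataclass
class LMEMSpec:
    response: str                       # region name (or bilateral base name
    #                                     when hemisphere is a fixed term)
    fixed_terms: tuple[str, ...]        # e.g. ("group", "log_tbv",
    #                                     "group:log_tbv")
    response_scale: str = "log10z"      # "log10z" or "rawz"
    random_intercepts: tuple[str, ...] = ("site",)
    data_filter: str = "full"           # full|no_outliers|no_comorbidities|both

    def __post_init__(self):
        self.fixed_terms = tuple(self.fixed_terms)
        for t in self.fixed_terms:
            for v in t.split(":"):
                if v not in MODEL_VARIABLES:
                    raise ValueError(f"unknown model variable {v!r} in term "
                                     f"{t!r}")
        has_hemi = any("hemisphere" in t.split(":") for t in self.fixed_terms)
        if has_hemi != ("subject" in self.random_intercepts):
            raise ValueError("a subject random intercept is required exactly "
                             "when hemisphere is a fixed term")


@dataclass
class LMEMResult:
    spec: LMEMSpec
    table: pd.DataFrame     # index: term; columns: beta, se, p, p_fdr, d
    meta: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.meta.get("converged", False))

    def term(self, name: str) -> pd.Series:
        key = _canon_term(name)
        if key not in self.table.index:
            raise KeyError(f"term {name!r} not in model "
                           f"({list(self.table.index)})")
        return self.table.loc[key]


def _canon_term(term: str) -> str:
    parts = term.split(":")
    return ":".join(sorted(parts, key=MODEL_VARIABLES.index))


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance predictor")
    return (x - np.nanmean(x)) / sd


def _centered_code(values, levels):
    code = np.select([values == levels[0], values == levels[1]], [1.0, 2.0],
                     default=np.nan)
    if np.nanstd(code) == 0:
        raise ValueError(f"factor with levels {levels} is constant in the "
                         "analysis sample")
    return code - np.nanmean(code)


def build_model_frame(spec: LMEMSpec, cohort: CohortTable) -> pd.DataFrame:
    """Complete-case model frame with standardized variables.

    Standardization (centering/scaling) is computed on the analysis sample
    itself, so betas are standardized effect sizes for that sample.
    """
    if not cohort.has_derived:
        raise ValueError("compute_derived must be called first")
    needed = sorted({v for t in spec.fixed_terms for v in t.split(":")})
    has_hemi = "hemisphere" in needed
    df = cohort.df

    if spec.data_filter in ("no_outliers", "both"):
        resp_regions = ([f"left_{spec.response}", f"right_{spec.response}"]
                        if has_hemi else [spec.response])
        df = df[~any_outlier_mask(cohort, resp_regions)]
    if spec.data_filter in ("no_comorbidities", "both"):
        df = df[~df["comorbidity"]]

    if has_hemi:
        left, right = f"left_{spec.response}", f"right_{spec.response}"
        for col in (left, right):
            if col not in df.columns:
                raise KeyError(f"bilateral response needs column {col!r}")
        long = []
        for hemi, col in (("left", left), ("right", right)):
            part = df.copy()
            part["_rawvol"] = part[col]
            part["_hemi"] = hemi
            long.append(part)
        df = pd.concat(long, ignore_index=True)
        raw = df["_rawvol"].to_numpy(dtype=float)
    else:
        if spec.response not in df.columns:
            raise KeyError(f"unknown response region {spec.response!r}")
        raw = df[spec.response].to_numpy(dtype=float)

    out = pd.DataFrame(index=df.index)
    out["site"] = df["site"].to_numpy()
    out["subject_id"] = df["subject_id"].to_numpy()
    if spec.response_scale == "log10z":
        out["y"] = _zscore(np.log10(raw))
    elif spec.response_scale == "rawz":
        out["y"] = _zscore(raw)
    else:
        raise ValueError(f"unknown response scale {spec.response_scale!r}")

    age_c = df["age"].to_numpy(dtype=float) - df["age"].mean()
    builders = {
        "group": lambda: _centered_code(df["group"].to_numpy(),
                                        ("control", "asd")),
        "sex": lambda: _centered_code(df["sex"].to_numpy(),
                                      ("male", "female")),
        "hemisphere": lambda: _centered_code(df["_hemi"].to_numpy(),
                                             ("left", "right")),
        "medication": lambda: _centered_code(
            df["medication"].to_numpy(dtype=bool), (False, True)),
        "log_tbv": lambda: _zscore(df["log10_tbv"].to_numpy(dtype=float)),
        "tbv": lambda: _zscore(df["tbv"].to_numpy(dtype=float)),
        "age": lambda: _zscore(age_c),
        "age2": lambda: _zscore(age_c ** 2),
        "fsiq": lambda: _zscore(df["fsiq"].to_numpy(dtype=float)),
        "ados": lambda: _zscore(df["ados_total"].to_numpy(dtype=float)),
    }
    for v in needed:
        out[v] = builders[v]()
    out = out.dropna().reset_index(drop=True)
    return out


def _fit_frame(spec: LMEMSpec, frame: pd.DataFrame) -> LMEMResult:
    terms = [_canon_term(t) for t in spec.fixed_terms]
    formula = "y ~ " + " + ".join(terms) if terms else "y ~ 1"
    meta = {"n": len(frame), "filter": spec.data_filter,
            "formula": formula, "method": "mixedlm"}
    use_site = "site" in spec.random_intercepts
    n_sites = frame["site"].nunique()
    use_subject = "subject" in spec.random_intercepts

    res = None
    if use_site and n_sites >= 2:
        kw = dict(groups=frame["site"], re_formula="1")
        if use_subject:
            kw["vc_formula"] = {"subject": "0 + C(subject_id)"}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, frame, **kw)
                res = model.fit(reml=True)
            if not res.converged:
                res = None
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is not None:
            meta["converged"] = True
            meta["reml_loglik"] = float(res.llf)
            meta["site_var"] = float(np.asarray(res.cov_re)[0, 0])
    if res is None:
        # fall back to OLS (site as fixed dummies when several sites exist)
        f2 = formula + (" + C(site)" if use_site and n_sites >= 2 else "")
        if use_subject and frame["subject_id"].duplicated().any():
            f2 += " + C(subject_id)"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.ols(f2, frame).fit()
        meta.update(method="ols_site_fixed" if "C(site)" in f2 else "ols",
                    converged=True)

    params = res.params
    bse = res.bse
    pvals = res.pvalues
    nu = len(frame) - (len(terms) + 1)
    meta["resid_df"] = nu
    rows = []
    for t in terms:
        if t not in params.index:
            raise RuntimeError(f"term {t!r} missing from fit")
        beta, se, p = float(params[t]), float(bse[t]), float(pvals[t])
        tstat = beta / se if se > 0 else np.inf
        d = 2.0 * tstat / np.sqrt(nu) if nu > 0 else np.nan
        rows.append((t, beta, se, p, d))
    table = pd.DataFrame(rows, columns=["term", "beta", "se", "p", "d"]
                         ).set_index("term")
    table["p_fdr"] = fdr_adjust(table["p"].tolist())
    table = table[["beta", "se", "p", "p_fdr", "d"]]
    return LMEMResult(spec=spec, table=table, meta=meta)


def fit_lmem(spec: LMEMSpec, cohort: CohortTable) -> LMEMResult:
    """REML mixed-model fit of one spec; OLS fallback on singular fits."""
    frame = build_model_frame(spec, cohort)
    if "site" in spec.random_intercepts and frame["site"].nunique() < 2:
        warnings.warn("single site: random intercept dropped, using OLS")
    return _fit_frame(spec, frame)


def fdr_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = list(p_values)
    if not p:
        return []
    if any(not 0 <= v <= 1 for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def sensitivity_suite(spec: LMEMSpec, cohort: CohortTable) -> dict:
    """(a) full data, (b) minus flagged outliers and comorbid subjects,
    (c) variant (b) plus a medication fixed effect."""
    results = {}
    results["full"] = fit_lmem(replace(spec, data_filter="full"), cohort)
    robust = replace(spec, data_filter="both")
    try:
        results["no_outliers_comorbid"] = fit_lmem(robust, cohort)
    except ValueError as exc:
        results["no_outliers_comorbid"] = f"skipped: {exc}"
        return results
    terms = robust.fixed_terms
    if "medication" not in terms:
        terms = terms + ("medication",)
    try:
        results["medication_covariate"] = fit_lmem(
            replace(robust, fixed_terms=terms), cohort)
    except ValueError as exc:
        results["medication_covariate"] = f"skipped: {exc}"
    return results


def severity_model(spec: LMEMSpec, cohort: CohortTable) -> LMEMResult:
    """Refit on the ASD subset with z-scored total ADOS replacing group."""
    terms = tuple(":".join("ados" if v == "group" else v for v in t.split(":"))
                  for t in spec.fixed_terms)
    if any("group" in t.split(":") for t in terms):
        raise ValueError("group term not permitted in a severity model")
    sub = cohort.subset(cohort.df["group"] == "asd")
    n_ados = int(sub.df["ados_total"].notna().sum())
    if n_ados < 30:
        raise ValueError(f"only {n_ados} ASD subjects with ADOS (need >= 30)")
    return fit_lmem(replace(spec, fixed_terms=terms), sub)


def _removable(terms):
    """Interactions removable under marginality: no retained higher-order
    interaction strictly contains them."""
    inter = [t for t in terms if ":" in t]
    out = []
    for t in inter:
        s = set(t.split(":"))
        if not any(s < set(u.split(":")) for u in inter if u != t):
            out.append(t)
    return out


def backward_eliminate(spec: LMEMSpec, cohort: CohortTable,
                       threshold: float = 0.05):
    """Sequentially remove the highest-p nonsignificant interaction
    (p > threshold, raw), respecting marginality; main effects are never
    removed.  Equal p-values break ties toward the lexicographically later
    term.  Returns (final_spec, final_fit)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    current = spec
    fit = fit_lmem(current, cohort)
    while True:
        if not fit.converged:
            fit.meta["elimination_status"] = "stopped: non-convergence"
            break
        cands = [(float(fit.table.loc[_canon_term(t), "p"]), t)
                 for t in _removable(current.fixed_terms)]
        cands = [(p, t) for p, t in cands if p > threshold]
        if not cands:
            break
        cands.sort(key=lambda pt: (pt[0], pt[1]))   # highest p, then latest
        _, drop = cands[-1]
        current = replace(current, fixed_terms=tuple(
            t for t in current.fixed_terms if t != drop))
        fit = fit_lmem(current, cohort)
    return current, fit


def cohens_d_from_fit(result: LMEMResult, term: str) -> float:
    """d = 2 t / sqrt(nu), t the Wald statistic, nu the residual df."""
    row = result.term(term)
    nu = result.meta.get("resid_df", 0)
    if nu <= 0:
        warnings.warn("residual df <= 0; Cohen's d undefined")
        return np.nan
    t = row["beta"] / row["se"] if row["se"] > 0 else np.inf
    return float(2.0 * t / np.sqrt(nu))
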