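"""Multi-group one-factor confirmatory factor analysis with mean structure.

The measurement model per group g is

    x = nu_g + lambda_g * eta + eps,   eta ~ N(kappa_g, phi_g),
    eps ~ N(0, Theta_g),

where x stacks the standardized log10 regional volumes, the latent factor
eta plays the role of (standardized) log10 TBV, loadings are the allometric-
slope analogs and intercepts the volume analogs.  Theta_g is diagonal plus
free covariances for designated residual pairs (homologous left/right
regions by default).  Identification: phi = 1 and kappa = 0 in every group
unless explicitly freed in the non-reference group; this convention
reproduces a metric-invariance chi-square difference test with exactly p
degrees of freedom for p indicators.

Estimation minimizes the two-group normal-theory ML discrepancy

    F = sum_g (n_g/N) [ log|Sigma_g| + tr(S_g Sigma_g^-1) - log|S_g| - p
                        + (m_g - mu_g)' Sigma_g^-1 (m_g - mu_g) ]

with sample covariances using divisor n_g; the test statistic is N*F, the
exact likelihood-ratio statistic against the saturated model.  The gradient
is analytic; variances are parameterized on the log scale; the start is
deterministic (first principal component loadings, half sample variances)
with seeded jitter restarts on non-convergence.

Invariance cascade: configural -> global metric (loadings equal) ->
regional metric (one loading freed at a time, Bonferroni) -> global scalar
(intercepts equal on top of the metric outcome) -> regional scalar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .cohort import CohortTable


class IdentificationError(ValueError):
    """Model not identified (e.g. free latent mean with free intercepts)."""


# --------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class CFASpec:
    """One-factor multi-group CFA specification with equality constraints."""

    indicators: tuple[str, ...]
    residual_pairs: tuple[tuple[str, str], ...] = ()
    groups: tuple[str, ...] = ("control", "asd")
    loadings_equal: bool = False
    intercepts_equal: bool = False
    free_loadings: frozenset = frozenset()     # exceptions to loadings_equal
    free_intercepts: frozenset = frozenset()   # exceptions to intercepts_equal
    latent_mean_free: bool = False             # kappa of 2nd group estimated
    latent_var_free: bool = False              # phi of 2nd group estimated

    def __post_init__(self):
        if len(self.indicators) < 3:
            raise ValueError("at least 3 indicators required")
        known = set(self.indicators)
        for a, b in self.residual_pairs:
            if a not in known or b not in known:
                raise ValueError(f"residual pair ({a}, {b}) references "
                                 "unknown indicator")
        for s in (self.free_loadings, self.free_intercepts):
            if not set(s) <= known:
                raise ValueError("free-parameter override references unknown "
                                 "indicator")
        if self.latent_mean_free and not self.intercepts_equal:
            raise IdentificationError(
                "a free latent mean requires cross-group intercept equality "
                "constraints (intercepts_equal=True)")

    @classmethod
    def from_constraint_set(cls, indicators, residual_pairs=(),
                            constraint_set="configural",
                            latent_on_group=False, **kw):
        """Build from the enum {configural, metric_all, scalar_all}."""
        flags = {
            "configural": dict(),
            "metric_all": dict(loadings_equal=True),
            "scalar_all": dict(loadings_equal=True, intercepts_equal=True),
        }
        if constraint_set not in flags:
            raise ValueError(f"unknown constraint set: {constraint_set!r}")
        return cls(indicators=tuple(indicators),
                   residual_pairs=tuple(tuple(p) for p in residual_pairs),
                   latent_mean_free=latent_on_group,
                   **flags[constraint_set], **kw)

    def is_nested_in(self, other: "CFASpec") -> bool:
        """True if self (restricted) nests inside other (freer)."""
        if (self.indicators != other.indicators
                or self.residual_pairs != other.residual_pairs
                or self.groups != other.groups):
            return False
        free_self = _free_param_keys(self)
        free_other = _free_param_keys(other)
        return free_self <= free_other


def _free_param_keys(spec: CFASpec) -> set:
    """Symbolic key set of free parameters (for nesting checks)."""
    keys = set()
    G = len(spec.groups)
    for i, ind in enumerate(spec.indicators):
        for g in range(G):
            lg = 0 if (g > 0 and spec.loadings_equal
                       and ind not in spec.free_loadings) else g
            keys.add(("lam", lg, i))
            ng = 0 if (g > 0 and spec.intercepts_equal
                       and ind not in spec.free_intercepts) else g
            keys.add(("nu", ng, i))
            keys.add(("th", g, i))
    for g in range(G):
        for k in range(len(spec.residual_pairs)):
            keys.add(("psi", g, k))
    if spec.latent_mean_free:
        keys.add(("kappa", 1))
    if spec.latent_var_free:
        keys.add(("phi", 1))
    return keys


# --------------------------------------------------------------------------
# parameter layout


class _Layout:
    """Maps free-parameter vector positions to model matrices per group."""

    def __init__(self, spec: CFASpec):
        p = len(spec.indicators)
        G = len(spec.groups)
        K = len(spec.residual_pairs)
        ix = {n: i for i, n in enumerate(spec.indicators)}
        self.pairs = np.array([[ix[a], ix[b]] for a, b in spec.residual_pairs],
                              dtype=int).reshape(K, 2)
        self.p, self.G, self.K = p, G, K
        nxt = 0

        def take():
            nonlocal nxt
            nxt += 1
            return nxt - 1

        self.lam = np.zeros((G, p), dtype=int)
        self.nu = np.zeros((G, p), dtype=int)
        self.lth = np.zeros((G, p), dtype=int)
        self.psi = np.zeros((G, K), dtype=int)
        for i in range(p):
            self.lam[0, i] = take()
        for i in range(p):
            self.nu[0, i] = take()
        if G == 2:
            for i, ind in enumerate(spec.indicators):
                self.lam[1, i] = (self.lam[0, i]
                                  if spec.loadings_equal
                                  and ind not in spec.free_loadings else take())
            for i, ind in enumerate(spec.indicators):
                self.nu[1, i] = (self.nu[0, i]
                                 if spec.intercepts_equal
                                 and ind not in spec.free_intercepts else take())
        for g in range(G):
            for i in range(p):
                self.lth[g, i] = take()
            for k in range(K):
                self.psi[g, k] = take()
        self.kappa = take() if spec.latent_mean_free else -1
        self.lphi = take() if spec.latent_var_free else -1
        self.n_free = nxt


# --------------------------------------------------------------------------
# results


@dataclass
class CFAParameters:
    loadings: dict        # group -> array over indicators
    intercepts: dict
    residual_var: dict
    residual_cov: dict    # group -> {(a, b): cov}
    latent_var: dict      # group -> phi
    latent_mean: dict     # group -> kappa


@dataclass
class CFAFitResult:
    spec: CFASpec
    parameters: CFAParameters
    chisq: float
    df: int
    fit_indices: tuple[float, float, float]   # (cfi, tli, rmsea)
    converged: bool
    n_per_group: dict
    loglik: float
    baseline_chisq: float = np.nan
    baseline_df: int = 0
    rmsea_flagged: bool = False
    _layout: object = field(default=None, repr=False)
    _x: object = field(default=None, repr=False)
    _moments: object = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return int(sum(self.n_per_group.values()))


@dataclass
class InvarianceTestResult:
    level: str                       # global_metric / regional_metric / ...
    target: str | None
    delta_chisq: float
    delta_df: int
    p_value: float
    delta_cfi: float
    delta_rmsea: float
    standardized_group_difference: float | None = None
    significant: bool | None = None  # at the alpha used by the cascade
    chen_flags: tuple[bool, bool] = (False, False)  # (|dCFI|>.005, |dRMSEA|>=.010)
    restricted: CFAFitResult | None = None
    free: CFAFitResult | None = None


@dataclass
class CascadeResult:
    tests: list
    fits: dict
    status: str = "complete"

    def __iter__(self):
        return iter(self.tests)


# --------------------------------------------------------------------------
# core estimation on sample moments


def _discrepancy(x, lay: _Layout, means, covs, weights, logdet_s):
    """Weighted ML discrepancy F and its analytic gradient."""
    p = lay.p
    F = 0.0
    grad = np.zeros(lay.n_free)
    for g in range(lay.G):
        lam = x[lay.lam[g]]
        nu = x[lay.nu[g]]
        th = np.exp(x[lay.lth[g]])
        phi = np.exp(x[lay.lphi]) if (g == 1 and lay.lphi >= 0) else 1.0
        kap = x[lay.kappa] if (g == 1 and lay.kappa >= 0) else 0.0
        Sigma = phi * np.outer(lam, lam)
        Sigma[np.diag_indices(p)] += th
        for k in range(lay.K):
            i, j = lay.pairs[k]
            Sigma[i, j] += x[lay.psi[g, k]]
            Sigma[j, i] += x[lay.psi[g, k]]
        try:
            cf = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return np.inf, grad
        logdet = 2.0 * np.log(np.diag(cf)).sum()
        Sinv = np.linalg.inv(cf).T @ np.linalg.inv(cf)
        S = covs[g]
        d = means[g] - (nu + lam * kap)
        Sd = Sinv @ d
        F_g = (logdet + np.trace(S @ Sinv) - logdet_s[g] - p + d @ Sd)
        w = weights[g]
        F += w * F_g
        # dF/dSigma and dF/dmu
        Gm = Sinv - Sinv @ (S + np.outer(d, d)) @ Sinv
        h = -2.0 * Sd
        glam = 2.0 * phi * (Gm @ lam) + kap * h
        np.add.at(grad, lay.lam[g], w * glam)
        np.add.at(grad, lay.nu[g], w * h)
        np.add.at(grad, lay.lth[g], w * np.diag(Gm) * th)
        for k in range(lay.K):
            i, j = lay.pairs[k]
            grad[lay.psi[g, k]] += w * 2.0 * Gm[i, j]
        if g == 1 and lay.lphi >= 0:
            grad[lay.lphi] += w * (lam @ Gm @ lam) * phi
        if g == 1 and lay.kappa >= 0:
            grad[lay.kappa] += w * (lam @ h)
    return F, grad


def _start_values(lay: _Layout, spec, means, covs, weights):
    x0 = np.zeros(lay.n_free)
    Sp = sum(w * S for w, S in zip(weights, covs))
    evals, evecs = np.linalg.eigh(Sp)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6))
    if lam0.sum() < 0:
        lam0 = -lam0
    for g in range(lay.G):
        x0[lay.lam[g]] = lam0
        x0[lay.nu[g]] = means[g]
        x0[lay.lth[g]] = np.log(0.5 * np.clip(np.diag(covs[g]), 1e-8, None))
    return x0


def _baseline_chisq(means, covs, ns):
    """Independence model (diagonal Sigma, free means) — closed form."""
    chisq = 0.0
    p = covs[0].shape[0]
    for S, n in zip(covs, ns):
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample covariance not positive definite")
        chisq += n * (np.log(np.diag(S)).sum() - logdet)
    G = len(ns)
    df = G * (p * (p + 3) // 2) - G * 2 * p
    return float(chisq), int(df)


def fit_cfa_moments(spec: CFASpec, means, covs, ns,
                    max_restarts: int = 5) -> CFAFitResult:
    """Fit the CFA to per-group sample means/covariances (divisor n_g)."""
    G = len(means)
    if G != len(spec.groups):
        raise ValueError("number of moment sets must match spec.groups")
    lay = _Layout(spec)
    p = lay.p
    means = [np.asarray(m, dtype=float) for m in means]
    covs = [np.asarray(S, dtype=float) for S in covs]
    ns = [int(n) for n in ns]
    N = sum(ns)
    weights = [n / N for n in ns]
    logdet_s = []
    for S in covs:
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample covariance matrix not positive definite")
        logdet_s.append(ld)

    x0 = _start_values(lay, spec, means, covs, weights)
    fun = lambda x: _discrepancy(x, lay, means, covs, weights, logdet_s)
    best = None
    rng = np.random.default_rng(123457)
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.05, lay.n_free)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # BFGS precision-loss chatter
            res = optimize.minimize(fun, start, jac=True, method="BFGS",
                                    options=dict(maxiter=3000, gtol=1e-8))
        ok = np.isfinite(res.fun) and np.max(np.abs(res.jac)) < 1e-5
        if best is None or (np.isfinite(res.fun) and res.fun < best[0].fun):
            best = (res, ok)
        if ok:
            best = (res, True)
            break
    res, converged = best

    x = res.x
    chisq = max(float(N * res.fun), 0.0) if np.isfinite(res.fun) else np.inf
    moments = G * (p * (p + 3) // 2)
    df = moments - lay.n_free
    loglik_sat = sum(-0.5 * n * (ld + p + p * np.log(2 * np.pi))
                     for n, ld in zip(ns, logdet_s))
    loglik = loglik_sat - chisq / 2.0

    pairs = list(spec.residual_pairs)
    params = CFAParameters(
        loadings={g: x[lay.lam[gi]].copy()
                  for gi, g in enumerate(spec.groups)},
        intercepts={g: x[lay.nu[gi]].copy()
                    for gi, g in enumerate(spec.groups)},
        residual_var={g: np.exp(x[lay.lth[gi]])
                      for gi, g in enumerate(spec.groups)},
        residual_cov={g: {pairs[k]: float(x[lay.psi[gi, k]])
                          for k in range(lay.K)}
                      for gi, g in enumerate(spec.groups)},
        latent_var={g: (float(np.exp(x[lay.lphi]))
                        if gi == 1 and lay.lphi >= 0 else 1.0)
                    for gi, g in enumerate(spec.groups)},
        latent_mean={g: (float(x[lay.kappa])
                         if gi == 1 and lay.kappa >= 0 else 0.0)
                     for gi, g in enumerate(spec.groups)},
    )
    b_chisq, b_df = _baseline_chisq(means, covs, ns)
    fit = CFAFitResult(spec=spec, parameters=params, chisq=chisq, df=df,
                       fit_indices=(np.nan, np.nan, np.nan),
                       converged=bool(converged),
                       n_per_group=dict(zip(spec.groups, ns)),
                       loglik=float(loglik), baseline_chisq=b_chisq,
                       baseline_df=b_df, _layout=lay, _x=x,
                       _moments=(means, covs, ns, weights, logdet_s))
    fit.fit_indices = fit_indices(fit)
    return fit


def group_moments(cohort: CohortTable, indicators, groups):
    """Per-group mean vectors and covariance matrices (divisor n_g) of the
    z-scored log10 indicator columns."""
    cols = [f"zlog10_{r}" for r in indicators]
    means, covs, ns = [], [], []
    for g in groups:
        sub = cohort.group_frame(g)[cols].dropna()
        X = sub.to_numpy(dtype=float)
        n = X.shape[0]
        if n < 3:
            raise ValueError(f"group {g!r} has too few complete cases")
        m = X.mean(axis=0)
        S = (X - m).T @ (X - m) / n
        means.append(m)
        covs.append(S)
        ns.append(n)
    return means, covs, ns


def fit_cfa(spec: CFASpec, cohort: CohortTable, **kw) -> CFAFitResult:
    """Fit the CFA to the z-scored log10 indicators of a cohort table."""
    if not cohort.has_derived:
        raise ValueError("compute_derived must be called before fit_cfa")
    means, covs, ns = group_moments(cohort, spec.indicators, spec.groups)
    lay = _Layout(spec)
    for n in ns:
        if n <= lay.n_free / len(spec.groups):
            warnings.warn("group size does not exceed the per-group free "
                          "parameter count; estimates may be unstable")
    return fit_cfa_moments(spec, means, covs, ns, **kw)


# --------------------------------------------------------------------------
# fit indices and difference tests


def fit_indices(fit: CFAFitResult, baseline=None):
    """(CFI, TLI, RMSEA) from the model and independence-baseline chi-squares.

    RMSEA uses the multi-group convention sqrt(G) * sqrt(max(chi2-df,0)/(df*N)).
    TLI is capped at 1.
    """
    if baseline is not None:
        chisq_b, df_b = baseline.chisq, baseline.df
    else:
        chisq_b, df_b = fit.baseline_chisq, fit.baseline_df
    chisq, df, N = fit.chisq, fit.df, fit.N
    G = len(fit.spec.groups)
    excess = max(chisq - df, 0.0)
    excess_b = max(chisq_b - df_b, 0.0)
    denom = max(excess_b, excess)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    if df == 0:
        fit.rmsea_flagged = True
        rmsea = 0.0
        tli = 1.0
    else:
        ratio_b = chisq_b / df_b
        tli = ((ratio_b - chisq / df) / (ratio_b - 1.0)
               if ratio_b != 1.0 else 1.0)
        tli = min(tli, 1.0)
        rmsea = np.sqrt(G) * np.sqrt(excess / (df * N))
    return (float(cfi), float(tli), float(rmsea))


def chisq_diff_test(restricted: CFAFitResult, free: CFAFitResult,
                    level: str = "global_metric",
                    target=None) -> InvarianceTestResult:
    """Chi-square difference test between nested fits on identical data."""
    if restricted.n_per_group != free.n_per_group:
        raise ValueError("fits are not on identical data")
    if not restricted.spec.is_nested_in(free.spec):
        raise ValueError("specs are not nested")
    if restricted.df < free.df:
        raise ValueError("restricted model must not have fewer df than the "
                         "free model")
    delta = restricted.chisq - free.chisq
    if delta < 0:
        if delta < -1e-4:
            warnings.warn(f"negative delta chi-square ({delta:.3g}) floored "
                          "at 0 (optimizer noise)")
        delta = 0.0
    ddf = restricted.df - free.df
    p = float(stats.chi2.sf(delta, ddf)) if (delta > 0 and ddf > 0) else 1.0
    d_cfi = restricted.fit_indices[0] - free.fit_indices[0]
    d_rmsea = restricted.fit_indices[2] - free.fit_indices[2]
    return InvarianceTestResult(
        level=level, target=target, delta_chisq=float(delta), delta_df=int(ddf),
        p_value=p, delta_cfi=float(d_cfi), delta_rmsea=float(d_rmsea),
        chen_flags=(abs(d_cfi) > 0.005, abs(d_rmsea) >= 0.010),
        restricted=restricted, free=free)


def _group_param_gap(fit: CFAFitResult, target: str, kind: str) -> float:
    """Reference-group minus second-group value of a freed loading/intercept."""
    i = fit.spec.indicators.index(target)
    g0, g1 = fit.spec.groups
    table = (fit.parameters.loadings if kind == "loading"
             else fit.parameters.intercepts)
    return float(table[g0][i] - table[g1][i])


def invariance_cascade(cohort: CohortTable, spec: CFASpec,
                       alpha_global: float = 0.05,
                       alpha_regional: float | None = None) -> CascadeResult:
    """Configural -> global metric -> regional metric -> global scalar ->
    regional scalar, with regional tests gated on the global rejection.

    ``alpha_regional`` defaults to alpha_global-level Bonferroni over the
    indicator count (0.05 / p).  Regional loadings rejected at the metric
    stage remain free (partial invariance) in the scalar models.
    """
    p_ind = len(spec.indicators)
    if alpha_regional is None:
        alpha_regional = 0.05 / p_ind
    base = replace(spec, loadings_equal=False, intercepts_equal=False,
                   free_loadings=frozenset(), free_intercepts=frozenset(),
                   latent_mean_free=False)
    tests, fits = [], {}

    def _fit(name, s):
        f = fit_cfa(s, cohort)
        fits[name] = f
        if not f.converged:
            raise _NonConvergence(name)
        return f

    try:
        configural = _fit("configural", base)
        metric = _fit("metric", replace(base, loadings_equal=True))
        g_metric = chisq_diff_test(metric, configural, "global_metric")
        g_metric.significant = g_metric.p_value < alpha_global
        tests.append(g_metric)

        rejected_loadings = set()
        if g_metric.significant:
            for ind in spec.indicators:
                freed = _fit(f"metric_free_{ind}",
                             replace(base, loadings_equal=True,
                                     free_loadings=frozenset({ind})))
                t = chisq_diff_test(metric, freed, "regional_metric", ind)
                t.significant = t.p_value < alpha_regional
                t.standardized_group_difference = _group_param_gap(
                    freed, ind, "loading")
                tests.append(t)
                if t.significant:
                    rejected_loadings.add(ind)

        part = frozenset(rejected_loadings)
        metric_part = (metric if not part else
                       _fit("metric_partial",
                            replace(base, loadings_equal=True,
                                    free_loadings=part)))
        scalar = _fit("scalar", replace(base, loadings_equal=True,
                                        intercepts_equal=True,
                                        free_loadings=part))
        g_scalar = chisq_diff_test(scalar, metric_part, "global_scalar")
        g_scalar.significant = g_scalar.p_value < alpha_global
        tests.append(g_scalar)

        if g_scalar.significant:
            for ind in spec.indicators:
                freed = _fit(f"scalar_free_{ind}",
                             replace(base, loadings_equal=True,
                                     intercepts_equal=True,
                                     free_loadings=part,
                                     free_intercepts=frozenset({ind})))
                t = chisq_diff_test(scalar, freed, "regional_scalar", ind)
                t.significant = t.p_value < alpha_regional
                t.standardized_group_difference = _group_param_gap(
                    freed, ind, "intercept")
                tests.append(t)
    except _NonConvergence as exc:
        return CascadeResult(tests, fits, status=f"halted: {exc} did not "
                                                 "converge")
    return CascadeResult(tests, fits)


class _NonConvergence(Exception):
    pass


def regional_metric_tests(cohort: CohortTable, spec: CFASpec,
                          alpha_regional: float | None = None) -> list:
    """Regional metric tests for every indicator, without the global gate.

    Used for localization/power experiments: the fully loading-constrained
    model is compared against each one-loading-freed model in turn.
    """
    if alpha_regional is None:
        alpha_regional = 0.05 / len(spec.indicators)
    base = replace(spec, loadings_equal=False, intercepts_equal=False,
                   free_loadings=frozenset(), free_intercepts=frozenset(),
                   latent_mean_free=False)
    metric = fit_cfa(replace(base, loadings_equal=True), cohort)
    tests = []
    for ind in spec.indicators:
        freed = fit_cfa(replace(base, loadings_equal=True,
                                free_loadings=frozenset({ind})), cohort)
        t = chisq_diff_test(metric, freed, "regional_metric", ind)
        t.significant = t.p_value < alpha_regional
        t.standardized_group_difference = _group_param_gap(freed, ind,
                                                           "loading")
        tests.append(t)
    return tests


# --------------------------------------------------------------------------
# latent group difference


def parameter_covariance(fit: CFAFitResult) -> np.ndarray:
    """Asymptotic covariance of the free parameters: (2/N) * H(F)^-1 with the
    Hessian of the discrepancy obtained by finite differences of the
    analytic gradient."""
    lay, x = fit._layout, fit._x
    means, covs, ns, weights, logdet_s = fit._moments
    n = lay.n_free
    H = np.zeros((n, n))
    eps = 1e-5
    for j in range(n):
        xp = x.copy(); xp[j] += eps
        xm = x.copy(); xm[j] -= eps
        _, gp = _discrepancy(xp, lay, means, covs, weights, logdet_s)
        _, gm = _discrepancy(xm, lay, means, covs, weights, logdet_s)
        H[:, j] = (gp - gm) / (2 * eps)
    H = 0.5 * (H + H.T)
    N = sum(ns)
    return (2.0 / N) * np.linalg.pinv(H)


def latent_group_difference(fit: CFAFitResult):
    """Standardized latent mean difference (second group minus reference, in
    reference-group latent SD units) with a delta-method SE and Wald p."""
    lay = fit._layout
    if lay is None or lay.kappa < 0:
        raise IdentificationError(
            "latent mean difference requires a fit with latent_mean_free=True "
            "(and intercepts_equal=True for identification)")
    effect = float(fit._x[lay.kappa])
    cov = parameter_covariance(fit)
    se = float(np.sqrt(max(cov[lay.kappa, lay.kappa], 0.0)))
    z = effect / se if se > 0 else np.inf
    return effect, se, float(2 * stats.norm.sf(abs(z)))
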