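"""Synthetic multi-site cohort generator with known allometric ground truth.

Emulates the structure of a two-group (control vs ASD) structural-MRI cohort:
~350 controls and ~300 ASD subjects spread over 17 scanner sites, a
left-skewed age distribution on 6-27 years, FSIQ restricted to 70-130 with a
group-specific FSIQ-TBV correlation (stronger in controls), male-dominated
sex ratios, and 22 regional volumes generated from per-group power laws

    log10(V_i) = intercept_i,g + alpha_i,g * log10(TBV) + site + eps_i,

with hyperallometric white matter, isometric cortex, and hypoallometric
subcortical structures.  Residuals of homologous left/right regions are
correlated.  Total gray matter is defined as TBV minus cerebral white matter
so the identity TBV = GM + WM holds exactly by construction.

The generator records the realized ground truth (per-region slopes and
intercepts per group, site intercepts, injected outliers) so downstream
estimators can be validated by parameter recovery.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import regions as _regions
from .cohort import CohortTable, OPTIONAL_PHENOTYPES, REQUIRED_PHENOTYPES


class ConfigError(ValueError):
    """The generator configuration is invalid (e.g. non-PD residual cov)."""


@dataclass
class RegionParams:
    alpha_control: float
    alpha_asd: float
    intercept_control: float
    intercept_asd: float
    residual_sd: float


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_per_group: tuple[int, int] = (352, 302)       # (control, asd)
    n_sites: int = 17
    site_sd: float = 0.01                            # SD of site intercepts, log10
    sex_ratio: tuple[float, float] = (0.804, 0.877)  # fraction male (control, asd)
    age_range: tuple[float, float] = (6.0, 27.0)
    age_beta: tuple[float, float] = (1.62, 2.38)     # left-skewed, mean ~14.5
    fsiq_mean: tuple[float, float] = (109.75, 102.18)
    fsiq_sd: tuple[float, float] = (11.05, 14.37)
    fsiq_bounds: tuple[float, float] = (70.0, 130.0)
    fsiq_tbv_corr: tuple[float, float] = (0.31, 0.08)
    tbv_log10_mean: dict = field(default_factory=lambda: {"male": 6.09,
                                                          "female": 6.03})
    tbv_log10_sd: float = 0.04
    tbv_group_shift: float = 0.0                     # log10 offset for ASD
    regions: dict = field(default_factory=dict)      # name -> RegionParams
    residual_corr_pairs: list = field(default_factory=list)  # (a, b, r)
    outlier_rate: float = 0.0
    comorbidity_rate: tuple[float, float] = (0.0085, 0.109)
    medication_rate: tuple[float, float] = (0.02, 0.25)
    ados_mean: float = 11.85
    ados_sd: float = 3.76
    ados_bounds: tuple[int, int] = (2, 21)
    ados_missing_rate: float = 0.28
    seed: int = 0

    def validate(self):
        if self.site_sd < 0 or self.tbv_log10_sd < 0:
            raise ConfigError("SDs must be non-negative")
        for f in (*self.sex_ratio, self.outlier_rate, *self.comorbidity_rate,
                  *self.medication_rate, self.ados_missing_rate):
            if not 0.0 <= f <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        for r in (*self.fsiq_tbv_corr, *(c for _, _, c in self.residual_corr_pairs)):
            if not -1.0 < r < 1.0:
                raise ConfigError("correlations must lie in (-1, 1)")
        for rp in self.regions.values():
            if rp.residual_sd < 0:
                raise ConfigError("residual_sd must be non-negative")

    @property
    def region_names(self) -> list[str]:
        return list(self.regions)


@dataclass
class GroundTruth:
    """Realized generative parameters of one cohort draw."""

    alphas: dict            # group -> {region: slope}
    intercepts: dict        # group -> {region: log10 intercept}
    site_effects: dict      # site label -> log10 intercept
    outliers: list          # (subject_id, region, factor)
    config: GeneratorConfig

    def to_json(self, path):
        payload = {
            "alphas": self.alphas,
            "intercepts": self.intercepts,
            "site_effects": self.site_effects,
            "outliers": [list(o) for o in self.outliers],
            "config": _config_dict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _config_dict(config):
    d = dataclasses.asdict(config)
    d["regions"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                    else v for k, v in d["regions"].items()}
    return d


def default_config(seed: int = 0) -> GeneratorConfig:
    """Null configuration: identical allometry in both groups, no TBV shift.

    Sample sizes (352 controls, 302 ASD over 17 sites), FSIQ-TBV correlations
    (0.31 control, 0.08 ASD), and the scaling pattern (white matter
    hyperallometric at 1.15, cortex isometric at 1.00, subcortical regions
    hypoallometric in [0.55, 0.90]) follow the cohort the generator emulates.
    """
    cfg = GeneratorConfig(seed=seed)
    cfg.regions = {
        r.name: RegionParams(r.alpha, r.alpha, r.intercept, r.intercept,
                             r.residual_sd)
        for r in _regions.REGIONS
    }
    cfg.residual_corr_pairs = [(a, b, 0.3) for a, b in _regions.HOMOLOGOUS_PAIRS]
    return cfg


def inject_group_difference(config: GeneratorConfig, region: str,
                            delta_alpha: float = 0.0,
                            delta_intercept: float = 0.0,
                            anchor_log10_tbv: float | None = None) -> GeneratorConfig:
    """Return a copy with the ASD slope/intercept of ``region`` shifted.

    With ``anchor_log10_tbv`` set, a slope shift pivots around that log10 TBV
    value (the ASD intercept absorbs -delta_alpha * anchor), so the expected
    volume at the anchor is unchanged — a pure scaling-relationship gap.
    Without it the parameter shifts are applied verbatim.
    """
    if region not in config.regions:
        raise KeyError(f"unknown region: {region!r}")
    cfg = copy.deepcopy(config)
    rp = cfg.regions[region]
    rp.alpha_asd = rp.alpha_asd + delta_alpha
    rp.intercept_asd = rp.intercept_asd + delta_intercept
    if anchor_log10_tbv is not None:
        rp.intercept_asd = rp.intercept_asd - delta_alpha * anchor_log10_tbv
    return cfg


def log10_volume_sd(config: GeneratorConfig, region: str,
                    group: str = "control") -> float:
    """Marginal SD of log10(volume) implied by the generative model
    (single-sex cohort; site variance included)."""
    rp = config.regions[region]
    alpha = rp.alpha_control if group == "control" else rp.alpha_asd
    return float(np.sqrt((alpha * config.tbv_log10_sd) ** 2
                         + rp.residual_sd ** 2 + config.site_sd ** 2))


def delta_alpha_for_standardized_gap(config: GeneratorConfig, region: str,
                                     gap: float) -> float:
    """Raw slope shift giving a standardized (z-scale) slope gap of ``gap``.

    The standardized group-by-log10(TBV) coefficient is approximately
    delta_alpha * SD(log10 TBV) / SD(log10 V); valid for single-sex cohorts.
    """
    sd_v = log10_volume_sd(config, region, "control")
    return gap * sd_v / config.tbv_log10_sd


def _residual_cholesky(config):
    names = config.region_names
    k = len(names)
    sds = np.array([config.regions[r].residual_sd for r in names])
    cov = np.diag(sds ** 2)
    pos = {n: i for i, n in enumerate(names)}
    for a, b, r in config.residual_corr_pairs:
        if a in pos and b in pos:
            i, j = pos[a], pos[b]
            cov[i, j] = cov[j, i] = r * sds[i] * sds[j]
    # zero-variance rows are permitted (noiseless generative checks)
    nz = sds > 0
    L = np.zeros((k, k))
    if nz.any():
        try:
            L[np.ix_(nz, nz)] = np.linalg.cholesky(cov[np.ix_(nz, nz)])
        except np.linalg.LinAlgError as exc:
            raise ConfigError("residual covariance not positive definite") from exc
    return L


def _truncnorm_ppf(u, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _trunc_attenuation(mean, sd, lo, hi):
    """corr(F^-1(Phi(Z)), Z) for the truncated-normal FSIQ marginal.

    The copula transform attenuates the Pearson correlation below the latent
    Gaussian correlation; the latent value is inflated by 1/attenuation so
    the configured correlation is realized on the observed scale.
    """
    z = np.linspace(-8.0, 8.0, 4001)
    w = stats.norm.pdf(z)
    w = w / w.sum()
    f = _truncnorm_ppf(stats.norm.cdf(z), mean, sd, lo, hi)
    mf = float((f * w).sum())
    vf = float((((f - mf) ** 2) * w).sum())
    cov = float(((f - mf) * z * w).sum())
    return cov / np.sqrt(vf)


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort.  Same config + seed gives bit-identical output."""
    config.validate()
    names = config.region_names
    if "cerebral_white_matter" not in names:
        raise ConfigError("regions must include cerebral_white_matter")
    wm_ix = names.index("cerebral_white_matter")
    L = _residual_cholesky(config)
    rng = np.random.default_rng(config.seed)

    site_labels = [f"site{i + 1:02d}" for i in range(config.n_sites)]
    site_probs = rng.dirichlet(np.full(config.n_sites, 4.0))
    site_eff = rng.normal(0.0, config.site_sd, config.n_sites) \
        if config.site_sd > 0 else np.zeros(config.n_sites)

    frames = []
    truth_alphas, truth_icpts = {}, {}
    sid = 0
    for gi, group in enumerate(("control", "asd")):
        n = config.n_per_group[0 if group == "control" else 1]
        alphas = np.array([config.regions[r].alpha_control if gi == 0
                           else config.regions[r].alpha_asd for r in names])
        icpts = np.array([config.regions[r].intercept_control if gi == 0
                          else config.regions[r].intercept_asd for r in names])
        truth_alphas[group] = dict(zip(names, alphas.tolist()))
        truth_icpts[group] = dict(zip(names, icpts.tolist()))

        site_ix = rng.choice(config.n_sites, size=n, p=site_probs)
        male = rng.random(n) < config.sex_ratio[gi]
        a, b = config.age_beta
        lo, hi = config.age_range
        age = lo + (hi - lo) * rng.beta(a, b, n)

        atten = _trunc_attenuation(config.fsiq_mean[gi], config.fsiq_sd[gi],
                                   *config.fsiq_bounds)
        # sex-mixture TBV variance also dilutes the observed correlation
        p_m = config.sex_ratio[gi]
        d_mu = config.tbv_log10_mean["male"] - config.tbv_log10_mean["female"]
        sd2 = config.tbv_log10_sd ** 2
        mix = np.sqrt((sd2 + p_m * (1 - p_m) * d_mu ** 2) / sd2) \
            if sd2 > 0 else 1.0
        r_ft = float(np.clip(config.fsiq_tbv_corr[gi] * mix / atten,
                             -0.99, 0.99))
        z = rng.multivariate_normal([0.0, 0.0],
                                    [[1.0, r_ft], [r_ft, 1.0]], size=n)
        fsiq = _truncnorm_ppf(stats.norm.cdf(z[:, 0]), config.fsiq_mean[gi],
                              config.fsiq_sd[gi], *config.fsiq_bounds)
        mu_t = np.where(male, config.tbv_log10_mean["male"],
                        config.tbv_log10_mean["female"])
        if group == "asd":
            mu_t = mu_t + config.tbv_group_shift
        log_tbv = mu_t + config.tbv_log10_sd * z[:, 1]

        eps = rng.standard_normal((n, len(names))) @ L.T
        log_v = icpts + np.outer(log_tbv, alphas) + site_eff[site_ix][:, None] + eps
        vols = 10.0 ** log_v
        tbv = 10.0 ** log_tbv
        gm = tbv - vols[:, wm_ix]
        if not (gm > 0).all():
            raise ConfigError("generated white matter exceeds TBV; check "
                              "white-matter intercept/slope settings")

        medication = rng.random(n) < config.medication_rate[gi]
        comorbidity = rng.random(n) < config.comorbidity_rate[gi]
        if group == "asd":
            ados = np.clip(np.rint(rng.normal(config.ados_mean, config.ados_sd,
                                              n)),
                           *config.ados_bounds)
            ados[rng.random(n) < config.ados_missing_rate] = np.nan
        else:
            ados = np.full(n, np.nan)

        frame = pd.DataFrame({
            "subject_id": [f"sub{sid + i + 1:05d}" for i in range(n)],
            "site": [site_labels[i] for i in site_ix],
            "group": group,
            "sex": np.where(male, "male", "female"),
            "age": age,
            "fsiq": fsiq,
            "medication": medication,
            "comorbidity": comorbidity,
            "ados_total": ados,
        })
        for j, r in enumerate(names):
            frame[r] = vols[:, j]
        frame["total_gray_matter"] = gm
        frames.append(frame)
        sid += n

    df = pd.concat(frames, ignore_index=True)

    outliers = []
    n_out = int(round(config.outlier_rate * len(df)))
    if n_out:
        subj_ix = rng.choice(len(df), size=n_out, replace=False)
        reg_ix = rng.integers(0, len(names), size=n_out)
        factors = rng.choice([0.5, 2.0], size=n_out)
        for i, j, f in zip(subj_ix, reg_ix, factors):
            r = names[j]
            df.loc[i, r] = df.loc[i, r] * f
            if r == "cerebral_white_matter":
                # keep the TBV identity: GM absorbs the WM perturbation
                tbv_i = df.loc[i, "total_gray_matter"] + df.loc[i, r] / f
                gm_new = tbv_i - df.loc[i, r]
                if gm_new <= 0:
                    df.loc[i, r] = df.loc[i, r] / f   # undo, keep valid
                    continue
                df.loc[i, "total_gray_matter"] = gm_new
            outliers.append((df.loc[i, "subject_id"], r, float(f)))

    all_regions = names + ["total_gray_matter"]
    cohort = CohortTable(df[REQUIRED_PHENOTYPES + OPTIONAL_PHENOTYPES
                            + all_regions].copy(), all_regions)
    truth = GroundTruth(truth_alphas, truth_icpts,
                        dict(zip(site_labels, site_eff.tolist())),
                        outliers, copy.deepcopy(config))
    return cohort, truth
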