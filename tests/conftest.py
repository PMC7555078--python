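"""Shared fixtures: synthetic cohorts and small indicator sets."""

import numpy as np
import pandas as pd
import pytest

from neuroallometry import (compute_derived, default_config, flag_outliers,
                            generate_cohort)
from neuroallometry.cohort import CohortTable

#: five left-hemisphere / midline regions without cross-region residual
#: correlation — a correctly specified diagonal-residual one-factor set
UNPAIRED5 = ("brain_stem", "left_hippocampus", "left_amygdala",
             "left_caudate", "left_thalamus")

PAIRED8 = ("cerebral_white_matter", "brain_stem",
           "left_hippocampus", "right_hippocampus",
           "left_thalamus", "right_thalamus",
           "left_caudate", "right_caudate")
PAIRED8_PAIRS = (("right_hippocampus", "left_hippocampus"),
                 ("right_thalamus", "left_thalamus"),
                 ("right_caudate", "left_caudate"))


@pytest.fixture(scope="session")
def null_cohort():
    """Default-condition cohort (352 controls / 302 ASD, 17 sites)."""
    cohort, truth = generate_cohort(default_config(seed=11))
    cohort = flag_outliers(compute_derived(cohort))
    return cohort, truth


@pytest.fixture(scope="session")
def clean_config():
    """Single-sex, site-free null config for calibration experiments."""
    cfg = default_config(seed=0)
    cfg.sex_ratio = (1.0, 1.0)
    cfg.site_sd = 0.0
    return cfg


def make_toy_cohort(n=12, slope=1.0, intercept=-2.9, noise=0.0, seed=0,
                    region="left_hippocampus", group="control"):
    """Hand-built cohort whose `region` lies on an exact log-log line."""
    rng = np.random.default_rng(seed)
    log_tbv = np.linspace(5.9, 6.3, n)
    log_v = intercept + slope * log_tbv + noise * rng.standard_normal(n)
    tbv = 10.0 ** log_tbv
    wm = 0.4 * tbv
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "site": "siteA",
        "group": group,
        "sex": "male",
        "age": np.linspace(8, 20, n),
        "fsiq": np.linspace(90, 120, n),
        "medication": False,
        "comorbidity": False,
        "ados_total": np.nan,
        region: 10.0 ** log_v,
        "cerebral_white_matter": wm,
        "total_gray_matter": tbv - wm,
    })
    return CohortTable(df, [region, "cerebral_white_matter",
                            "total_gray_matter"])
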