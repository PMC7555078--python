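"""Per-subject cohort table: I/O, validation, filters, derived columns, outliers.

The cohort table is the single data model shared by every analysis stage.  It
wraps a pandas DataFrame with one row per subject: phenotypes (site, group,
sex, age, FSIQ, medication, comorbidity, optional ADOS total) and regional
volumes in mm^3.  Derived columns added by :func:`compute_derived` are TBV
(total gray + cerebral white matter), log10 volumes, and z-scored log10
volumes; :func:`flag_outliers` adds per-region boolean outlier flags based on
studentized residuals from the within-group log-log regression on TBV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import FREESURFER_ALIASES


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """A value violates the data model (e.g. non-positive volume)."""


class StandardizationError(ValueError):
    """A column cannot be z-scored (zero variance)."""


REQUIRED_PHENOTYPES = ["subject_id", "site", "group", "sex", "age", "fsiq",
                       "medication", "comorbidity"]
OPTIONAL_PHENOTYPES = ["ados_total"]

_GROUP_MAP = {"control": "control", "ctrl": "control", "td": "control",
              "hc": "control", "typically developing": "control", "1": "control",
              "asd": "asd", "autism": "asd", "aut": "asd", "2": "asd"}
_SEX_MAP = {"male": "male", "m": "male", "1": "male",
            "female": "female", "f": "female", "2": "female"}
_BOOL_MAP = {"true": True, "yes": True, "y": True, "1": True, "1.0": True,
             "false": False, "no": False, "n": False, "0": False, "0.0": False}


@dataclass
class CohortTable:
    """Ordered collection of subject records plus derived columns.

    Invariants: no duplicate subject ids, all volumes strictly positive,
    TBV == total_gray_matter + cerebral_white_matter after
    :func:`compute_derived`, z-scored columns have mean 0 / SD 1.
    """

    df: pd.DataFrame
    regions: list[str]
    exclusion_log: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        self._validate()

    def _validate(self):
        for col in REQUIRED_PHENOTYPES:
            if col not in self.df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        missing = [r for r in self.regions if r not in self.df.columns]
        if missing:
            raise SchemaError(f"missing region columns: {missing}")
        if self.df["subject_id"].duplicated().any():
            dups = self.df.loc[self.df["subject_id"].duplicated(), "subject_id"]
            raise ValidationError(f"duplicate subject_id: {sorted(set(dups))}")
        vols = self.df[self.regions].to_numpy(dtype=float)
        bad = ~(vols > 0) | ~np.isfinite(vols)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            sid = self.df["subject_id"].iloc[i]
            raise ValidationError(
                f"non-positive or non-finite volume {self.regions[j]!r} "
                f"for subject {sid!r}")
        for col in ("age", "fsiq"):
            if not np.isfinite(self.df[col].to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite values in {col!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_derived(self) -> bool:
        return "tbv" in self.df.columns

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), list(self.regions),
                           list(self.exclusion_log))

    def subset(self, mask) -> "CohortTable":
        """Row-subset sharing the exclusion log (derived columns retained)."""
        return CohortTable(self.df.loc[mask].reset_index(drop=True),
                           list(self.regions), list(self.exclusion_log))

    def group_frame(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == group]


def _normalize_cat(series: pd.Series, mapping: dict, col: str) -> pd.Series:
    def conv(v):
        key = str(v).strip().lower()
        if key not in mapping:
            raise ValidationError(f"unrecognized {col} label: {v!r}")
        return mapping[key]
    return series.map(conv)


def _normalize_bool(series: pd.Series, col: str) -> pd.Series:
    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        key = str(v).strip().lower()
        if key not in _BOOL_MAP:
            raise ValidationError(f"unrecognized boolean {col} value: {v!r}")
        return _BOOL_MAP[key]
    return series.map(conv)


def read_cohort(path, region_list, alias_map=None, units="mm3") -> CohortTable:
    """Read a per-subject CSV/TSV volume table.

    ``alias_map`` maps file column names to canonical region names (the
    FreeSurfer aseg conventions are understood by default).  ``units`` may be
    "mm3" or "cm3"; cm^3 volumes are converted to mm^3 (x1000).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not region_list:
        raise ValueError("region_list must be non-empty")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    aliases = dict(FREESURFER_ALIASES)
    if alias_map:
        aliases.update(alias_map)
    df = df.rename(columns={c: aliases[c] for c in df.columns if c in aliases})
    for col in REQUIRED_PHENOTYPES:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df["group"] = _normalize_cat(df["group"], _GROUP_MAP, "group")
    df["sex"] = _normalize_cat(df["sex"], _SEX_MAP, "sex")
    df["medication"] = _normalize_bool(df["medication"], "medication")
    df["comorbidity"] = _normalize_bool(df["comorbidity"], "comorbidity")
    df["subject_id"] = df["subject_id"].astype(str)
    df["site"] = df["site"].astype(str)
    if "ados_total" not in df.columns:
        df["ados_total"] = np.nan
    if units == "cm3":
        for r in region_list:
            if r in df.columns:
                df[r] = df[r] * 1000.0
    elif units != "mm3":
        raise ValueError(f"unknown units: {units!r}")
    return CohortTable(df, list(region_list))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the raw (non-derived) columns in the dialect read_cohort reads."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = REQUIRED_PHENOTYPES + OPTIONAL_PHENOTYPES + list(cohort.regions)
    cohort.df[cols].to_csv(path, sep=sep, index=False)


def write_exclusion_log(cohort: CohortTable, path) -> None:
    pd.DataFrame(cohort.exclusion_log,
                 columns=["subject_id", "rule", "value"]
                 ).to_csv(path, sep="\t", index=False)


def apply_inclusion_filters(cohort: CohortTable, age_max: float = 27.0,
                            fsiq_min: float = 70.0,
                            fsiq_max: float = 130.0) -> CohortTable:
    """Retain subjects with age <= age_max and fsiq_min <= FSIQ <= fsiq_max.

    Bounds are inclusive; every excluded subject is logged once with the
    triggering rule ("age" takes precedence if both are violated).
    """
    for v in (age_max, fsiq_min, fsiq_max):
        if not np.isfinite(v):
            raise ValueError("filter thresholds must be finite")
    df = cohort.df
    age_bad = df["age"] > age_max
    fsiq_bad = (df["fsiq"] < fsiq_min) | (df["fsiq"] > fsiq_max)
    keep = ~(age_bad | fsiq_bad)
    log = list(cohort.exclusion_log)
    for _, row in df.loc[~keep].iterrows():
        if row["age"] > age_max:
            log.append((row["subject_id"], "age", float(row["age"])))
        else:
            log.append((row["subject_id"], "fsiq", float(row["fsiq"])))
    if keep.sum() == 0:
        warnings.warn("inclusion filters removed every subject")
    return CohortTable(df.loc[keep].reset_index(drop=True),
                       list(cohort.regions), log)


def compute_derived(cohort: CohortTable) -> CohortTable:
    """Add TBV, log10 volumes, and z-scored log10 volumes.

    TBV is the sum of total gray matter and cerebral white matter.  z-scores
    use the sample SD (ddof=1) over the current table.
    """
    for col in ("total_gray_matter", "cerebral_white_matter"):
        if col not in cohort.df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df = cohort.df.copy()
    df["tbv"] = df["total_gray_matter"] + df["cerebral_white_matter"]
    for r in list(cohort.regions) + ["tbv"]:
        x = df[r].to_numpy(dtype=float)
        if not (x > 0).all():
            bad = df["subject_id"].iloc[int(np.argmax(~(x > 0)))]
            raise ValidationError(
                f"log10 undefined: non-positive {r!r} for subject {bad!r}")
        lx = np.log10(x)
        df[f"log10_{r}"] = lx
        sd = lx.std(ddof=1) if len(lx) > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            raise StandardizationError(f"zero-variance column: log10_{r}")
        df[f"zlog10_{r}"] = (lx - lx.mean()) / sd
    return CohortTable(df, list(cohort.regions), list(cohort.exclusion_log))


def flag_outliers(cohort: CohortTable, threshold: float = 3.0) -> CohortTable:
    """Flag subjects whose studentized residual from the within-group
    regression of z-scored log10(volume) on z-scored log10(TBV) exceeds
    ``threshold`` in absolute value.  Flags are stored as ``out_<region>``
    boolean columns; no record is removed.  Groups with fewer than 10
    subjects are skipped with a warning (insufficient residual df).
    """
    if not cohort.has_derived:
        raise ValueError("compute_derived must be called before flag_outliers")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    df = cohort.df.copy()
    zt_all = df["zlog10_tbv"].to_numpy(dtype=float)
    for r in cohort.regions:
        flags = np.zeros(len(df), dtype=bool)
        for g in df["group"].unique():
            idx = np.flatnonzero((df["group"] == g).to_numpy())
            n = len(idx)
            if n < 10:
                warnings.warn(
                    f"group {g!r} has {n} records; outlier flagging skipped")
                continue
            if np.isinf(threshold):
                continue
            y = df[f"zlog10_{r}"].to_numpy(dtype=float)[idx]
            X = np.column_stack([np.ones(n), zt_all[idx]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            # hat diagonal for the two-column design
            Q, _ = np.linalg.qr(X)
            h = np.einsum("ij,ij->i", Q, Q)
            s2 = resid @ resid / (n - 2)
            if s2 < 1e-20:    # numerically exact fit: nothing to flag
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                stud = resid / np.sqrt(s2 * (1.0 - h))
            flags[idx] = np.abs(stud) > threshold
        df[f"out_{r}"] = flags
    return CohortTable(df, list(cohort.regions), list(cohort.exclusion_log))


def any_outlier_mask(cohort: CohortTable, regions=None) -> np.ndarray:
    """Boolean mask of subjects flagged in any of the given regions."""
    regions = list(regions) if regions is not None else list(cohort.regions)
    cols = [f"out_{r}" for r in regions if f"out_{r}" in cohort.df.columns]
    if not cols:
        return np.zeros(len(cohort.df), dtype=bool)
    return cohort.df[cols].to_numpy(dtype=bool).any(axis=1)
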