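"""Phenotype construction, cleaning and phenotypic correlations.

Cleaning rules for a registry-linked cohort with measured cardiometabolic
phenotypes: birthweight exclusions and Z-scoring, antihypertensive-use
adjustment of blood pressure, Friedewald LDL derivation, optional natural-log
transformation, and single-pass trimming of values beyond k standard
deviations from the mean. The fixed pipeline order is
BP adjustment -> derivations -> transform -> trim -> Z-score (birthweight).
"""

from __future__ import annotations

from collections import OrderedDict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

#: traits analysed on the natural-log scale (right-skewed distributions)
LOG_TRAITS = frozenset({"hdl", "triglycerides", "bmi", "glucose"})

BW_FLOOR_G = 1000.0
GESTATION_MIN_DAYS = 258
GESTATION_MAX_DAYS = 301
SBP_MEDICATION_OFFSET = 15.0
DBP_MEDICATION_OFFSET = 10.0
FRIEDEWALD_TG_MAX = 4.5  # mmol/L; formula invalid above this


def _as_bool(s: pd.Series) -> pd.Series:
    """Missing flags count as False (nullable-boolean safe)."""
    return s.astype("boolean").fillna(False).astype(bool)


def clean_birthweight(records: pd.DataFrame) -> tuple[pd.DataFrame, "OrderedDict[str, int]"]:
    """Apply birthweight exclusions and Z-score the survivors.

    Exclusions, applied sequentially so the log counts sum exactly to
    input - output: multiple births, congenital malformations, induced or
    Cesarean-section births, birthweight < 1000 g, gestation outside
    [258, 301] days. Adds a ``birthweight_z`` column.
    """
    df = records.copy()
    log: OrderedDict[str, int] = OrderedDict()
    steps = [
        ("multiple birth", lambda d: _as_bool(d["multiple_birth"])),
        ("congenital malformation",
         lambda d: _as_bool(d["congenital_malformation"])),
        ("induced or C-section", lambda d: _as_bool(d["induced_or_csection"])),
        ("low birthweight", lambda d: d["birthweight"] < BW_FLOOR_G),
        ("gestation out of window",
         lambda d: (d["gestational_age"] < GESTATION_MIN_DAYS)
         | (d["gestational_age"] > GESTATION_MAX_DAYS)),
    ]
    for reason, rule in steps:
        drop = rule(df)
        log[reason] = int(drop.sum())
        df = df.loc[~drop]
    if len(df) == 0:
        raise ValueError("all records excluded by birthweight cleaning")
    bw = df["birthweight"].astype(float)
    df = df.assign(birthweight_z=(bw - bw.mean()) / bw.std(ddof=1))
    return df.reset_index(drop=True), log


def adjust_bp(records: pd.DataFrame) -> pd.DataFrame:
    """Add 15 mmHg SBP / 10 mmHg DBP for medicated individuals.

    Records with a missing medication flag pass through unchanged; their
    count is stored in ``df.attrs['bp_flag_missing']``.
    """
    df = records.copy()
    flag = df["bp_medication"]
    missing = flag.isna()
    med = _as_bool(flag)
    df.loc[med, "sbp"] = df.loc[med, "sbp"] + SBP_MEDICATION_OFFSET
    df.loc[med, "dbp"] = df.loc[med, "dbp"] + DBP_MEDICATION_OFFSET
    df.attrs["bp_flag_missing"] = int(missing.sum())
    return df


def friedewald_ldl(tc, hdl, tg):
    """LDL = TC - HDL - TG / 2.2 (mmol/L); missing when TG >= 4.5 mmol/L."""
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    ldl = tc - hdl - tg / 2.2
    out = np.where(tg >= FRIEDEWALD_TG_MAX, np.nan, ldl)
    return out if out.ndim else float(out)


def transform_and_trim(values, log_transform: bool = False, k_sd: float = 4.0) -> pd.Series:
    """Optional natural log, then a single-pass removal of values more than
    ``k_sd`` standard deviations from the mean.

    The mean/SD are computed once on the (transformed) input; trimming is
    not iterated. Non-positive values under ``log_transform`` are excluded
    (count in ``result.attrs['nonpositive_excluded']``).
    """
    s = pd.Series(values, dtype=float).dropna()
    n_nonpos = 0
    if log_transform:
        pos = s > 0
        n_nonpos = int((~pos).sum())
        s = np.log(s[pos])
    mu, sd = s.mean(), s.std(ddof=1)
    out = s[(s - mu).abs() <= k_sd * sd] if sd > 0 else s
    out.attrs["nonpositive_excluded"] = n_nonpos
    out.attrs["trimmed"] = int(len(s) - len(out))
    return out


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int


def correlate(x, y, age=None, age_min: float | None = None) -> CorrelationResult:
    """Pearson correlation of paired complete cases, optionally restricted
    to individuals aged >= ``age_min``. Undefined (NaN) when n < 3."""
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    keep = x.notna() & y.notna()
    if age_min is not None:
        if age is None:
            raise ValueError("age values required when age_min is set")
        keep &= pd.Series(np.asarray(age, dtype=float)) >= age_min
    x, y = x[keep], y[keep]
    if len(x) < 3:
        return CorrelationResult(np.nan, np.nan, int(len(x)))
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(len(x)))


def correlation_table(bw, traits: dict, age=None, age_min=None) -> pd.DataFrame:
    """Birthweight-trait Pearson correlations, one row per trait
    (columns N, correlation coefficient, p-value)."""
    rows = []
    for name, vals in traits.items():
        res = correlate(bw, vals, age=age, age_min=age_min)
        rows.append({"trait": name, "N": res.n, "correlation": res.r, "p": res.p})
    return pd.DataFrame(rows)


def clean_cohort(records: pd.DataFrame, k_sd: float = 4.0):
    """Full phenotype pipeline in the fixed order; returns (frame, log).

    BP medication adjustment, Friedewald LDL, log transforms and k-SD trim
    of each quantitative trait (trimmed values set missing), birthweight
    exclusions and Z-score.
    """
    df = adjust_bp(records)
    if {"total_cholesterol", "hdl", "triglycerides"} <= set(df.columns):
        df["ldl"] = friedewald_ldl(df["total_cholesterol"], df["hdl"], df["triglycerides"])
    quantitative = [c for c in ("sbp", "dbp", "total_cholesterol", "hdl",
                                "triglycerides", "glucose", "bmi", "ldl")
                    if c in df.columns]
    for col in quantitative:
        kept = transform_and_trim(df[col], log_transform=col in LOG_TRAITS, k_sd=k_sd)
        cleaned = pd.Series(np.nan, index=df.index)
        cleaned[kept.index] = kept
        df[col] = cleaned
    df, log = clean_birthweight(df)
    return df, log
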