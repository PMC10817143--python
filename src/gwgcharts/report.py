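"""Descriptive median/IQR tables for the harmonized cohort.

Quantiles use the linear-interpolation convention (numpy default); every
emitted table states this in its footer because median and IQR values
depend on it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["median_iqr_table", "describe", "QUANTILE_FOOTER"]

QUANTILE_FOOTER = "# quantiles: linear interpolation; IQR = (P25, P75)"

#: Table-1 style variables and where they come from
_SUBJECT_VARS = ("maternal_age_y", "prepreg_bmi", "height_cm",
                 "prepreg_weight_kg", "third_trimester_weight_kg",
                 "birth_weight_g", "ga_birth_weeks")


def median_iqr_table(df: pd.DataFrame, value_cols, by) -> pd.DataFrame:
    """Per-group n, median and IQR for each value column.

    Groups with no finite values in a column get blank (NaN) statistics;
    the table is invariant to input row order.
    """
    by = [by] if isinstance(by, str) else list(by)
    rows = []
    for keys, grp in df.groupby(by, dropna=False, observed=True, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        row["n"] = len(grp)
        for col in value_cols:
            vals = grp[col].dropna().to_numpy(dtype=float)
            if vals.size:
                row[f"{col}_median"] = float(np.quantile(vals, 0.5))
                row[f"{col}_q25"] = float(np.quantile(vals, 0.25))
                row[f"{col}_q75"] = float(np.quantile(vals, 0.75))
            else:
                row[f"{col}_median"] = np.nan
                row[f"{col}_q25"] = np.nan
                row[f"{col}_q75"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _third_trimester_weight(visits: pd.DataFrame,
                            window: tuple[int, int] = (28, 42),
                            how: str = "last") -> pd.Series:
    """Per-subject third-trimester weight: last visit in the window (or max)."""
    lo, hi = window
    t3 = visits[visits["ga_weeks"].between(lo, hi)]
    if how == "max":
        return t3.groupby("subject_id")["weight_kg"].max()
    t3 = t3.sort_values(["subject_id", "ga_weeks"], kind="stable")
    return t3.groupby("subject_id")["weight_kg"].last()


def describe(subjects: pd.DataFrame, visits: pd.DataFrame,
             by: str | list = "site",
             third_trimester: tuple[int, int] = (28, 42),
             third_weight: str = "last") -> pd.DataFrame:
    """Country/category-level distribution table of the variables of interest.

    Median (IQR) of maternal age, pre-pregnancy BMI, height, pre-pregnancy
    weight, third-trimester weight (last visit at weeks 28-42 by default,
    switchable to the maximum), birth weight and gestational age at birth.
    """
    subj = subjects.copy()
    t3w = _third_trimester_weight(visits, third_trimester, third_weight)
    subj["third_trimester_weight_kg"] = t3w.reindex(subj["subject_id"]).to_numpy()
    cols = [c for c in _SUBJECT_VARS if c in subj.columns]
    return median_iqr_table(subj, cols, by)
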